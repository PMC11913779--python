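"""Moderated differential expression on the log-normalized scale.

Two designs are supported: paired pre-/on-treatment contrasts (per-gene
paired differences across patients) and a continuous per-sample covariate
(per-gene simple regression). Both moderate the per-gene variance with the
empirical-Bayes shrinkage of Smyth (2004): the posterior variance is

    s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)

where the prior (d0, s0^2) is estimated by fitting a scaled inverse-chi-square
distribution to the observed residual variances via the method of moments on
log(s^2). The moderated t statistic has d0 + d degrees of freedom. p values
are corrected across genes with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ON_TREATMENT, PRETX, ExpressionMatrix

FDR_THRESHOLD = 0.1  # significance threshold for calling DE genes


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up FDR values (monotone, in [0, 1])."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (vectorized)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y  # starting value accurate for large y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def squeeze_variance(s2: np.ndarray, df: float) -> Tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-gene variances toward a pooled prior.

    Returns (d0, s0_sq, s2_post). d0 = inf means complete shrinkage (the
    observed variances are less dispersed than chi-square sampling alone
    would produce).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two genes with positive variance")
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
        s2_post = np.full_like(s2, s0_sq)
    else:
        d0 = float(2.0 * _trigamma_inverse(np.array([e_var]))[0])
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_post


def _moderated_table(
    effect: np.ndarray,
    s2: np.ndarray,
    df: float,
    stderr_unit: np.ndarray,
    genes: pd.Index,
    mean_expr: np.ndarray,
    prior_df: Optional[float],
) -> pd.DataFrame:
    """Assemble a DE table from effects and residual variances.

    ``stderr_unit`` maps sqrt(variance) to the standard error of the effect
    (e.g. 1/sqrt(n) for a paired mean difference).
    """
    if prior_df is None:
        d0, s0_sq, s2_post = squeeze_variance(s2, df)
    elif prior_df == 0:
        d0, s0_sq, s2_post = 0.0, float("nan"), s2.copy()
    else:
        d0 = float(prior_df)
        _, s0_sq, _ = squeeze_variance(s2, df)
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / (np.sqrt(s2_post) * stderr_unit)
    total_df = df + (0.0 if not np.isfinite(d0) else d0)
    if np.isfinite(d0):
        p = 2.0 * stats.t.sf(np.abs(t), df=total_df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    p = np.where(np.isnan(t), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    out = pd.DataFrame(
        {
            "lfc": effect,
            "t": t,
            "pvalue": p,
            "fdr": benjamini_hochberg(p),
            "mean_expr": mean_expr,
        },
        index=genes,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    out.attrs["residual_df"] = df
    return out


def paired_differential_expression(
    m: ExpressionMatrix,
    timepoints: Tuple[str, str] = (PRETX, ON_TREATMENT),
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Paired pre/on-treatment DE controlling for patient-specific effects.

    Computes, per gene, paired differences (second timepoint minus first) of
    log-normalized values across patients with both timepoints; unpaired
    samples are dropped with a warning. The moderated statistic is a paired t
    with empirical-Bayes variance shrinkage (``prior_df=0`` disables
    moderation and recovers the classic paired t test).

    Returns a table with columns lfc (mean paired log2 difference), t,
    pvalue, fdr, mean_expr.
    """
    if m.scale != "log":
        raise ValueError("paired DE expects log-normalized expression")
    base_tp, alt_tp = timepoints
    meta = m.samples
    pre = meta.index[meta["timepoint"] == base_tp]
    on = meta.index[meta["timepoint"] == alt_tp]
    pre_by_pat = dict(zip(meta.loc[pre, "patient"], pre))
    on_by_pat = dict(zip(meta.loc[on, "patient"], on))
    paired = sorted(set(pre_by_pat) & set(on_by_pat))
    unpaired = (set(pre_by_pat) | set(on_by_pat)) - set(paired)
    if unpaired:
        warnings.warn(f"dropping {len(unpaired)} patients without both timepoints")
    if len(paired) < 3:
        raise ValueError(f"need >= 3 complete pairs, have {len(paired)}")
    diffs = (
        m.values[[on_by_pat[p] for p in paired]].to_numpy()
        - m.values[[pre_by_pat[p] for p in paired]].to_numpy()
    )
    n = len(paired)
    effect = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)
    mean_expr = m.values.to_numpy().mean(axis=1)
    out = _moderated_table(
        effect, s2, n - 1.0, np.full(m.values.shape[0], 1.0 / np.sqrt(n)),
        m.genes, mean_expr, prior_df,
    )
    out.attrs["n_pairs"] = n
    out.attrs["patients"] = paired
    return out


def covariate_differential_expression(
    m: ExpressionMatrix,
    covariate: pd.Series,
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Single-timepoint DE against a continuous covariate.

    The covariate is centered and scaled before the fit; per gene the slope
    of log-normalized expression on the scaled covariate is tested with the
    same empirical-Bayes moderation as the paired contrast. A positive slope
    means higher expression with a larger covariate. ``lfc`` holds the slope.
    """
    if m.scale != "log":
        raise ValueError("covariate DE expects log-normalized expression")
    x = covariate.reindex(m.sample_ids).to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 samples")
    if np.std(x) == 0:
        raise ValueError("covariate has zero variance")
    x = (x - x.mean()) / x.std(ddof=1)
    Y = m.values.to_numpy()
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    slope = (Y - Y.mean(axis=1, keepdims=True)) @ xc / sxx
    fitted = Y.mean(axis=1, keepdims=True) + slope[:, None] * xc[None, :]
    rss = ((Y - fitted) ** 2).sum(axis=1)
    df = n - 2.0
    s2 = rss / df
    out = _moderated_table(
        slope, s2, df, np.full(Y.shape[0], 1.0 / np.sqrt(sxx)),
        m.genes, Y.mean(axis=1), prior_df,
    )
    out.attrs["n_samples"] = n
    return out
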