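"""Treatment-responsive signature derivation, scoring and robustness.

The signature is the top-k genes (default 70) of the paired pre-/on-treatment
DE ranking at FDR < 0.1. The per-patient signature score is the mean
log-normalized change of signature genes divided by the cohort standard
deviation of that mean — scaled but not centered, so the zero point (no
change) is preserved. Patients at or above the cohort median score are
"reactive", the rest "quiescent". A noise-robustness sweep over prefix
subsets identifies the smallest subset whose correlation with tumor-size
change survives added noise (the compact-signature analog).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSignature
from .diffexp import FDR_THRESHOLD


def derive_signature(
    de: pd.DataFrame,
    k: int = 70,
    fdr_threshold: float = FDR_THRESHOLD,
    name: str = "signature",
) -> GeneSignature:
    """Top-k genes of a DE table by significance.

    Ordering: ascending FDR, ties by ascending p, then descending \\|lfc\\|,
    then gene ID — fully deterministic. Direction is the sign of the fold
    change. If fewer than ``k`` genes pass ``fdr_threshold`` the signature is
    truncated with a warning; zero significant genes is an error.
    """
    sig = de[de["fdr"] < fdr_threshold].copy()
    if sig.empty:
        raise ValueError(f"no genes significant at FDR < {fdr_threshold}")
    sig["_abs_lfc"] = -sig["lfc"].abs()
    sig = sig.iloc[np.lexsort((sig.index, sig["_abs_lfc"], sig["pvalue"], sig["fdr"]))]
    if len(sig) < k:
        warnings.warn(f"only {len(sig)} significant genes; truncating signature from k={k}")
        k = len(sig)
    top = sig.iloc[:k]
    return GeneSignature(
        list(top.index),
        np.sign(top["lfc"]).replace(0, 1.0),
        top["lfc"],
        name=name,
    )


def _paired_changes(
    pre: ExpressionMatrix, on: ExpressionMatrix, genes: Sequence[str]
) -> pd.DataFrame:
    """Per-gene, per-patient log-expression change (on minus pre) for ``genes``."""
    for m in (pre, on):
        if m.scale != "log":
            raise ValueError("signature scoring expects log-normalized expression")
    pre_pat = dict(zip(pre.samples["patient"], pre.sample_ids))
    on_pat = dict(zip(on.samples["patient"], on.sample_ids))
    patients = sorted(set(pre_pat) & set(on_pat))
    if not patients:
        raise ValueError("no paired patients present in both matrices")
    present = [g for g in genes if g in pre.genes and g in on.genes]
    missing = set(genes) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} signature genes missing from expression; dropped")
    if not present:
        raise ValueError("no signature genes present in the expression matrices")
    delta = (
        on.values.loc[present, [on_pat[p] for p in patients]].to_numpy()
        - pre.values.loc[present, [pre_pat[p] for p in patients]].to_numpy()
    )
    return pd.DataFrame(delta, index=present, columns=patients)


def signature_mean_change(
    pre: ExpressionMatrix, on: ExpressionMatrix, sig: GeneSignature
) -> pd.Series:
    """Raw per-patient mean (direction-weighted) change of signature genes."""
    changes = _paired_changes(pre, on, sig.genes)
    d = sig.directions.loc[changes.index].to_numpy()
    return pd.Series((changes.to_numpy() * d[:, None]).mean(axis=0), index=changes.columns)


def score_signature_change(
    pre: ExpressionMatrix, on: ExpressionMatrix, sig: GeneSignature
) -> pd.Series:
    """Per-patient signature score: mean change scaled, without centering.

    The cohort SD divides the raw mean change; no mean is subtracted, so a
    score of 0 still means "no change". A zero cohort SD (degenerate cohort)
    is an error.
    """
    raw = signature_mean_change(pre, on, sig)
    sd = raw.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cohort SD of signature changes is zero; cannot scale")
    return raw / sd


def classify_reactivity(scores: pd.Series) -> pd.Series:
    """Median split of signature scores into reactive (>= median) / quiescent.

    Ties at the median are reactive, so the reactive group always holds
    ceil(n/2) patients.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 patients to classify reactivity")
    med = scores.median()
    if scores.nunique() == 1:
        warnings.warn("all scores identical; every patient classified reactive")
    return pd.Series(
        np.where(scores >= med, "reactive", "quiescent"), index=scores.index
    )


def gene_set_score(m: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    """Mean per-sample Z-score (across samples) of a gene set's log expression."""
    if m.scale != "log":
        raise ValueError("gene_set_score expects log-normalized expression")
    present = [g for g in genes if g in m.genes]
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    if len(present) < len(set(genes)):
        warnings.warn(f"{len(set(genes)) - len(present)} set genes missing; dropped")
    vals = m.values.loc[present]
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1).replace(0, np.nan)
    z = vals.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return z.mean(axis=0)


def subset_robustness(
    de: pd.DataFrame,
    pre: ExpressionMatrix,
    on: ExpressionMatrix,
    outcome: pd.Series,
    sizes: Optional[Sequence[int]] = None,
    noise_sd_grid: Sequence[float] = (0.25, 0.5, 1.0),
    reps: int = 50,
    seed: int = 0,
    retention: float = 0.9,
    k_full: int = 70,
    fdr_threshold: float = FDR_THRESHOLD,
) -> Tuple[pd.DataFrame, int]:
    """Noise-robustness of prefix subsets of the ranked signature.

    For each prefix size k: the Pearson correlation of the k-gene score with
    the outcome (tumor-size change), and the mean correlation after adding
    Gaussian noise (SDs from ``noise_sd_grid``) to the per-gene changes over
    ``reps`` replicates. Returns the sweep table and the smallest k whose
    noise-degraded correlation retains ``retention`` of the full signature's
    (same sign, magnitude criterion) — the compact-signature selection rule.
    """
    if reps < 10:
        warnings.warn("reps < 10 gives unstable robustness estimates")
    full = derive_signature(de, k=k_full, fdr_threshold=fdr_threshold)
    changes = _paired_changes(pre, on, full.genes)
    d = full.directions.loc[changes.index].to_numpy()[:, None]
    changes = changes * d
    y = outcome.reindex(changes.columns).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if sizes is None:
        sizes = range(1, len(full) + 1)
    sizes = [k for k in sizes if 1 <= k <= len(full)]

    def corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    arr = changes.to_numpy()
    rows = []
    for k in sizes:
        score_k = arr[:k].mean(axis=0)
        r_plain = corr(score_k, y)
        noisy = []
        for sd in noise_sd_grid:
            for _ in range(reps):
                pert = arr[:k] + rng.normal(0.0, sd, size=arr[:k].shape)
                noisy.append(corr(pert.mean(axis=0), y))
        rows.append({"size": k, "correlation": r_plain, "noise_correlation": float(np.mean(noisy))})
    table = pd.DataFrame(rows).set_index("size")

    full_noise = table["noise_correlation"].iloc[-1]
    sign = np.sign(full_noise) if full_noise != 0 else 1.0
    ok = (np.sign(table["noise_correlation"]) == sign) & (
        table["noise_correlation"].abs() >= retention * abs(full_noise)
    )
    selected = int(table.index[ok][0]) if ok.any() else int(table.index[-1])
    return table, selected


def pseudobulk_aggregate(
    sc: ad.AnnData,
    by: Sequence[str] = ("patient",),
    cell_type: Optional[str] = None,
) -> ExpressionMatrix:
    """Sum single-cell counts within groups to form pseudobulk samples.

    ``by`` names obs columns (e.g. patient, or patient + cell_type);
    restricting to one ``cell_type`` first enables cell-type-specific
    outcome DE. Empty groups are simply absent from the output.
    """
    obs = sc.obs
    for key in by:
        if key not in obs:
            raise ValueError(f"grouping key {key!r} not in obs")
    mask = np.ones(sc.n_obs, dtype=bool)
    if cell_type is not None:
        mask = (obs["cell_type"] == cell_type).to_numpy()
        if not mask.any():
            raise ValueError(f"no cells of type {cell_type!r}")
    X = sc.X[mask]
    keys = obs.loc[mask, list(by)].astype(str).agg("|".join, axis=1)
    groups = sorted(keys.unique())
    cols = {}
    for g in groups:
        cols[g] = np.asarray(X[(keys == g).to_numpy()].sum(axis=0)).ravel()
    values = pd.DataFrame(cols, index=sc.var_names)
    meta = pd.DataFrame(
        [dict(zip(by, g.split("|"))) for g in groups], index=groups
    )
    return ExpressionMatrix(values, meta, scale="counts")
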