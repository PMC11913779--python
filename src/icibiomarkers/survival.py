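"""Clinical outcome classification and survival statistics.

Response bookkeeping follows immune-related RECIST: best target-lesion
change of -30% or better is a response (irCR at -100%), +20% growth or
unequivocal new lesions is progression, clinical progression without scans
is irPD, the rest is stable disease. Clinical benefit (CB) is 12 months of
progression-free survival. Kaplan-Meier, log-rank and Cox proportional
hazards (Efron tie handling) are computed with lifelines; continuous
covariates are optionally log10-transformed and are scaled and centered
before regression. Multiple cell-type screens are BH-corrected.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from .datatypes import CompositionEstimate, validate_survival_frame
from .diffexp import benjamini_hochberg

CB_HORIZON_MONTHS = 12.0
RESPONSE_SHRINKAGE_PCT = -30.0
PROGRESSION_GROWTH_PCT = 20.0

NOT_ASSESSABLE = "not assessable"


def classify_response(
    changes: Sequence[float],
    new_lesions: bool = False,
    clinical_progression: bool = False,
) -> Tuple[str, bool]:
    """irRECIST category and responder flag from per-scan % size changes.

    ``changes`` are percent changes in the target-lesion diameter sum from
    the pre-treatment scan. Best change <= -30% is a response (irCR at
    -100%, else irPR); any change >= +20% or unequivocal new lesions is
    irPD; clinical progression without scans is irPD; otherwise irSD.
    """
    changes = [c for c in changes if c is not None and np.isfinite(c)]
    if not changes:
        if clinical_progression:
            return "irPD", False
        raise ValueError("no assessable scans and no clinical-progression override")
    best, worst = min(changes), max(changes)
    if best <= -100.0:
        return "irCR", True
    if best <= RESPONSE_SHRINKAGE_PCT:
        return "irPR", True
    if worst >= PROGRESSION_GROWTH_PCT or new_lesions:
        return "irPD", False
    return "irSD", False


def ici_window_shrinkage(pre_sum: float, on_sum: float) -> float:
    """Tumor shrinkage over the ICI-only window: change in target-lesion
    diameter sum between the pre-treatment and first on-treatment scans,
    as a percentage of the pre-treatment sum."""
    if pre_sum <= 0:
        raise ValueError("pre-treatment lesion sum must be positive")
    return 100.0 * (on_sum - pre_sum) / pre_sum


def classify_cb(
    pfs_time: pd.Series,
    pfs_event: pd.Series,
    horizon: float = CB_HORIZON_MONTHS,
    excluded: Sequence[str] = (),
) -> pd.Series:
    """Clinical-benefit labels from PFS.

    CB if progression-free (and alive) for at least ``horizon`` months; NCB
    if progression/death occurred earlier; censored before the horizon
    without progression is not assessable. Patients on the exclusion list
    (e.g. switched to alternative therapy) are not assessable.
    """
    labels = {}
    for p in pfs_time.index:
        if p in excluded:
            labels[p] = NOT_ASSESSABLE
        elif pfs_time[p] >= horizon:
            labels[p] = "CB"
        elif pfs_event[p]:
            labels[p] = "NCB"
        else:
            labels[p] = NOT_ASSESSABLE
    return pd.Series(labels, name="cb").reindex(pfs_time.index)


def km_estimate(
    time: pd.Series,
    event: pd.Series,
    risk_times: Optional[Sequence[float]] = None,
) -> Dict[str, object]:
    """Product-limit survival estimate.

    Returns the step curve, the median survival time (earliest time with
    S(t) <= 0.5; ``inf`` = not reached) and, if requested, the number at
    risk at each time in ``risk_times``.
    """
    df = validate_survival_frame(pd.DataFrame({"time": time, "event": event}))
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], df["event"])
    curve = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
    out = {
        "curve": curve,
        "median": float(kmf.median_survival_time_),
        "model": kmf,
    }
    if risk_times is not None:
        at_risk = [int((df["time"] >= t).sum()) for t in risk_times]
        out["risk_table"] = pd.Series(at_risk, index=list(risk_times), name="at_risk")
    return out


def logrank_test(time: pd.Series, event: pd.Series, groups: pd.Series) -> Tuple[float, float]:
    """k-sample log-rank test; returns (chi-square, p) with k-1 df."""
    df = pd.DataFrame({"time": time, "event": event, "group": groups}).dropna()
    counts = df["group"].value_counts()
    if len(counts) < 2 or (counts == 0).any():
        raise ValueError("need >= 2 non-empty groups")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), float(res.p_value)


def _prepare_covariates(
    df: pd.DataFrame,
    covariates: Sequence[str],
    log10_transform: Sequence[str],
    scale: bool,
) -> pd.DataFrame:
    out = df.copy()
    for c in covariates:
        if c in log10_transform:
            if (out[c] <= 0).any():
                raise ValueError(f"covariate {c!r} must be positive for log10 transform")
            out[c] = np.log10(out[c])
        if out[c].std(ddof=0) == 0:
            raise ValueError(f"covariate {c!r} is constant")
        if scale:
            out[c] = (out[c] - out[c].mean()) / out[c].std(ddof=1)
    return out


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
    scale: bool = True,
    log10_transform: Sequence[str] = (),
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards fit (uni- or multivariable).

    Continuous covariates are optionally log10-transformed, then scaled and
    centered (default). Returns per covariate: coef, HR, 95% CI bounds,
    standard error and Wald p. Efron tie correction by default (switchable
    to Breslow).
    """
    validate_survival_frame(df, time_col, event_col)
    n_events = int(df[event_col].sum())
    if n_events < 10:
        warnings.warn(f"only {n_events} events; Cox estimates may be unstable")
    work = _prepare_covariates(df[[time_col, event_col, *covariates]].dropna(),
                               covariates, log10_transform, scale)
    cph = CoxPHFitter()
    cph.fit(work, duration_col=time_col, event_col=event_col, robust=False)
    if ties == "breslow":  # lifelines uses Efron; refit via statsmodels for Breslow
        import statsmodels.duration.hazard_regression as hr

        mod = hr.PHReg(work[time_col], work[covariates], status=work[event_col], ties="breslow")
        res = mod.fit()
        coefs = pd.Series(res.params, index=covariates)
        ses = pd.Series(res.bse, index=covariates)
        pvals = pd.Series(res.pvalues, index=covariates)
    else:
        coefs, ses, pvals = cph.params_, cph.standard_errors_, cph.summary["p"]
    z = sps.norm.ppf(0.975)
    out = pd.DataFrame(
        {
            "coef": coefs,
            "hr": np.exp(coefs),
            "hr_lower": np.exp(coefs - z * ses),
            "hr_upper": np.exp(coefs + z * ses),
            "se": ses,
            "pvalue": pvals,
        }
    )
    out.attrs["n_events"] = n_events
    out.attrs["model"] = cph
    return out


def screen_cell_types(
    comp: CompositionEstimate,
    df: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    scale_name: str = "rna",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Univariable Cox screen across cell types with BH correction.

    For each cell type, the per-patient fraction (log10-transformed with a
    half-minimum floor, scaled and centered) enters a univariable Cox model;
    p values are BH-corrected across all tested types. Types with all-zero
    fractions are skipped with a warning. ``significant`` marks FDR below
    ``fdr_threshold``.
    """
    fr = comp.rna_fraction if scale_name == "rna" else comp.cell_fraction
    fr = fr.loc[df.index]
    rows = []
    for ct in fr.columns:
        v = fr[ct].astype(float)
        if (v == 0).all():
            warnings.warn(f"cell type {ct!r} has all-zero fractions; skipped")
            continue
        floor = v[v > 0].min() / 2.0
        x = np.log10(v.where(v > 0, floor))
        if x.std(ddof=0) == 0:
            warnings.warn(f"cell type {ct!r} is constant after transform; skipped")
            continue
        work = df[[time_col, event_col]].copy()
        work[ct] = x
        fit = cox_fit(work, [ct], time_col, event_col, scale=True)
        rows.append(
            {
                "cell_type": ct,
                "coef": fit.loc[ct, "coef"],
                "hr": fit.loc[ct, "hr"],
                "hr_lower": fit.loc[ct, "hr_lower"],
                "hr_upper": fit.loc[ct, "hr_upper"],
                "pvalue": fit.loc[ct, "pvalue"],
            }
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    out["fdr"] = benjamini_hochberg(out["pvalue"])
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values("pvalue")


def median_split(values: pd.Series) -> pd.Series:
    """High/low split at the cohort median; values at the median go low."""
    if len(values) < 2:
        raise ValueError("need >= 2 patients for a median split")
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index)


def quadrant_analysis(
    tmb: pd.Series,
    tmc: pd.Series,
    df: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
) -> Dict[str, object]:
    """Four-way stratification by crossing the TMB and TMC median splits.

    Patients missing either marker are excluded with a warning. Returns the
    quadrant labels, per-quadrant KM medians, the overall (k=4) log-rank
    test and the label of the double-high quadrant.
    """
    common = tmb.dropna().index.intersection(tmc.dropna().index).intersection(df.index)
    dropped = df.index.difference(common)
    if len(dropped):
        warnings.warn(f"excluding {len(dropped)} patients missing a marker")
    tmb_split = median_split(tmb.loc[common])
    tmc_split = median_split(tmc.loc[common])
    labels = "TMB-" + tmb_split + "/TMC-" + tmc_split
    medians = {}
    for g, idx in labels.groupby(labels).groups.items():
        sub = df.loc[idx]
        medians[g] = km_estimate(sub[time_col], sub[event_col])["median"]
    chi2, p = logrank_test(df.loc[common, time_col], df.loc[common, event_col], labels)
    return {
        "labels": labels,
        "medians": pd.Series(medians),
        "logrank_chi2": chi2,
        "logrank_p": p,
        "double_high": "TMB-high/TMC-high",
    }


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> Tuple[float, float]:
    """Two-proportions z-test (pooled variance, two-sided)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * sps.norm.sf(abs(z)))
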