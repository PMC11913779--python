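"""Genomic biomarker rules: caller consensus, TMB, MSI, copy-number classes.

Mutation tables carry one record per (biopsy, variant) with the set of
callers supporting it and a nonsynonymous-coding flag (consequence
annotation is upstream). TMB is nonsynonymous coding mutations per megabase
over a 35.6 Mb coding space, averaged across a patient's biopsies. MSI is
called at an MSIsensor score of at least 3.5. Amplification means copies
greater than twice the (copy-number-adjusted) ploidy; deletion means loss of
more than half the baseline copies (baseline = ploidy).
"""

from __future__ import annotations

import warnings
from typing import Tuple, Union

import numpy as np
import pandas as pd

CODING_SPACE_MB = 35.6
MSI_THRESHOLD = 3.5

REQUIRED_COLUMNS = ("patient", "biopsy", "chrom", "pos", "ref", "alt", "nonsyn_coding", "callers")


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> Tuple[str, int, str, str]:
    """Left-align an indel key: trim shared suffix, then shared prefix.

    Keeps (chrom, pos, ref, alt) comparable across callers that pad alleles
    differently. Positions are 1-based.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _caller_sets(callers: pd.Series) -> pd.Series:
    def to_set(v):
        if isinstance(v, (set, frozenset)):
            return frozenset(v)
        if isinstance(v, (list, tuple)):
            return frozenset(v)
        return frozenset(x for x in str(v).split(";") if x)

    return callers.map(to_set)


def consensus_filter(table: pd.DataFrame, min_callers: int = 2) -> pd.DataFrame:
    """Retain variants supported by at least ``min_callers`` callers."""
    sets = _caller_sets(table["callers"])
    if (sets.map(len) == 0).any():
        raise ValueError("caller sets must be non-empty")
    distinct = frozenset().union(*sets)
    if min_callers > len(distinct):
        warnings.warn(
            f"min_callers={min_callers} exceeds the {len(distinct)} distinct callers present; "
            "result may be empty"
        )
    return table[sets.map(len) >= min_callers].copy()


def compute_tmb(
    table: pd.DataFrame,
    coding_space_mb: float = CODING_SPACE_MB,
) -> pd.Series:
    """Per-patient TMB: nonsynonymous coding mutations per Mb, biopsy-averaged.

    Per biopsy, the count of flagged mutations divided by the coding space;
    per patient, the mean across that patient's biopsies (multi-biopsy
    averaging). Patients appear in the output iff they have >= 1 biopsy in
    the table; a biopsy with zero flagged mutations contributes TMB 0.
    """
    if coding_space_mb <= 0:
        raise ValueError("coding_space_mb must be positive")
    biopsies = table[["patient", "biopsy"]].drop_duplicates()
    flagged = table[table["nonsyn_coding"].astype(bool)]
    per_biopsy = (
        flagged.groupby(["patient", "biopsy"]).size()
        .reindex(pd.MultiIndex.from_frame(biopsies), fill_value=0)
        / coding_space_mb
    )
    return per_biopsy.groupby(level="patient").mean().rename("tmb")


def classify_msi(score: Union[float, pd.Series], threshold: float = MSI_THRESHOLD):
    """MSI flag: score at least ``threshold`` (boundary inclusive)."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MSI scores must be non-negative")
    flag = arr >= threshold
    if isinstance(score, pd.Series):
        return pd.Series(flag, index=score.index, name="msi")
    return bool(flag) if np.isscalar(score) else flag


def classify_cna(copies: float, ploidy: float) -> str:
    """Copy-number class: amplified / deleted / neutral.

    Amplified if copies > 2 * ploidy; deleted if the loss from the baseline
    (= ploidy) exceeds half the baseline, i.e. copies < ploidy / 2.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if copies < 0:
        raise ValueError("copy number must be non-negative")
    if copies > 2.0 * ploidy:
        return "amplified"
    if ploidy - copies > ploidy / 2.0:
        return "deleted"
    return "neutral"


def genomic_summary(
    table: pd.DataFrame,
    msi_scores: pd.Series,
    coding_space_mb: float = CODING_SPACE_MB,
    msi_threshold: float = MSI_THRESHOLD,
    min_callers: int = 2,
) -> pd.DataFrame:
    """Consensus-filter, then per-patient TMB + MSI flag in one table."""
    consensus = consensus_filter(table, min_callers=min_callers)
    tmb = compute_tmb(consensus, coding_space_mb)
    out = tmb.to_frame()
    out["msi_score"] = msi_scores.reindex(out.index)
    out["msi"] = classify_msi(out["msi_score"].fillna(0.0), msi_threshold)
    return out
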