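"""Core in-memory containers shared across the pipeline.

Expression data is held genes x samples (the bulk RNA-seq convention);
single-cell data uses :class:`anndata.AnnData` (cells x genes). Survival and
outcome tables are plain :class:`pandas.DataFrame` objects with documented
column contracts so they compose directly with lifelines and statsmodels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Allowed values of the ExpressionMatrix scale flag.
SCALES = ("counts", "linear", "log")

#: Timepoint labels used in sample metadata.
PRETX = "PreTx"
ON_TREATMENT = "ICI-4W"
POSTTX = "PostTx"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample. Raw counts,
        linear-normalized, or log-normalized depending on ``scale``.
    samples
        DataFrame indexed by sample ID (must equal ``values.columns``).
        Recognised columns: ``patient``, ``timepoint``, ``tissue``, ``arm``.
    scale
        One of ``"counts"``, ``"linear"``, ``"log"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = None
    scale: str = "counts"

    def __post_init__(self):
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.columns)
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene IDs must be unique")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample metadata index must match expression columns")
        if self.scale in ("counts", "linear"):
            arr = self.values.to_numpy()
            if np.any(arr < 0):
                raise ValueError(f"negative values not allowed on the {self.scale} scale")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, ids) -> "ExpressionMatrix":
        ids = pd.Index(ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids].copy(), self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.samples.copy(), self.scale)


@dataclass
class GeneSignature:
    """An ordered, directed gene list (e.g. an on-treatment T/NK signature).

    ``genes`` are ordered by the selection statistic; ``directions`` holds
    +1/-1 per gene (sign of the fold change); ``stats`` the selection
    statistic itself.
    """

    genes: list
    directions: pd.Series
    stats: pd.Series = None
    name: str = "signature"

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        self.directions = pd.Series(self.directions, dtype=float).reindex(self.genes)
        if self.stats is not None:
            self.stats = pd.Series(self.stats, dtype=float).reindex(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def head(self, k: int, name: Optional[str] = None) -> "GeneSignature":
        """Prefix sub-signature of the ``k`` top-ranked genes."""
        g = list(self.genes[:k])
        return GeneSignature(
            g,
            self.directions.loc[g],
            None if self.stats is None else self.stats.loc[g],
            name or f"{self.name}[:{k}]",
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene": self.genes, "direction": self.directions.values})
        if self.stats is not None:
            out["stat"] = self.stats.values
        return out


@dataclass
class GroundTruth:
    """Known composition and patient-level parameters of a simulated panel.

    ``rna_fractions`` / ``cell_fractions``: samples x cell types, each row
    summing to 1. ``sampled_cells`` maps sample ID -> integer positions of the
    reference cells that were pooled, so every truth quantity is recomputable.
    ``patients`` (cohort simulations only): per-patient responder flag,
    signature effect delta, TMC, TMB and true hazard.
    """

    rna_fractions: pd.DataFrame
    cell_fractions: pd.DataFrame
    sampled_cells: dict = field(default_factory=dict)
    patients: Optional[pd.DataFrame] = None

    def __post_init__(self):
        for name in ("rna_fractions", "cell_fractions"):
            df = getattr(self, name)
            bad = np.abs(df.sum(axis=1) - 1.0) > 1e-9
            if bad.any():
                raise ValueError(f"{name} rows must sum to 1 (violated for {list(df.index[bad])})")


@dataclass
class CompositionEstimate:
    """Deconvolution output: samples x cell types on two scales.

    ``rna_fraction`` is the share of transcript mass per cell type;
    ``cell_fraction`` the share of cells (converted via per-type RNA
    content); ``residual`` the per-sample least-squares residual norm.
    """

    rna_fraction: pd.DataFrame
    cell_fraction: Optional[pd.DataFrame] = None
    residual: Optional[pd.Series] = None

    def __post_init__(self):
        for name in ("rna_fraction", "cell_fraction"):
            df = getattr(self, name)
            if df is None:
                continue
            arr = df.to_numpy()
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} entries must be non-negative")
            bad = np.abs(arr.sum(axis=1) - 1.0) > 1e-6
            if bad.any():
                raise ValueError(f"{name} rows must sum to 1")

    @property
    def cell_types(self) -> pd.Index:
        return self.rna_fraction.columns


def validate_survival_frame(df: pd.DataFrame, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
    """Check the survival-table contract: positive times, binary event flags."""
    if time_col not in df or event_col not in df:
        raise ValueError(f"survival table needs {time_col!r} and {event_col!r} columns")
    if (df[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df[event_col].isin([0, 1, True, False]).all():
        raise ValueError("event flags must be binary")
    return df


def as_dataclass_dict(obj) -> dict:
    return dataclasses.asdict(obj)
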