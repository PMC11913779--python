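"""Reference-based bulk deconvolution, benchmarking and the TMC readout.

A cell-type reference is built from a labeled single-cell atlas: per-cell
linear-normalized expression averaged within type, restricted to the most
variable genes (default 3000) after removing confounder gene classes
(mitochondrial, ribosomal, sex-specific, TCR/BCR variable-region genes by
configurable ID patterns). The reference method is non-negative least
squares on the linear scale; the benchmark harness accepts any method
registry so alternative algorithms can be compared on the same pseudobulk
ground truth (Spearman rho and NRMSE against both RNA- and cell-fraction
truth, where NRMSE = RMSE / range of predicted values).

Tumor monocyte content (TMC) is the monocyte fraction of a sample's
composition estimate (RNA-fraction scale by default, the scale the spike-in
experiment validates).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .datatypes import CompositionEstimate, ExpressionMatrix, GroundTruth

#: Default gene-ID patterns for confounder classes (symbol conventions).
CONFOUNDER_PATTERNS = (
    r"^MT-",            # mitochondrial
    r"^RP[LS]\d",       # ribosomal proteins
    r"^TR[ABGD][VJC]",  # TCR variable/joining/constant segments
    r"^IG[HKL][VJC]",   # BCR variable-region segments
    r"^XIST$", r"^RPS4Y", r"^DDX3Y$", r"^UTY$", r"^USP9Y$",  # sex-specific
)


@dataclass
class ReferenceProfile:
    """Cell-type expression reference for deconvolution.

    ``profiles``: cell types x genes mean linear-normalized expression;
    ``rna_content``: per-type mean total RNA (mean library size of the
    type's cells), used to convert RNA fractions to cell fractions;
    ``genes``: the selected (variable, non-confounder) gene list;
    ``malignant``: label of the malignant type.
    """

    profiles: pd.DataFrame
    rna_content: pd.Series
    genes: list
    malignant: Optional[str] = None

    def __post_init__(self):
        if (self.rna_content <= 0).any():
            raise ValueError("per-type RNA content must be positive")
        missing = set(self.genes) - set(self.profiles.columns)
        if missing:
            raise ValueError(f"selected genes absent from profiles: {sorted(missing)[:5]}")

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.index


def build_reference(
    sc: ad.AnnData,
    top_n: int = 3000,
    exclude_confounders: bool = True,
    confounder_patterns: Sequence[str] = CONFOUNDER_PATTERNS,
    min_cells: int = 10,
    exclude_types: Sequence[str] = (),
) -> ReferenceProfile:
    """Build a deconvolution reference from a labeled single-cell atlas.

    Cells are linear-normalized to the mean library size, averaged within
    type; the gene list is the ``top_n`` most variable genes (variance of
    log1p-normalized expression across cells) after confounder removal.
    Types below ``min_cells`` cells, or named in ``exclude_types`` (rare
    types such as Schwann cells), are dropped with a warning.
    """
    X = np.asarray(sc.X, dtype=float)
    lib = X.sum(axis=1)
    keep_cells = lib > 0
    X, lib = X[keep_cells], lib[keep_cells]
    obs_type = sc.obs["cell_type"][keep_cells]
    norm = X / lib[:, None] * lib.mean()

    genes = pd.Index(sc.var_names)
    keep_genes = np.ones(len(genes), dtype=bool)
    if exclude_confounders:
        pattern = re.compile("|".join(confounder_patterns))
        keep_genes = ~genes.to_series().str.match(pattern).to_numpy()

    profiles, content = {}, {}
    for t, idx in obs_type.groupby(obs_type, observed=True).groups.items():
        positions = obs_type.index.get_indexer(idx)
        if t in exclude_types:
            warnings.warn(f"cell type {t!r} excluded by name")
            continue
        if len(positions) < min_cells:
            warnings.warn(f"cell type {t!r} has {len(positions)} < {min_cells} cells; excluded")
            continue
        profiles[t] = norm[positions].mean(axis=0)
        content[t] = float(lib[positions].mean())

    prof = pd.DataFrame(profiles, index=genes).T
    log_norm = np.log1p(norm)
    variance = log_norm.var(axis=0)
    candidates = np.flatnonzero(keep_genes)
    order = candidates[np.argsort(variance[candidates], kind="stable")[::-1]]
    selected = [genes[i] for i in sorted(order[: min(top_n, len(order))])]

    malignant = None
    if "malignant" in sc.obs:
        malig_types = sc.obs.loc[sc.obs["malignant"].astype(bool), "cell_type"].unique()
        malignant = malig_types[0] if len(malig_types) else None
    return ReferenceProfile(prof, pd.Series(content), selected, malignant)


class NNLSDeconvolution(BaseEstimator):
    """Non-negative least-squares deconvolution (sklearn-style estimator).

    ``fit`` accepts a :class:`ReferenceProfile` (or a labeled AnnData atlas,
    from which a reference is built with :func:`build_reference`);
    ``predict`` takes a linear-scale bulk matrix and returns a
    :class:`CompositionEstimate` with RNA fractions (NNLS coefficients
    renormalized to sum 1), converted cell fractions and per-sample residual
    norms.
    """

    def __init__(self, top_n: int = 3000, exclude_confounders: bool = True, min_overlap: int = 100):
        self.top_n = top_n
        self.exclude_confounders = exclude_confounders
        self.min_overlap = min_overlap

    def fit(self, reference, y=None):
        if isinstance(reference, ad.AnnData):
            reference = build_reference(
                reference, top_n=self.top_n, exclude_confounders=self.exclude_confounders
            )
        self.reference_ = reference
        self.cell_types_ = list(reference.cell_types)
        return self

    def predict(self, bulk: ExpressionMatrix) -> CompositionEstimate:
        if not hasattr(self, "reference_"):
            raise ValueError("estimator is not fitted")
        ref = self.reference_
        if bulk.scale != "linear":
            raise ValueError("deconvolution expects linear-normalized bulk expression")
        overlap = [g for g in ref.genes if g in bulk.genes]
        if len(overlap) < self.min_overlap:
            raise ValueError(
                f"gene overlap {len(overlap)} below required {self.min_overlap}"
            )
        A = ref.profiles[overlap].to_numpy().T  # genes x types
        rows, resid = [], []
        for s in bulk.sample_ids:
            b = bulk.values.loc[overlap, s].to_numpy(dtype=float)
            if not np.any(b > 0):
                raise ValueError(f"sample {s!r} is all zero over the reference genes")
            coef, r = nnls(A, b)
            total = coef.sum()
            if total == 0:
                raise ValueError(f"sample {s!r}: all-zero NNLS solution")
            rows.append(coef / total)
            resid.append(r)
        f_rna = pd.DataFrame(rows, index=bulk.sample_ids, columns=ref.cell_types)
        f_cell = rna_to_cell_fraction(f_rna, ref.rna_content)
        return CompositionEstimate(f_rna, f_cell, pd.Series(resid, index=bulk.sample_ids))

    transform = predict


def deconvolve_nnls(bulk: ExpressionMatrix, ref: ReferenceProfile, min_overlap: int = 100) -> CompositionEstimate:
    """Functional wrapper over :class:`NNLSDeconvolution`."""
    return NNLSDeconvolution(min_overlap=min_overlap).fit(ref).predict(bulk)


def rna_to_cell_fraction(f_rna, s: pd.Series):
    """Convert RNA fractions to cell fractions via per-type RNA content.

    f_cell_k = (f_rna_k / s_k) / sum_j(f_rna_j / s_j). Accepts a Series (one
    sample) or DataFrame (samples x types).
    """
    if isinstance(f_rna, pd.Series):
        return rna_to_cell_fraction(f_rna.to_frame().T, s).iloc[0]
    s = s.reindex(f_rna.columns)
    active = f_rna > 0
    if (s.isna() | (s <= 0))[active.any(axis=0)].any():
        raise ValueError("RNA content must be positive for every type with f_rna > 0")
    ratio = f_rna / s
    denom = ratio.sum(axis=1)
    if (denom == 0).any():
        raise ValueError("zero denominator in RNA-to-cell conversion")
    return ratio.div(denom, axis=0)


def cell_to_rna_fraction(f_cell, s: pd.Series):
    """Inverse conversion: multiply by RNA content and renormalize."""
    if isinstance(f_cell, pd.Series):
        return cell_to_rna_fraction(f_cell.to_frame().T, s).iloc[0]
    prod = f_cell * s.reindex(f_cell.columns)
    return prod.div(prod.sum(axis=1), axis=0)


def _nrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    rng = pred.max() - pred.min()
    if rng == 0:
        return np.nan
    return float(np.sqrt(np.mean((pred - truth) ** 2)) / rng)


def _spearman(pred: np.ndarray, truth: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(truth) == 0:
        return np.nan
    return float(stats.spearmanr(pred, truth).statistic)


def benchmark_deconvolution(
    methods: Dict[str, Callable[[ExpressionMatrix], CompositionEstimate]],
    bulk: ExpressionMatrix,
    truth: GroundTruth,
) -> Dict[str, pd.DataFrame]:
    """Benchmark deconvolution methods against pseudobulk ground truth.

    Each method maps the bulk panel to a :class:`CompositionEstimate`;
    per sample and scale (RNA fraction / cell fraction) the Spearman rho
    across cell types and NRMSE (RMSE / range of predicted values) are
    computed against the matching truth. Returns ``{"per_sample": ...,
    "summary": ...}`` where the summary holds per-method medians and the
    ranking (ascending median NRMSE, ties by descending median rho, on the
    RNA scale).
    """
    if not methods:
        raise ValueError("need at least one registered method")
    per_sample = []
    for name, fn in methods.items():
        est = fn(bulk)
        for scale, pred_df, truth_df in (
            ("rna", est.rna_fraction, truth.rna_fractions),
            ("cell", est.cell_fraction, truth.cell_fractions),
        ):
            if pred_df is None:
                continue
            common = [t for t in truth_df.columns if t in pred_df.columns]
            for s in bulk.sample_ids:
                pred = pred_df.loc[s, common].to_numpy(dtype=float)
                tru = truth_df.loc[s, common].to_numpy(dtype=float)
                per_sample.append(
                    {
                        "method": name,
                        "sample": s,
                        "scale": scale,
                        "spearman": _spearman(pred, tru),
                        "nrmse": _nrmse(pred, tru),
                        "degenerate": np.std(pred) == 0,
                    }
                )
    per_sample = pd.DataFrame(per_sample)
    summary = (
        per_sample.groupby(["method", "scale"])[["spearman", "nrmse"]]
        .median()
        .rename(columns={"spearman": "median_spearman", "nrmse": "median_nrmse"})
        .reset_index()
    )
    rna = summary[summary["scale"] == "rna"].copy()
    rna = rna.sort_values(["median_nrmse", "median_spearman"], ascending=[True, False])
    summary.attrs["ranking"] = list(rna["method"])
    return {"per_sample": per_sample, "summary": summary}


def extract_tmc(
    comp: CompositionEstimate,
    monocyte_label: str = "Monocyte",
    scale: str = "rna",
    floor: Optional[float] = None,
) -> pd.DataFrame:
    """Tumor monocyte content per sample, with log10 transform.

    ``scale`` selects the RNA-fraction (default; validated by the spike-in
    experiment) or cell-fraction estimate. Zeros are floored at ``floor``
    before log10 (default: half the smallest nonzero fraction) and flagged.
    """
    df = comp.rna_fraction if scale == "rna" else comp.cell_fraction
    if df is None or monocyte_label not in df.columns:
        raise ValueError(f"monocyte label {monocyte_label!r} not in composition estimate")
    tmc = df[monocyte_label].astype(float)
    nonzero = tmc[tmc > 0]
    if floor is None:
        floor = float(nonzero.min() / 2.0) if len(nonzero) else 1e-6
    floored = tmc <= 0
    out = pd.DataFrame(
        {
            "tmc": tmc,
            "log10_tmc": np.log10(tmc.where(~floored, floor)),
            "floored": floored,
        }
    )
    return out


def cluster_compartment(
    comp_subset: pd.DataFrame,
    k: int = 2,
    floor: Optional[float] = None,
) -> Tuple[pd.Series, np.ndarray]:
    """Ward clustering of log10-scaled compartment composition.

    Values are log10-transformed (zeros floored at half the smallest nonzero
    value per column), column Z-scored, then clustered agglomeratively with
    Ward minimum-variance linkage on Euclidean distances. Constant columns
    are dropped with a warning before scaling. Returns the sample -> cluster
    map (labels 1..k by decreasing size for determinism of downstream
    comparisons) and the scipy linkage matrix.
    """
    if comp_subset.shape[0] < 3:
        raise ValueError("need >= 3 samples to cluster")
    X = comp_subset.astype(float).copy()
    logged = {}
    for col in X.columns:
        v = X[col]
        nz = v[v > 0]
        f = floor if floor is not None else (float(nz.min() / 2.0) if len(nz) else 1.0)
        logged[col] = np.log10(v.where(v > 0, f))
    L = pd.DataFrame(logged)
    sd = L.std(ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping constant columns before scaling: {list(constant)}")
        L = L.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (L - L.mean()) / sd
    linkage = hierarchy.linkage(Z.to_numpy(), method="ward")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # relabel clusters by decreasing size, ties by first occurrence
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], list(raw).index(c)))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=comp_subset.index, name="cluster")
    return labels, linkage


def spike_in_validation(
    spiked: ExpressionMatrix,
    ref: ReferenceProfile,
    fractions: Optional[pd.Series] = None,
    groups: Optional[pd.Series] = None,
    monocyte_label: str = "Monocyte",
    min_overlap: int = 100,
) -> Tuple[float, float, pd.DataFrame]:
    """Regress deconvolution-assessed TMC on known spike-in fractions.

    Deconvolves each spiked sample, then fits OLS of estimated TMC on the
    known monocyte mass fraction (with the source biopsy as a fixed effect
    when ``groups`` is given). Returns (slope, p, per-sample table).
    """
    import statsmodels.formula.api as smf

    if fractions is None:
        fractions = spiked.samples["spike_fraction"]
    fractions = fractions.reindex(spiked.sample_ids).astype(float)
    if fractions.nunique() < 2:
        raise ValueError("need >= 2 distinct spike levels")
    if fractions.nunique() < 3:
        warnings.warn("fewer than 3 spike levels; slope estimate is fragile")
    comp = deconvolve_nnls(spiked, ref, min_overlap=min_overlap)
    tmc = extract_tmc(comp, monocyte_label)["tmc"]
    table = pd.DataFrame({"tmc": tmc, "fraction": fractions})
    if groups is not None:
        table["group"] = groups.reindex(spiked.sample_ids).astype(str)
        fit = smf.ols("tmc ~ fraction + C(group)", data=table).fit()
    else:
        fit = smf.ols("tmc ~ fraction", data=table).fit()
    return float(fit.params["fraction"]), float(fit.pvalues["fraction"]), table
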