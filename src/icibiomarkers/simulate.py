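"""Synthetic cohort generator.

Produces every input the downstream pipeline consumes, with known ground
truth: a labeled single-cell reference with negative-binomial counts and
cell-type marker structure; pseudobulk mixtures with known RNA and cell
fractions across purity/infiltration gradients; paired pre-/on-treatment
bulk cohorts with responder-specific upregulation of T/NK markers;
tumor-size changes coupled to that upregulation and to tumor monocyte
content (TMC); and proportional-hazards survival in scaled log10(TMC)
and TMB.

Counts are gamma-Poisson (negative binomial) with variance mu + mu^2/theta.
All randomness flows from ``SimulationConfig.seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig
from .datatypes import ON_TREATMENT, PRETX, ExpressionMatrix, GroundTruth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mu`` and dispersion ``theta``."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-300) / theta)
    return rng.poisson(lam)


def simulate_single_cell_reference(config: SimulationConfig) -> ad.AnnData:
    """Simulate a labeled single-cell atlas (cells x genes AnnData).

    Each cell type boosts its own ``n_markers_per_type`` marker genes by
    ``marker_fold``; one type is malignant, one is the monocyte type (split
    10:1 into classical / non-classical subtypes), one is the T/NK type whose
    markers carry the on-treatment signature in cohort simulations. Per-type
    RNA content spans ``rna_content_range`` and per-cell library sizes vary
    log-normally.
    """
    rng = np.random.default_rng(config.seed)
    types = config.cell_type_names
    n_types, n_genes = len(types), config.n_genes
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]

    base = config.base_mean_scale * rng.lognormal(0.0, config.base_mean_log_sd, size=n_genes)
    marker_of = np.full(n_genes, "", dtype=object)
    marker_blocks = {}
    for k, t in enumerate(types):
        block = np.arange(k * config.n_markers_per_type, (k + 1) * config.n_markers_per_type)
        marker_blocks[t] = block
        marker_of[block] = t

    # per-type RNA content multipliers, malignant cells richest
    content = np.linspace(config.rna_content_range[1], config.rna_content_range[0], n_types)

    X_rows, obs_rows = [], []
    for k, t in enumerate(types):
        mu_type = base.copy()
        mu_type[marker_blocks[t]] *= config.marker_fold
        mu_type *= content[k]
        lib_scale = rng.lognormal(0.0, config.library_size_sigma, size=config.cells_per_type)
        mu_cells = lib_scale[:, None] * mu_type[None, :]
        X_rows.append(_nb_draw(rng, mu_cells, config.nb_dispersion))
        for c in range(config.cells_per_type):
            subtype = t
            if t == config.monocyte_type:
                # 10:1 classical : non-classical, mirroring intratumoral proportions
                subtype = f"{t}_classical" if c % 11 != 10 else f"{t}_nonclassical"
            obs_rows.append(
                {
                    "cell_type": t,
                    "subtype": subtype,
                    "patient": f"REF{(len(obs_rows) % config.n_reference_patients) + 1:02d}",
                    "malignant": t == config.malignant_type,
                }
            )

    X = np.vstack(X_rows)
    obs = pd.DataFrame(obs_rows, index=[f"cell{i + 1:05d}" for i in range(X.shape[0])])
    var = pd.DataFrame({"marker_of": marker_of}, index=pd.Index(genes, name="gene"))
    adata = ad.AnnData(X=X.astype(np.float64), obs=obs, var=var)
    adata.uns["config"] = config.to_dict()
    adata.uns["expected_type_means"] = pd.DataFrame(
        {t: base * np.where(marker_of == t, config.marker_fold, 1.0) * content[k]
         for k, t in enumerate(types)},
        index=genes,
    )
    return adata


def _sample_mixture(
    rng: np.random.Generator,
    ref: ad.AnnData,
    weights: pd.Series,
    n_cells: int,
) -> Tuple[np.ndarray, pd.Series, pd.Series, np.ndarray]:
    """Draw ``n_cells`` cells with type probabilities ``weights`` and sum counts.

    Returns (summed counts, per-type cell counts, per-type RNA mass, sampled
    cell positions).
    """
    types = list(weights.index)
    missing = [t for t in types if t not in set(ref.obs["cell_type"])]
    if missing:
        raise ValueError(f"cell types absent from reference: {missing}")
    counts_per_type = rng.multinomial(n_cells, (weights / weights.sum()).to_numpy())
    X = ref.X
    lib = np.asarray(X.sum(axis=1)).ravel()
    pooled = np.zeros(ref.n_vars)
    cells_taken, mass, all_idx = {}, {}, []
    type_positions = {t: np.flatnonzero((ref.obs["cell_type"] == t).to_numpy()) for t in types}
    for t, n in zip(types, counts_per_type):
        if n == 0:
            cells_taken[t], mass[t] = 0, 0.0
            continue
        idx = rng.choice(type_positions[t], size=n, replace=True)
        pooled += X[idx].sum(axis=0)
        cells_taken[t] = int(n)
        mass[t] = float(lib[idx].sum())
        all_idx.append(idx)
    cell_counts = pd.Series(cells_taken, index=types, dtype=float)
    rna_mass = pd.Series(mass, index=types, dtype=float)
    sampled = np.concatenate(all_idx) if all_idx else np.empty(0, dtype=int)
    return pooled, cell_counts, rna_mass, sampled


def simulate_pseudobulk_panel(
    ref: ad.AnnData,
    n_samples: int,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Build a pseudobulk benchmark panel by pooling known cells.

    Each sample draws a tumor purity from ``purity_range``, splits the
    residual mass over non-malignant types by a Dirichlet draw, samples
    ``cells_per_pseudobulk`` cells multinomially and sums their counts.
    Ground truth records both the RNA-fraction scale (share of counts per
    type) and the cell-fraction scale (share of cells per type).
    """
    if ref.n_obs == 0:
        raise ValueError("reference is empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    types = config.cell_type_names
    non_malig = [t for t in types if t != config.malignant_type]

    cols, rna_rows, cell_rows, sampled = {}, [], [], {}
    for s in range(n_samples):
        name = f"PB{s + 1:03d}"
        purity = rng.uniform(*config.purity_range)
        resid = rng.dirichlet(np.full(len(non_malig), config.dirichlet_concentration))
        weights = pd.Series(0.0, index=types)
        weights[config.malignant_type] = purity
        weights[non_malig] = (1.0 - purity) * resid
        pooled, cell_counts, rna_mass, idx = _sample_mixture(
            rng, ref, weights, config.cells_per_pseudobulk
        )
        cols[name] = pooled
        cell_rows.append(cell_counts / cell_counts.sum())
        rna_rows.append(rna_mass / rna_mass.sum())
        sampled[name] = idx

    values = pd.DataFrame(cols, index=ref.var_names)
    em = ExpressionMatrix(values, scale="counts")
    truth = GroundTruth(
        rna_fractions=pd.DataFrame(rna_rows, index=list(cols)),
        cell_fractions=pd.DataFrame(cell_rows, index=list(cols)),
        sampled_cells=sampled,
    )
    return em, truth


def simulate_cohort(
    config: SimulationConfig,
    ref: ad.AnnData,
) -> Tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate a paired pre-/on-treatment trial cohort with outcomes.

    Per patient: TMC (monocyte share) is logit-normal; TMB log10-normal and
    independent of TMC; the pre-treatment bulk sample is a cell mixture with
    monocyte weight TMC; the on-treatment sample applies a patient-specific
    log2 fold change ``delta`` to the T/NK marker genes (responders:
    Normal(signature_effect_mean, sd); others Normal(0, sd)). Tumor-size
    percent change is linear in ``-delta`` and ``-z(log10 TMC)`` plus noise.
    OS and PFS are exponential with hazard
    ``baseline * exp(-a*z(log10 TMC) - b*z(TMB))``; censoring is independent
    exponential, calibrated to censor about ``censor_rate`` of subjects.
    Response (irRECIST) and clinical-benefit labels are derived through the
    survival module's classification rules.

    Returns (paired expression counts, outcomes table, ground truth).
    """
    from . import survival as surv  # local import: survival does not depend on us

    if config.baseline_hazard <= 0 or config.pfs_baseline_hazard <= 0:
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_patients
    types = config.cell_type_names
    other = [t for t in types if t not in (config.malignant_type, config.monocyte_type)]
    sig_genes = np.flatnonzero((ref.var["marker_of"] == config.tnk_type).to_numpy())

    patients = [f"P{i + 1:03d}" for i in range(n)]
    tmc = expit(rng.normal(config.tmc_logit_mean, config.tmc_logit_sd, size=n))
    tmb = 10 ** rng.normal(config.tmb_log_mean, config.tmb_log_sd, size=n)
    responder = rng.random(n) < config.responder_rate
    delta = np.where(
        responder,
        rng.normal(config.signature_effect_mean, config.signature_effect_sd, size=n),
        rng.normal(0.0, config.signature_effect_sd, size=n),
    )

    def z(x):
        return (x - x.mean()) / x.std(ddof=0)

    z_tmc = z(np.log10(tmc))
    z_tmb = z(tmb)
    size_change = (
        -config.size_effect_delta * delta
        - config.size_effect_tmc * z_tmc
        + rng.normal(0.0, config.size_noise_sd, size=n)
    )

    lin_pred = -config.hazard_coef_tmc * z_tmc - config.hazard_coef_tmb * z_tmb
    os_hazard = config.baseline_hazard * np.exp(lin_pred)
    prog_hazard = config.pfs_baseline_hazard * np.exp(lin_pred)
    os_true = rng.exponential(1.0 / os_hazard)
    pfs_true = np.minimum(rng.exponential(1.0 / prog_hazard), os_true)

    def censor(t_true, baseline):
        # independent exponential censoring calibrated so that roughly
        # censor_rate of subjects are censored for an average patient
        if config.censor_rate == 0:
            return t_true, np.ones(n, dtype=int)
        c_rate = baseline * config.censor_rate / (1.0 - config.censor_rate)
        c = rng.exponential(1.0 / c_rate, size=n)
        t_obs = np.minimum(t_true, c)
        return np.maximum(t_obs, 1e-6), (t_true <= c).astype(int)

    os_time, os_event = censor(os_true, config.baseline_hazard)
    pfs_time, pfs_event = censor(pfs_true, config.pfs_baseline_hazard)
    pfs_time = np.minimum(pfs_time, os_time)
    pfs_event = np.where(pfs_time < os_time, pfs_event, np.maximum(pfs_event, os_event))

    # paired expression
    cols, meta_rows = {}, []
    rna_rows, cell_rows, sampled = [], [], {}
    sample_names = []
    for i, p in enumerate(patients):
        purity = rng.uniform(*config.purity_range) * (1.0 - tmc[i])
        resid = rng.dirichlet(np.full(len(other), config.dirichlet_concentration))
        weights = pd.Series(0.0, index=types)
        weights[config.malignant_type] = purity
        weights[config.monocyte_type] = tmc[i]
        weights[other] = (1.0 - purity - tmc[i]) * resid
        for tp in (PRETX, ON_TREATMENT):
            pooled, cell_counts, rna_mass, idx = _sample_mixture(
                rng, ref, weights, config.cells_per_pseudobulk
            )
            if tp == ON_TREATMENT:
                # responder-specific upregulation of T/NK markers, kept integer
                pooled = pooled.copy()
                pooled[sig_genes] = rng.poisson(pooled[sig_genes] * 2.0 ** delta[i])
            name = f"{p}_{tp}"
            cols[name] = pooled
            sample_names.append(name)
            meta_rows.append({"patient": p, "timepoint": tp, "tissue": "tumor"})
            rna_rows.append(rna_mass / rna_mass.sum())
            cell_rows.append(cell_counts / cell_counts.sum())
            sampled[name] = idx

    values = pd.DataFrame(cols, index=ref.var_names)
    em = ExpressionMatrix(values, pd.DataFrame(meta_rows, index=sample_names), scale="counts")

    irrecist, resp_flag = [], []
    for i in range(n):
        cat, is_resp = surv.classify_response([size_change[i]])
        irrecist.append(cat)
        resp_flag.append(is_resp)
    cb = surv.classify_cb(pd.Series(pfs_time, index=patients), pd.Series(pfs_event, index=patients))

    outcomes = pd.DataFrame(
        {
            "patient": patients,
            "irrecist": irrecist,
            "responder": resp_flag,
            "cb": cb.values,
            "size_change_pct": size_change,
            "os_time": os_time,
            "os_event": os_event,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "tmb": tmb,
            "msi_score": rng.gamma(1.0, 0.8, size=n),
        }
    ).set_index("patient")

    truth = GroundTruth(
        rna_fractions=pd.DataFrame(rna_rows, index=sample_names),
        cell_fractions=pd.DataFrame(cell_rows, index=sample_names),
        sampled_cells=sampled,
        patients=pd.DataFrame(
            {
                "responder_true": responder,
                "delta": delta,
                "tmc": tmc,
                "tmb": tmb,
                "z_log10_tmc": z_tmc,
                "z_tmb": z_tmb,
                "os_hazard": os_hazard,
            },
            index=patients,
        ),
    )
    return em, outcomes, truth


def blend_monocyte_profile(
    classical: pd.Series, nonclassical: pd.Series, ratio: float = 10.0
) -> pd.Series:
    """Blend monocyte subtype profiles ``ratio``:1 (classical:non-classical) by RNA mass."""
    if not classical.index.equals(nonclassical.index):
        raise ValueError("subtype profiles must share the same gene index")
    c = classical / classical.sum()
    nc = nonclassical / nonclassical.sum()
    return (ratio * c + nc) / (ratio + 1.0)


def simulate_spike_in(
    bulk_profile: pd.Series,
    monocyte_profile: pd.Series,
    fractions: Sequence[float],
) -> ExpressionMatrix:
    """Spike monocyte RNA into a bulk profile at given mass fractions.

    Column ``f`` is ``(1-f)*bulk + f*monocyte`` on the linear scale with the
    bulk sample's total RNA mass preserved, mirroring a wet-lab spike-in of
    sorted monocyte RNA at 0-8% of total mass.
    """
    if not bulk_profile.index.equals(monocyte_profile.index):
        raise ValueError("bulk and monocyte profiles must share the same gene index")
    fractions = list(fractions)
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    total = float(bulk_profile.sum())
    mono_scaled = monocyte_profile / monocyte_profile.sum() * total
    cols = {
        f"spike_{f:g}": (1.0 - f) * bulk_profile + f * mono_scaled for f in fractions
    }
    values = pd.DataFrame(cols, index=bulk_profile.index)
    samples = pd.DataFrame({"spike_fraction": fractions}, index=list(cols))
    return ExpressionMatrix(values, samples, scale="linear")
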