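"""Simulation configuration.

The defaults encode the cohort conditions the pipeline is designed around:
a ~38-patient esophageal adenocarcinoma trial with a four-week ICI-only
window, monocyte fractions in the low percent range, TMB of a few
nonsynonymous coding mutations per megabase, and proportional-hazards
survival effects of scaled log10 tumor monocyte content (TMC) and TMB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic single-cell reference, pseudobulk panel and cohort.

    Notes on defaults
    -----------------
    * ``hazard_coef_tmc``/``hazard_coef_tmb`` are log-hazard effects per SD of
      log10(TMC) and TMB; 0.97 and 0.69 correspond to hazard ratios of 0.38
      and 0.50 for a one-SD increase.
    * ``baseline_hazard`` 0.05/month and ``pfs_baseline_hazard`` 0.076/month
      put median OS near 13.9 months and median PFS near 9.1 months for an
      average patient.
    * ``tmb_log_mean``/``sd`` are on the log10 scale (mutations/Mb).
    """

    # --- single-cell reference ---
    n_genes: int = 2000
    n_cell_types: int = 6
    n_markers_per_type: int = 40
    marker_fold: float = 8.0
    nb_dispersion: float = 2.0           # theta; variance = mu + mu^2/theta
    cells_per_type: int = 200
    n_reference_patients: int = 8
    base_mean_log_sd: float = 1.0        # lognormal spread of baseline gene means
    base_mean_scale: float = 2.0         # mean expression per gene before markers
    library_size_sigma: float = 0.35     # lognormal sd of per-cell library scaling
    rna_content_range: Tuple[float, float] = (0.6, 1.8)  # per-type RNA content span
    malignant_type: str = "EAC"
    monocyte_type: str = "Monocyte"
    tnk_type: str = "T_NK"

    # --- pseudobulk panel ---
    cells_per_pseudobulk: int = 500
    purity_range: Tuple[float, float] = (0.2, 0.9)
    dirichlet_concentration: float = 1.0

    # --- cohort ---
    n_patients: int = 38
    responder_rate: float = 0.45
    signature_effect_mean: float = 1.0   # delta_resp, log2 scale
    signature_effect_sd: float = 0.4
    tmc_logit_mean: float = -2.5
    tmc_logit_sd: float = 1.0
    tmb_log_mean: float = 0.5            # log10 muts/Mb
    tmb_log_sd: float = 0.4
    size_effect_delta: float = 25.0      # % tumor-size change per log2 unit of delta
    size_effect_tmc: float = 10.0        # % change per SD of log10 TMC
    size_noise_sd: float = 15.0          # % points
    hazard_coef_tmc: float = 0.97        # a: protective effect of scaled log10 TMC
    hazard_coef_tmb: float = 0.69        # b: protective effect of scaled TMB
    baseline_hazard: float = 0.05        # OS events per month
    pfs_baseline_hazard: float = 0.076   # PFS events per month
    censor_rate: float = 0.2

    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_cell_types", "n_markers_per_type", "cells_per_type",
                     "cells_per_pseudobulk", "n_patients", "n_reference_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("purity_range must be an ordered sub-interval of [0, 1]")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must be in [0, 1]")
        for name in ("marker_fold", "nb_dispersion", "baseline_hazard", "pfs_baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cell_types * self.n_markers_per_type > self.n_genes:
            raise ValueError(
                "n_cell_types * n_markers_per_type exceeds n_genes: "
                f"{self.n_cell_types} * {self.n_markers_per_type} > {self.n_genes}"
            )
        if self.n_cell_types < 3:
            raise ValueError("need at least 3 cell types (malignant, monocyte, T/NK)")

    @property
    def cell_type_names(self) -> list:
        base = [self.malignant_type, self.monocyte_type, self.tnk_type,
                "Fibroblast", "B_cell", "Neutrophil", "Squamous_epithelium", "Macrophage"]
        if self.n_cell_types <= len(base):
            return base[: self.n_cell_types]
        return base + [f"Type_{i}" for i in range(len(base), self.n_cell_types)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["purity_range"] = list(self.purity_range)
        d["rna_content_range"] = list(self.rna_content_range)
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("purity_range", "rna_content_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def replace(self, **kwargs) -> "SimulationConfig":
        d = asdict(self)
        d.update(kwargs)
        return SimulationConfig(**d)
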