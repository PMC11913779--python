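"""Plain-text readers and writers for the pipeline's tabular formats.

Expression travels as TSV (genes x samples) or sparse MatrixMarket triples
(matrix.mtx + genes.tsv + barcodes.tsv) for single-cell data; metadata,
truth, outcome and result tables as TSV; configs as YAML. Simulation runs
are emitted under a run directory with a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import ExpressionMatrix


def read_expression_tsv(path, metadata: Optional[str] = None, scale: str = "counts") -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    samples = pd.read_csv(metadata, sep="\t", index_col=0) if metadata else None
    return ExpressionMatrix(values, samples, scale)


def write_expression_tsv(em: ExpressionMatrix, path, metadata: Optional[str] = None) -> None:
    em.values.to_csv(path, sep="\t")
    if metadata:
        em.samples.to_csv(metadata, sep="\t")


def read_single_cell_mtx(matrix, genes, barcodes, labels: Optional[str] = None) -> ad.AnnData:
    """Read a cells x genes sparse triple (+ optional per-cell label TSV)."""
    X = spio.mmread(matrix).tocsr()
    var = pd.read_csv(genes, sep="\t", index_col=0)
    obs = pd.read_csv(barcodes, sep="\t", index_col=0)
    if labels:
        lab = pd.read_csv(labels, sep="\t", index_col=0)
        obs = obs.join(lab)
    return ad.AnnData(X=np.asarray(X.todense(), dtype=float), obs=obs, var=var)


def write_single_cell_mtx(adata: ad.AnnData, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(np.asarray(adata.X)))
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    adata.obs.to_csv(outdir / "barcodes.tsv", sep="\t")


def read_mutation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})


def read_outcomes_tsv(path) -> pd.DataFrame:
    """Clinical outcome table: patient-indexed, time/event (+ covariate) columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_manifest(outdir, entries: dict) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(entries, indent=2, default=str))
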