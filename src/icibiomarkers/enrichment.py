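"""Preranked gene-set enrichment with a gene-permutation null.

The enrichment score (ES) is the extreme deviation of the weighted
Kolmogorov-Smirnov running sum over a ranking: genes in the set increment
the sum proportionally to |stat|^weight (normalized over set hits), genes
outside decrement it by 1/(N - |S|). Significance comes from random gene
sets of the same size drawn from the ranked universe; the permutation p is

    p = (1 + #{null ES of the same sign with |ES_null| >= |ES|})
        / (1 + #{null ES of the same sign})

and NES = ES / mean(|same-sign null ES|), following the original GSEA
normalization with separate positive/negative null pools. The smallest
attainable p is therefore 1/(n_perm + 1). BH correction is applied across
the tested sets.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .diffexp import benjamini_hochberg


def correlation_ranking(changes: pd.DataFrame, outcome: pd.Series) -> pd.Series:
    """Rank genes by Pearson correlation with a per-patient outcome.

    ``changes`` is genes x patients (e.g. on-treatment minus pre-treatment
    log expression); the returned Series is sorted descending with
    lexicographic tie-break and carries the correlation as the statistic.
    Constant gene rows get r = 0 with a warning.
    """
    y = outcome.reindex(changes.columns).to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 patients for a correlation ranking")
    X = changes.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    constant = denom == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene rows; correlation set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(constant, 0.0, Xc @ yc / np.where(denom == 0, 1.0, denom))
    s = pd.Series(r, index=changes.index)
    order = np.lexsort((s.index, -s.to_numpy()))
    return s.iloc[order]


def enrichment_score(stats: np.ndarray, hit_mask: np.ndarray, weight: float = 1.0) -> float:
    """ES of a set (``hit_mask``) against a descending-ordered statistic vector."""
    n = len(stats)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("set must be a proper, non-empty subset of the ranking")
    w = np.abs(stats) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit statistics are zero; fall back to unweighted
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - np.where(hit_mask, 0.0, 1.0 / (n - n_hits)))
    i_max, i_min = running.argmax(), running.argmin()
    return float(running[i_max]) if abs(running[i_max]) >= abs(running[i_min]) else float(running[i_min])


def _leading_edge(stats, genes, hit_mask, weight, es) -> list:
    n = len(stats)
    n_hits = int(hit_mask.sum())
    w = np.abs(stats) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum() or float(n_hits)
    running = np.cumsum(hit_w / total - np.where(hit_mask, 0.0, 1.0 / (n - n_hits)))
    if es >= 0:
        cut = int(running.argmax())
        idx = np.flatnonzero(hit_mask[: cut + 1])
    else:
        cut = int(running.argmin())
        idx = np.flatnonzero(hit_mask[cut + 1:]) + cut + 1
    return [genes[i] for i in idx]


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: Dict[str, Sequence[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 2,
    max_size: int = 500,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    ``ranking`` maps genes to a real statistic; it is sorted descending
    internally (stable, lexicographic tie-break). Sets are intersected with
    the ranking; those outside [min_size, max_size] or with an empty
    intersection are skipped and reported in ``result.attrs['skipped']``.
    """
    s = ranking.copy()
    order = np.lexsort((s.index, -s.to_numpy(dtype=float)))
    s = s.iloc[order]
    stats = s.to_numpy(dtype=float)
    genes = list(s.index)
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows, skipped = [], {}
    for name, members in gene_sets.items():
        hits = sorted({pos[g] for g in members if g in pos})
        if not hits:
            skipped[name] = "empty intersection with ranking"
            continue
        if not (min_size <= len(hits) <= max_size):
            skipped[name] = f"size {len(hits)} outside [{min_size}, {max_size}]"
            continue
        mask = np.zeros(n, dtype=bool)
        mask[hits] = True
        es = enrichment_score(stats, mask, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_mask = np.zeros(n, dtype=bool)
            perm_mask[rng.choice(n, size=len(hits), replace=False)] = True
            null[b] = enrichment_score(stats, perm_mask, weight)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        p = (1.0 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1.0 + n_same)
        nes = es / np.abs(null[same_sign]).mean() if n_same else np.nan
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "pvalue": min(p, 1.0),
                "size": len(hits),
                "leading_edge": _leading_edge(stats, genes, mask, weight, es),
            }
        )

    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["es", "nes", "pvalue", "size", "leading_edge"]
    )
    if len(out):
        out["fdr"] = benjamini_hochberg(out["pvalue"])
    out.attrs["skipped"] = skipped
    out.attrs["n_perm"] = n_perm
    return out


def read_gmt(path) -> Dict[str, list]:
    """Read a GMT gene-set collection (set name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Dict[str, Sequence[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
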