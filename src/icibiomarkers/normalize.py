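"""Count normalization by the median-of-ratios method.

Size factor for sample j = median over genes of count_gj / (geometric mean of
gene g across samples), restricted to genes with no zero count in any sample
(the geometric-mean reference is undefined for them). The log-normalized
("VST"-scale) output is log2(count / size_factor + 1); the linear scale is
count / size_factor, used for deconvolution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import ExpressionMatrix


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for median-of-ratios normalization.

    Operates on genes x samples DataFrames (the orientation bulk RNA-seq
    tools use). ``fit`` estimates per-sample size factors; ``transform``
    divides by them and optionally applies log2(x + 1).

    Parameters
    ----------
    output
        ``"log"`` for log2(normalized + 1), ``"linear"`` for normalized counts.
    """

    def __init__(self, output: str = "log"):
        self.output = output

    def fit(self, X: pd.DataFrame, y=None):
        counts = X.to_numpy(dtype=float)
        if counts.shape[1] < 2:
            raise ValueError("need at least 2 samples to estimate size factors")
        all_positive = (counts > 0).all(axis=1)
        if not all_positive.any():
            raise ValueError(
                "every gene contains a zero count; no gene is usable for the "
                "geometric-mean reference — consider a pseudo-reference variant"
            )
        ref = np.exp(np.log(counts[all_positive]).mean(axis=1))
        ratios = counts[all_positive] / ref[:, None]
        self.size_factors_ = pd.Series(np.median(ratios, axis=0), index=X.columns)
        self.n_reference_genes_ = int(all_positive.sum())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        norm = X / self.size_factors_
        if self.output == "log":
            return np.log2(norm + 1.0)
        if self.output == "linear":
            return norm
        raise ValueError(f"unknown output scale {self.output!r}")


def size_factors(em: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors for a count matrix."""
    return MedianOfRatiosNormalizer().fit(em.values).size_factors_


def _normalize(em: ExpressionMatrix, output: str) -> ExpressionMatrix:
    if em.scale != "counts":
        raise ValueError(f"expected counts, got scale {em.scale!r}")
    norm = MedianOfRatiosNormalizer(output=output)
    values = norm.fit(em.values).transform(em.values)
    out = ExpressionMatrix(values, em.samples.copy(), "log" if output == "log" else "linear")
    out.samples.attrs["size_factors"] = norm.size_factors_
    return out


def normalize_log(em: ExpressionMatrix) -> ExpressionMatrix:
    """log2(median-of-ratios normalized + 1), the scale used for scoring and DE."""
    return _normalize(em, "log")


def normalize_linear(em: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios normalized counts on the linear scale (deconvolution input)."""
    return _normalize(em, "linear")
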