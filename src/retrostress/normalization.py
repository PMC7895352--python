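"""The normalization chain: counts-per-million, pedestal by 2, log2, quantile.

Each sample's counts are scaled to a library of 10^6 (cpm), a pedestal of 2
is added before the log2 transform (so a zero count maps to exactly 1.0),
and the samples are then quantile-normalized so that every column shares the
same empirical distribution (the cross-sample mean of order statistics).
After the full chain every value is >= 1 and within-column ranks are
preserved (ties may merge, never invert).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "cpm",
    "pedestal_log2",
    "quantile_normalize",
    "normalize",
]


@dataclass
class NormalizedMatrix:
    """Real-valued expression matrix plus the ordered list of applied steps."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: value[i,j] = counts[i,j] * 1e6 / colsum(j)."""
    df = counts.counts.astype(float)
    libsizes = df.sum(axis=0)
    if (libsizes <= 0).any():
        bad = list(libsizes.index[libsizes <= 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    return df * (1e6 / libsizes)


def pedestal_log2(x: pd.DataFrame, pedestal: float = 2.0) -> pd.DataFrame:
    """log2(x + pedestal); requires x + pedestal > 0 everywhere."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr + pedestal <= 0):
        raise ValueError("x + pedestal must be positive everywhere")
    return pd.DataFrame(np.log2(arr + pedestal), index=x.index, columns=x.columns)


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns; ties get the mean of their tied-rank
    reference values."""
    n, m = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(x, order, axis=0)
    reference = sorted_vals.mean(axis=1)  # mean order statistic per rank

    out = np.empty_like(x, dtype=float)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        ref = reference.copy()
        # average the reference values over runs of tied input values
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    ref[start:i] = ref[start:i].mean()
                start = i
        out[order[:, j], j] = ref
    return out


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share one distribution (mean order statistics).

    For each rank r the cross-column mean of the r-th order statistics is
    computed; each value is replaced by the reference value at its
    within-column rank, with ties receiving the mean of the tied-rank
    reference values.  Idempotent, and rank-preserving within columns.
    """
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("matrix contains non-finite values")
    return pd.DataFrame(
        _quantile_normalize_array(arr), index=x.index, columns=x.columns
    )


def normalize(counts: CountMatrix, pedestal: float = 2.0) -> NormalizedMatrix:
    """Full chain: quantile_normalize(log2(cpm + pedestal))."""
    values = quantile_normalize(pedestal_log2(cpm(counts), pedestal))
    return NormalizedMatrix(
        values=values,
        provenance=["cpm", f"pedestal_log2(pedestal={pedestal:g})", "quantile_normalize"],
    )
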