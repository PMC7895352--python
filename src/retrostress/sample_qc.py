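"""Sample-level QC on the normalized matrix.

Three read-only checks, mirroring the usual visual triage of bulk expression
data: Tukey box-plot fences on per-sample medians, a sample-by-sample
Pearson correlation matrix with a low-correlation flag, and covariance-based
PCA of the samples.  Flags are advisory; nothing is removed automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import NormalizedMatrix

__all__ = ["QcReport", "boxplot_outliers", "correlation_matrix", "pca_covariance", "run_qc"]


@dataclass
class QcReport:
    box_stats: pd.DataFrame          # per sample: q1, median, q3, lo_fence, hi_fence
    correlations: pd.DataFrame       # sample x sample Pearson r
    pca_scores: pd.DataFrame         # per sample: PC1, PC2
    explained_variance: np.ndarray   # fractions, non-increasing
    flagged_samples: list[tuple[str, str]]  # (sample, reason)


def _values(norm) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedMatrix) else norm


def boxplot_outliers(norm, k: float = 1.5) -> tuple[pd.DataFrame, list[str]]:
    """Flag samples whose median expression falls outside the Tukey fences
    of the distribution of sample medians."""
    x = _values(norm)
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples for box-plot outlier flagging")
    medians = x.median(axis=0)
    q1, q3 = medians.quantile(0.25), medians.quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    stats = pd.DataFrame(
        {
            "q1": x.quantile(0.25, axis=0),
            "median": medians,
            "q3": x.quantile(0.75, axis=0),
            "lo_fence": lo,
            "hi_fence": hi,
        }
    )
    flagged = [s for s in x.columns if medians[s] < lo or medians[s] > hi]
    return stats, flagged


def correlation_matrix(
    norm, mad_factor: float = 3.0, abs_floor: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson r between samples; flag samples whose mean
    correlation with all others is either below (median - mad_factor*MAD) of
    the mean-correlation distribution or below an absolute floor."""
    x = _values(norm)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = list(x.columns[sd == 0])
        raise ValueError(f"constant column(s), correlation undefined: {bad}")
    r = x.corr(method="pearson")
    n = r.shape[0]
    mean_r = (r.sum(axis=1) - 1.0) / (n - 1)
    med = mean_r.median()
    mad = (mean_r - med).abs().median()
    cutoff = med - mad_factor * mad
    flagged = [s for s in r.index if mean_r[s] < cutoff or mean_r[s] < abs_floor]
    return r, flagged


def pca_covariance(norm, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariance-based PCA: samples as observations, features as variables,
    features centered but not scaled.  Axis signs are fixed by making the
    largest-magnitude feature loading of each component positive."""
    x = _values(norm)
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples for PCA")
    # observations x variables
    data = x.to_numpy().T
    centered = data - data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    k = min(n_components, scores.shape[1])
    score_df = pd.DataFrame(
        scores[:, :k], index=x.columns, columns=[f"PC{i+1}" for i in range(k)]
    )
    return score_df, explained


def run_qc(norm, mad_factor: float = 3.0, abs_floor: float = 0.5) -> QcReport:
    box_stats, box_flags = boxplot_outliers(norm)
    corr, corr_flags = correlation_matrix(norm, mad_factor=mad_factor, abs_floor=abs_floor)
    scores, explained = pca_covariance(norm)
    flagged = [(s, "median outside Tukey fences") for s in box_flags]
    flagged += [(s, "low mean correlation") for s in corr_flags]
    return QcReport(
        box_stats=box_stats,
        correlations=corr,
        pca_scores=scores,
        explained_variance=explained,
        flagged_samples=flagged,
    )
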