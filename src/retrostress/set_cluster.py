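"""Cross-comparison summaries of DE calls and heatmap clustering order.

Venn region counts and direction concordance for two call sets, union-set
construction, and agglomerative clustering of the union-set expression
matrix (rows and columns) for heatmap ordering.  Default distance/linkage
(Euclidean, complete) mirror the defaults of the heatmap.2-style clustered
heatmap; a correlation-based distance (1 - Pearson r) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = ["VennSummary", "ClusterOrder", "venn", "union_set", "cluster_heatmap_order"]


@dataclass
class VennSummary:
    label_a: str
    label_b: str
    only_a: int
    only_b: int
    intersection: int
    concordant: int
    discordant: int

    @property
    def size_a(self) -> int:
        return self.only_a + self.intersection

    @property
    def size_b(self) -> int:
        return self.only_b + self.intersection

    @property
    def union(self) -> int:
        return self.only_a + self.only_b + self.intersection


@dataclass
class ClusterOrder:
    feature_order: list[str]
    sample_order: list[str]
    feature_linkage: np.ndarray
    sample_linkage: np.ndarray
    metric: str
    method: str


def _as_direction_map(calls) -> dict[str, str]:
    """Accept a DECallSet, a dict {feature: direction} or an iterable of
    (feature, direction) pairs."""
    if hasattr(calls, "as_set"):
        return calls.as_set()
    if isinstance(calls, dict):
        return dict(calls)
    out: dict[str, str] = {}
    for feature, direction in calls:
        if feature in out:
            raise ValueError(f"duplicate feature within one set: {feature!r}")
        out[feature] = direction
    return out


def venn(calls_a, calls_b, label_a: str = "A", label_b: str = "B") -> VennSummary:
    """Region counts (A-only, B-only, A∩B) and direction concordance."""
    a = _as_direction_map(calls_a)
    b = _as_direction_map(calls_b)
    inter = set(a) & set(b)
    concordant = sum(1 for f in inter if a[f] == b[f])
    return VennSummary(
        label_a=label_a,
        label_b=label_b,
        only_a=len(set(a) - inter),
        only_b=len(set(b) - inter),
        intersection=len(inter),
        concordant=concordant,
        discordant=len(inter) - concordant,
    )


def union_set(*call_sets) -> list[str]:
    """Deduplicated union in stable first-seen order."""
    if not call_sets:
        raise ValueError("need at least one call set")
    seen: dict[str, None] = {}
    for cs in call_sets:
        features = cs.calls.index if hasattr(cs, "calls") else cs
        for f in features:
            seen.setdefault(f, None)
    return list(seen)


def cluster_heatmap_order(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> ClusterOrder:
    """Hierarchical-clustering order of rows (features) and columns (samples).

    metric: 'euclidean' or 'correlation' (1 - Pearson r); method: any scipy
    linkage method.  Leaf order is deterministic; ties resolve by input
    order (scipy's stable behaviour for equal merge heights).
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("matrix contains NaN")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 features and >= 2 samples")

    def _linkage(data: np.ndarray) -> np.ndarray:
        if metric == "correlation":
            d = pdist(data, metric="correlation")
        elif metric == "euclidean":
            d = pdist(data, metric="euclidean")
        else:
            raise ValueError(f"unsupported metric: {metric!r}")
        # guard tiny negative distances from roundoff
        d = np.maximum(d, 0)
        return linkage(d, method=method)

    feat_link = _linkage(matrix.to_numpy(dtype=float))
    samp_link = _linkage(matrix.to_numpy(dtype=float).T)
    return ClusterOrder(
        feature_order=[matrix.index[i] for i in leaves_list(feat_link)],
        sample_order=[matrix.columns[i] for i in leaves_list(samp_link)],
        feature_linkage=feat_link,
        sample_linkage=samp_link,
        metric=metric,
        method=method,
    )
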