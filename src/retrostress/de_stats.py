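"""Differential-expression cascade: one-way ANOVA, BH FDR, Tukey HSD, fold change.

Each feature is tested across all sample groups with a one-factor ANOVA;
p-values are Benjamini-Hochberg adjusted across features; features passing
the FDR gate are post-hoc tested per requested pair of groups with Tukey's
HSD (studentized-range distribution on the pooled within-group mean
square); a pair is called differentially expressed when additionally the
linear fold change of the (log2-scale) group means is at least ``fc_min``.

ANOVA and BH are implemented here, vectorized across the feature matrix;
the studentized-range survival function comes from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SampleDesign

__all__ = [
    "DEResult",
    "DECallSet",
    "anova_oneway",
    "anova_oneway_matrix",
    "bh_adjust",
    "tukey_hsd",
    "fold_change",
    "call_de",
]


@dataclass
class DECallSet:
    """Features called differentially expressed for one pairwise comparison."""

    comparison: str                  # e.g. "THP1_5_vs_THP1_0"
    calls: pd.DataFrame              # index feature; columns direction, fc, delta, q, tukey_p

    def as_set(self) -> dict[str, str]:
        return dict(zip(self.calls.index, self.calls["direction"]))


@dataclass
class DEResult:
    table: pd.DataFrame              # per-feature statistics
    call_sets: dict[str, DECallSet]
    alpha: float
    alpha_post: float
    fc_min: float


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float, bool]:
    """One-way fixed-effects ANOVA for a single feature.

    Returns (F, p, degenerate).  All-identical observations are flagged
    degenerate with F = 0, p = 1.
    """
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    allv = np.concatenate(groups)
    n = allv.size
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within == 0 and ss_between == 0:
        return 0.0, 1.0, True
    if ss_within == 0:
        return np.inf, 0.0, False
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p, False


def anova_oneway_matrix(
    x: pd.DataFrame, design: SampleDesign
) -> pd.DataFrame:
    """Vectorized one-way ANOVA of every feature (row) across design groups.

    Returns a DataFrame with group means, F, p, MS_within, df_within and a
    degenerate flag."""
    groups = design.groups
    k = len(groups)
    cols = {}
    n_total = 0
    ss_between = np.zeros(len(x))
    ss_within = np.zeros(len(x))
    grand_sum = np.zeros(len(x))
    arrs = {}
    for g, samples in groups.items():
        a = x[samples].to_numpy(dtype=float)
        arrs[g] = a
        cols[f"mean_{g}"] = a.mean(axis=1)
        grand_sum += a.sum(axis=1)
        n_total += a.shape[1]
    grand_mean = grand_sum / n_total
    for g, a in arrs.items():
        m = a.mean(axis=1)
        ss_between += a.shape[1] * (m - grand_mean) ** 2
        ss_within += ((a - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    degenerate = (ss_within == 0) & (ss_between == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f = np.where(degenerate, 0.0, f)
    p = np.where(
        np.isinf(f), 0.0, stats.f.sf(np.where(np.isfinite(f), f, 1.0), df_b, df_w)
    )
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame(cols, index=x.index)
    out["F"] = f
    out["p"] = p
    out["ms_within"] = ss_within / df_w
    out["df_within"] = df_w
    out["degenerate"] = degenerate
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def tukey_hsd(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """All-pairs Tukey HSD for one feature.

    q-statistic per pair a,b: |mean_a - mean_b| / sqrt(MS_within/2 *
    (1/n_a + 1/n_b)) with p from the studentized range distribution
    (k groups, N-k df; Tukey-Kramer for unequal n).
    """
    k = len(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = sum(len(g) for g in groups)
    df_w = n - k
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    rows = []
    for (ia, a), (ib, b) in combinations(enumerate(groups), 2):
        delta = a.mean() - b.mean()
        if ms_within == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            q = abs(delta) / np.sqrt(
                ms_within / 2 * (1 / len(a) + 1 / len(b))
            )
            p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append((labels[ia], labels[ib], delta, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "delta", "p"])


def _tukey_p_pair(
    delta: np.ndarray, ms_within: np.ndarray, n_a: int, n_b: int, k: int, df_w: int
) -> np.ndarray:
    """Vector of Tukey p-values for one fixed pair across many features."""
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(delta) / np.sqrt(ms_within / 2 * (1 / n_a + 1 / n_b))
    p = np.ones_like(q)
    ok = np.isfinite(q) & (q > 0)
    if ok.any():
        p[ok] = stats.studentized_range.sf(q[ok], k, df_w)
    p[np.isinf(q)] = 0.0
    return p


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Linear fold change of log2-scale means: FC = 2^|a-b|; direction 'up'
    when the first (treated) mean exceeds the second."""
    delta = mean_a - mean_b
    return float(2 ** abs(delta)), ("up" if delta > 0 else "down")


def call_de(
    x: pd.DataFrame,
    design: SampleDesign,
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
    alpha_post: float = 0.05,
    fc_min: float = 1.5,
) -> DEResult:
    """Full cascade on a (filtered) log2 expression matrix.

    comparisons: list of (treated_group, control_group) pairs; direction is
    the sign of mean(treated) - mean(control).  Tukey p-values are computed
    only for features passing the BH gate (the post-hoc step of the
    cascade).
    """
    for a, b in comparisons:
        for g in (a, b):
            if g not in design.groups:
                raise ValueError(f"unknown group in comparison: {g!r}")
    table = anova_oneway_matrix(x, design)
    table["q"] = bh_adjust(table["p"].to_numpy())
    pass_fdr = table["q"].to_numpy() < alpha

    k = len(design.groups)
    df_w = int(table["df_within"].iloc[0]) if len(table) else 0
    ms_within = table["ms_within"].to_numpy()

    call_sets: dict[str, DECallSet] = {}
    for a, b in comparisons:
        label = f"{a}_vs_{b}"
        delta = (table[f"mean_{a}"] - table[f"mean_{b}"]).to_numpy()
        tukey_p = np.full(len(table), np.nan)
        if pass_fdr.any():
            tukey_p[pass_fdr] = _tukey_p_pair(
                delta[pass_fdr],
                ms_within[pass_fdr],
                len(design.groups[a]),
                len(design.groups[b]),
                k,
                df_w,
            )
        fc = 2 ** np.abs(delta)
        called = pass_fdr & (tukey_p < alpha_post) & (fc >= fc_min)
        table[f"delta_{label}"] = delta
        table[f"fc_{label}"] = fc
        table[f"tukey_p_{label}"] = tukey_p
        table[f"called_{label}"] = called
        calls = pd.DataFrame(
            {
                "direction": np.where(delta > 0, "up", "down")[called],
                "fc": fc[called],
                "delta": delta[called],
                "q": table["q"].to_numpy()[called],
                "tukey_p": tukey_p[called],
            },
            index=table.index[called],
        )
        call_sets[label] = DECallSet(comparison=label, calls=calls)

    return DEResult(
        table=table, call_sets=call_sets, alpha=alpha, alpha_post=alpha_post,
        fc_min=fc_min,
    )
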