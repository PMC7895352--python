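"""Noise-floor detection from the CV ~ mean relation, and discard/floor filtering.

For each sample group the per-feature coefficient of variation (CV, sample
SD over mean of the normalized log2 values) is smoothed against the
per-feature mean with a robust lowess.  In the well-measured regime CV
declines roughly linearly with the mean; below the noise floor shot noise
and overdispersion push CV above that trend.  The point where the fitted
curve "grossly" departs from the linear trend is taken as the group's noise
breakpoint; per-group breakpoints are combined — by default their minimum,
the lowest mean at which any fit loses linearity — into one threshold.  Features that never exceed the threshold
in any sample are discarded as noise-biased; surviving values below the
threshold are floored to exactly the threshold.

The departure rule is made operational as: fit an OLS line to the lowess
curve over the high-mean region (default the top half of the observed mean
range), measure the RMS residual s of the curve about that line inside the
region, and scan the grid from high to low mean for the first run of at
least ``persistence`` consecutive grid points whose absolute deviation from
the line exceeds both ``tau * s`` and a relative floor (``rel_floor`` times
the line's local value); the breakpoint is the highest mean in that run.
If no such run exists the breakpoint falls back to the minimum observed
mean (no filtering).

The relative floor is what makes "grossly" operational: the lowess curve
is far smoother than the scatter it summarizes, so its residual about the
reference line can be orders of magnitude below any departure a reader
would call gross; a departure must therefore also be a non-trivial
fraction of the local trend value itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .data_model import SampleDesign
from .normalization import NormalizedMatrix

__all__ = [
    "NoiseParams",
    "GroupNoiseFit",
    "NoiseModel",
    "FilterOutcome",
    "cv_mean_profile",
    "fit_lowess",
    "detect_breakpoint",
    "apply_noise_filter",
    "build_noise_model",
]


@dataclass(frozen=True)
class NoiseParams:
    """Tunables of the noise-floor procedure.

    span: lowess smoothing fraction; iterations: robustifying iterations;
    gridsize: evaluation grid; fit_fraction: top fraction of the mean range
    used for the linear reference fit; tau: deviation multiplier on the RMS
    residual; rel_floor: minimum departure as a fraction of the local
    linear-trend value; persistence: minimum run length (grid points) of
    deviation; combine: reduction of per-group breakpoints into one
    threshold.
    """

    span: float = 0.3
    iterations: int = 3
    gridsize: int = 512
    fit_fraction: float = 0.5
    tau: float = 3.0
    rel_floor: float = 0.05
    persistence: int = 5
    combine: str = "min"  # min | mean | max


@dataclass
class GroupNoiseFit:
    group: str
    points: pd.DataFrame          # per feature: mean, cv
    grid: np.ndarray              # mean values (gridsize,)
    curve: np.ndarray             # fitted CV on the grid
    line_slope: float
    line_intercept: float
    fit_region: tuple[float, float]
    residual_scale: float         # RMS residual s of curve about line in region
    breakpoint: float


@dataclass
class NoiseModel:
    group_fits: dict[str, GroupNoiseFit]
    combined_threshold: float
    params: NoiseParams = field(default_factory=NoiseParams)

    def breakpoints(self) -> dict[str, float]:
        return {g: f.breakpoint for g, f in self.group_fits.items()}


@dataclass
class FilterOutcome:
    kept: pd.DataFrame            # values possibly floored
    discarded: list[str]          # feature ids never exceeding the threshold
    floored_cells: int
    threshold: float


def cv_mean_profile(norm, design: SampleDesign) -> dict[str, pd.DataFrame]:
    """Per group: per-feature arithmetic mean and CV (n-1 SD / mean).

    Assumes normalized values >= 1 (the chain guarantees it), so means are
    positive and CV is well defined.
    """
    x = norm.values if isinstance(norm, NormalizedMatrix) else norm
    out: dict[str, pd.DataFrame] = {}
    for group, samples in design.groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        sub = x[samples]
        mean = sub.mean(axis=1)
        if (mean <= 0).any():
            raise ValueError("non-positive feature mean; CV undefined")
        cv = sub.std(axis=1, ddof=1) / mean
        out[group] = pd.DataFrame({"mean": mean, "cv": cv})
    return out


def fit_lowess(
    points: pd.DataFrame, params: NoiseParams = NoiseParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Robust lowess of CV on mean, evaluated on a uniform grid over the
    observed mean range."""
    if len(points) < 10:
        raise ValueError("need >= 10 (mean, CV) points for lowess")
    x = points["mean"].to_numpy(dtype=float)
    y = points["cv"].to_numpy(dtype=float)
    grid = np.linspace(x.min(), x.max(), params.gridsize)
    # delta collapses near-duplicate x for speed; harmless at our densities
    delta = 0.002 * (x.max() - x.min())
    fitted = sm_lowess(y, x, frac=params.span, it=params.iterations, delta=delta,
                       return_sorted=True)
    curve = np.interp(grid, fitted[:, 0], fitted[:, 1])
    return grid, curve


def detect_breakpoint(
    grid: np.ndarray, curve: np.ndarray, params: NoiseParams = NoiseParams()
) -> tuple[float, dict]:
    """Mean value at which the CV curve departs from its high-mean line.

    Returns (breakpoint, diagnostics).  Falls back to the minimum observed
    mean (with a warning for a degenerate flat curve) when no persistent
    departure exists.
    """
    grid = np.asarray(grid, dtype=float)
    curve = np.asarray(curve, dtype=float)
    lo, hi = grid[0], grid[-1]
    region_lo = hi - params.fit_fraction * (hi - lo)
    in_region = grid >= region_lo
    gx, gy = grid[in_region], curve[in_region]

    diag: dict = {"fit_region": (float(region_lo), float(hi))}
    if np.ptp(curve) == 0 or gx.size < 2:
        warnings.warn("degenerate CV curve; breakpoint set to minimum mean")
        diag.update(slope=0.0, intercept=float(curve[0]) if curve.size else 0.0,
                    residual_scale=0.0)
        return float(lo), diag

    slope, intercept = np.polyfit(gx, gy, 1)
    resid = gy - (slope * gx + intercept)
    s = float(np.sqrt(np.mean(resid**2)))
    diag.update(slope=float(slope), intercept=float(intercept), residual_scale=s)

    line = slope * grid + intercept
    deviation = np.abs(curve - line)
    bar = np.maximum(params.tau * s, params.rel_floor * np.abs(line))
    exceeding = deviation > bar

    r = params.persistence
    breakpoint_idx = None
    # scan from high to low mean for a run of >= r consecutive exceedances
    run = 0
    for i in range(grid.size - 1, -1, -1):
        if exceeding[i]:
            run += 1
            if run >= r:
                # highest mean of this run
                breakpoint_idx = i + r - 1
                break
        else:
            run = 0
    if breakpoint_idx is None:
        return float(lo), diag
    return float(grid[breakpoint_idx]), diag


def _fit_group(group: str, points: pd.DataFrame, params: NoiseParams) -> GroupNoiseFit:
    grid, curve = fit_lowess(points, params)
    bp, diag = detect_breakpoint(grid, curve, params)
    return GroupNoiseFit(
        group=group,
        points=points,
        grid=grid,
        curve=curve,
        line_slope=diag["slope"],
        line_intercept=diag["intercept"],
        fit_region=diag["fit_region"],
        residual_scale=diag["residual_scale"],
        breakpoint=bp,
    )


def build_noise_model(
    norm, design: SampleDesign, params: NoiseParams = NoiseParams()
) -> NoiseModel:
    """Fit the CV~mean lowess per group, detect per-group breakpoints, and
    combine them into one threshold."""
    profiles = cv_mean_profile(norm, design)
    fits = {g: _fit_group(g, pts, params) for g, pts in profiles.items()}
    bps = np.array([f.breakpoint for f in fits.values()])
    if params.combine == "max":
        threshold = float(bps.max())
    elif params.combine == "min":
        threshold = float(bps.min())
    elif params.combine == "mean":
        threshold = float(bps.mean())
    else:
        raise ValueError(f"unknown combine rule: {params.combine!r}")
    return NoiseModel(group_fits=fits, combined_threshold=threshold, params=params)


def apply_noise_filter(norm, threshold: float) -> FilterOutcome:
    """Discard features never exceeding the threshold; floor surviving
    sub-threshold values to exactly the threshold."""
    x = norm.values if isinstance(norm, NormalizedMatrix) else norm
    exceeds = (x > threshold).any(axis=1)
    kept = x.loc[exceeds].copy()
    discarded = list(x.index[~exceeds])
    below = kept < threshold
    floored_cells = int(below.to_numpy().sum())
    kept = kept.mask(below, threshold)
    return FilterOutcome(
        kept=kept, discarded=discarded, floored_cells=floored_cells,
        threshold=float(threshold),
    )
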