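"""qPCR quantification arithmetic.

ΔΔCt relative expression against a reference gene (assumed doubling per
cycle), reference-gene stability ranking (median |ΔCq| plus paired
Wilcoxon), primer-efficiency estimation from a dilution series with the
100 ± 10 % acceptance window, the no-reverse-transcriptase contamination
check, RIP percent-of-input, strand-specific sense/antisense ratios, and
volcano tables for PCR arrays.

Cq values are quantification cycles; an undetermined Cq (no amplification
within the run) is represented explicitly as ``None``/NaN, never as a
sentinel number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqRecord",
    "QpcrResult",
    "EfficiencyFit",
    "collapse_replicates",
    "ddct_fold",
    "reference_stability",
    "efficiency_from_titration",
    "no_rt_check",
    "bound_input_ratio",
    "strand_ratio",
    "volcano_table",
]

#: slope of a perfect doubling reaction, Cq ~ log10(amount)
PERFECT_SLOPE = -1.0 / math.log10(2.0)


@dataclass(frozen=True)
class CqRecord:
    sample_id: str
    condition: str
    target: str
    replicate: int
    cq: float | None            # None = undetermined
    strand: str = "n/a"          # sense | antisense | n/a
    rt_minus: bool = False

    def __post_init__(self) -> None:
        if self.cq is not None and not (self.cq > 0):
            raise ValueError("determined Cq must be positive")


@dataclass
class QpcrResult:
    target: str
    reference: str
    dct_control: float
    dct_treated: float
    ddct: float
    fold: float


@dataclass
class EfficiencyFit:
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    passes: bool


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    return df


def collapse_replicates(records) -> pd.DataFrame:
    """Mean Cq (and replicate SD) per (sample, condition, target, strand,
    rt_minus); undetermined replicates are excluded with a warning, a group
    that is entirely undetermined yields NaN."""
    df = _records_frame(records)
    keys = ["sample_id", "condition", "target", "strand", "rt_minus"]
    n_undet = int(df["cq"].isna().sum())
    if n_undet:
        warnings.warn(f"excluding {n_undet} undetermined Cq replicate(s)")
    out = (
        df.groupby(keys, dropna=False)["cq"]
        .agg(
            mean_cq="mean",
            sd_cq=lambda v: v.std(ddof=1) if v.notna().sum() > 1 else 0.0,
            n_determined=lambda v: int(v.notna().sum()),
            n_total="size",
        )
        .reset_index()
    )
    out["single_replicate"] = out["n_determined"] == 1
    return out


def ddct_fold(
    target_cq: dict[str, float],
    reference_cq: dict[str, float],
    treated: str,
    control: str,
    target: str = "target",
    reference: str = "reference",
    efficiency_target: float = 1.0,
    efficiency_reference: float = 1.0,
) -> QpcrResult:
    """ΔΔCt fold change: ΔCt_c = Cq_target,c - Cq_ref,c per condition c;
    ΔΔCt = ΔCt_treated - ΔCt_control; fold = 2^(-ΔΔCt).

    With non-default efficiencies the efficiency-corrected (Pfaffl-style)
    ratio is returned instead:
    fold = (1+E_t)^(Cq_t,control - Cq_t,treated)
         / (1+E_r)^(Cq_r,control - Cq_r,treated),
    which reduces to 2^(-ΔΔCt) at E = 1.  The plain form is the default
    because primers are gated on the 100 ± 10 % titration window.
    """
    for label, d in (("target", target_cq), ("reference", reference_cq)):
        for cond in (treated, control):
            v = d.get(cond)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"undetermined {label} Cq for condition {cond!r}")
    dct_t = target_cq[treated] - reference_cq[treated]
    dct_c = target_cq[control] - reference_cq[control]
    ddct = dct_t - dct_c
    fold = (1.0 + efficiency_target) ** (target_cq[control] - target_cq[treated]) / (
        (1.0 + efficiency_reference) ** (reference_cq[control] - reference_cq[treated])
    )
    return QpcrResult(
        target=target,
        reference=reference,
        dct_control=dct_c,
        dct_treated=dct_t,
        ddct=ddct,
        fold=fold,
    )


def reference_stability(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate reference genes by stability between two conditions.

    cq_table: long format with columns gene, pair_id, cq_exposed,
    cq_control — one row per biological pair.  Per gene: median |ΔCq|,
    exact paired Wilcoxon signed-rank p (two-sided), rank by median |ΔCq|
    ascending, stable flag when p > 0.05.
    """
    required = {"gene", "pair_id", "cq_exposed", "cq_control"}
    if not required <= set(cq_table.columns):
        raise ValueError(f"need columns {sorted(required)}")
    rows = []
    for gene, sub in cq_table.groupby("gene", sort=True):
        if sub["pair_id"].duplicated().any() or sub[["cq_exposed", "cq_control"]].isna().any().any():
            raise ValueError(f"unpaired or incomplete data for gene {gene!r}")
        d = (sub["cq_exposed"] - sub["cq_control"]).to_numpy(dtype=float)
        if d.size < 5:
            raise ValueError("need >= 5 pairs for the signed-rank test")
        if np.all(d == 0):
            p = 1.0
        else:
            p = float(
                stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
            )
        rows.append((gene, float(np.median(np.abs(d))), p))
    out = pd.DataFrame(rows, columns=["gene", "median_abs_dcq", "wilcoxon_p"])
    out = out.sort_values(
        ["median_abs_dcq", "gene"], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["stable"] = out["wilcoxon_p"] > 0.05
    return out


def efficiency_from_titration(series) -> EfficiencyFit:
    """Least-squares Cq ~ log10(template amount); efficiency percent
    E = (10^(-1/slope) - 1) * 100; pass iff 90 <= E <= 110."""
    pts = [(float(a), float(c)) for a, c in series]
    amounts = np.array([a for a, _ in pts])
    cqs = np.array([c for _, c in pts])
    if np.unique(amounts).size < 3:
        raise ValueError("need >= 3 distinct template amounts")
    if np.any(amounts <= 0):
        raise ValueError("amounts must be positive")
    logs = np.log10(amounts)
    if logs.max() - logs.min() < 2.0:
        raise ValueError("dilution series must span >= 2 log10 units")
    slope, intercept, r, _, _ = stats.linregress(logs, cqs)
    eff = (10 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r**2),
        efficiency_percent=float(eff),
        passes=bool(90.0 <= eff <= 110.0),
    )


def no_rt_check(
    cq_with_rt: float, cq_without_rt: float | None, margin: float = 5.0
) -> bool:
    """Genomic-DNA contamination check: pass when the no-RT control is
    undetermined or at least ``margin`` cycles later than the +RT reaction
    (boundary counts as pass)."""
    if cq_with_rt is None or math.isnan(cq_with_rt):
        raise ValueError("Cq with RT must be determined")
    if cq_without_rt is None or (
        isinstance(cq_without_rt, float) and math.isnan(cq_without_rt)
    ):
        return True
    return (cq_without_rt - cq_with_rt) >= margin


def bound_input_ratio(
    cq_bound: float, cq_input: float, input_fraction: float = 0.001
) -> float:
    """RIP enrichment as percent of input.

    The input aliquot measures only ``input_fraction`` of the total RNA, so
    its Cq is first shifted by log2(input_fraction) (scaling it up to 100 %);
    percent = 100 * 2^(adjusted_input_cq - cq_bound)."""
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    for v in (cq_bound, cq_input):
        if v is None or math.isnan(v):
            raise ValueError("both Cq values must be determined")
    adjusted = cq_input + math.log2(input_fraction)
    return 100.0 * 2.0 ** (adjusted - cq_bound)


def strand_ratio(
    cq_sense: float, cq_antisense: float, amplicon_sense: str | None = None,
    amplicon_antisense: str | None = None,
) -> float:
    """Antisense/sense abundance ratio = 2^(Cq_sense - Cq_antisense).

    Valid when both strand-specific assays target the same amplicon with
    matched efficiency (shared reference terms cancel)."""
    if amplicon_sense is not None and amplicon_sense != amplicon_antisense:
        raise ValueError(
            f"mismatched amplicons: {amplicon_sense!r} vs {amplicon_antisense!r}"
        )
    return 2.0 ** (cq_sense - cq_antisense)


def volcano_table(
    table: pd.DataFrame, p_max: float = 0.05, fold_min: float = 2.0
) -> pd.DataFrame:
    """Annotate (fold, p) per gene with log2 fold, -log10 p and a strict
    significance flag (p < p_max AND fold > fold_min)."""
    required = {"gene", "fold", "p"}
    if not required <= set(table.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if (table["p"] <= 0).any():
        raise ValueError("p-values must be positive")
    out = table.copy()
    out["log2_fold"] = np.log2(out["fold"].astype(float))
    out["neg_log10_p"] = -np.log10(out["p"].astype(float))
    out["significant"] = (out["p"] < p_max) & (out["fold"] > fold_min)
    return out
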