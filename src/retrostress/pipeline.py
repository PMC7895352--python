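"""End-to-end orchestration: simulate/ingest -> normalize -> QC -> noise
filter -> DE cascade -> cross-comparison summaries.

One call, one config, deterministic under the seed.  Each stage's artifact
is kept on the result object so analysis drivers and tests can inspect any
intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data_model import CountMatrix, SampleDesign
from .de_stats import DEResult, call_de
from .noise_filter import FilterOutcome, NoiseModel, NoiseParams, apply_noise_filter, build_noise_model
from .normalization import NormalizedMatrix, normalize
from .sample_qc import QcReport, run_qc
from .set_cluster import ClusterOrder, VennSummary, cluster_heatmap_order, union_set, venn
from .simulate import SimConfig, generate_counts

__all__ = ["PipelineResult", "run_pipeline", "default_comparisons"]


def default_comparisons(design: SampleDesign) -> list[tuple[str, str]]:
    """Irradiated vs control within each cell type, e.g. (THP1_5, THP1_0)."""
    tbl = design.table
    pairs = []
    for cell_type in tbl["cell_type"].unique():
        sub = tbl[tbl["cell_type"] == cell_type]
        doses = sorted(sub["dose_Gy"].astype(float).unique())
        if len(doses) >= 2:
            control, treated = doses[0], doses[-1]
            g = lambda d: sub[sub["dose_Gy"].astype(float) == d]["group"].iloc[0]
            pairs.append((g(treated), g(control)))
    return pairs


@dataclass
class PipelineResult:
    counts: CountMatrix
    design: SampleDesign
    truth: pd.DataFrame | None
    normalized: NormalizedMatrix
    qc: QcReport
    noise_model: NoiseModel
    filtered: FilterOutcome
    de: DEResult
    venn: VennSummary | None
    union_features: list[str]
    cluster_order: ClusterOrder | None = None


def run_pipeline(
    config: SimConfig | None = None,
    counts: CountMatrix | None = None,
    design: SampleDesign | None = None,
    seed: int | None = None,
    noise_params: NoiseParams = NoiseParams(),
    alpha: float = 0.05,
    alpha_post: float = 0.05,
    fc_min: float = 1.5,
    comparisons: list[tuple[str, str]] | None = None,
    cluster: bool = True,
) -> PipelineResult:
    """Run the whole analysis from a simulation config or an ingested
    counts/design pair."""
    truth = None
    if counts is None:
        config = config or SimConfig()
        counts, design, truth = generate_counts(config, seed=seed)
    if design is None:
        raise ValueError("a SampleDesign is required with explicit counts")
    design.check_against(counts)

    norm = normalize(counts)
    qc = run_qc(norm)
    noise_model = build_noise_model(norm, design, noise_params)
    filtered = apply_noise_filter(norm, noise_model.combined_threshold)
    comparisons = comparisons or default_comparisons(design)
    de = call_de(
        filtered.kept, design, comparisons,
        alpha=alpha, alpha_post=alpha_post, fc_min=fc_min,
    )

    labels = list(de.call_sets)
    venn_summary = None
    if len(labels) == 2:
        venn_summary = venn(
            de.call_sets[labels[0]], de.call_sets[labels[1]],
            label_a=labels[0], label_b=labels[1],
        )
    union_features = union_set(*de.call_sets.values()) if labels else []

    order = None
    if cluster and len(union_features) >= 2:
        order = cluster_heatmap_order(filtered.kept.loc[union_features])

    return PipelineResult(
        counts=counts,
        design=design,
        truth=truth,
        normalized=norm,
        qc=qc,
        noise_model=noise_model,
        filtered=filtered,
        de=de,
        venn=venn_summary,
        union_features=union_features,
        cluster_order=order,
    )
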