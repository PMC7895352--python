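#!/usr/bin/env python
"""Normalize the count matrix (cpm -> +2 pedestal -> log2 -> quantile) and
run the three sample-QC checks: Tukey box fences on sample medians, Pearson
correlation, covariance-based PCA.

Reads results/data/counts.tsv + design.tsv; writes normalized.tsv,
qc_box.tsv, qc_correlations.tsv, qc_pca.tsv.
"""

from pathlib import Path

import retrostress as rs

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts = rs.read_counts(BASE / "data" / "counts.tsv")
    design = rs.read_design(BASE / "data" / "design.tsv")
    design.check_against(counts)

    norm = rs.normalize(counts)
    norm.values.rename_axis("feature").to_csv(BASE / "normalized.tsv", sep="\t")

    report = rs.run_qc(norm)
    report.box_stats.rename_axis("sample").to_csv(BASE / "qc_box.tsv", sep="\t")
    report.correlations.rename_axis("sample").to_csv(
        BASE / "qc_correlations.tsv", sep="\t"
    )
    report.pca_scores.rename_axis("sample").to_csv(BASE / "qc_pca.tsv", sep="\t")

    print(f"normalization chain: {' -> '.join(norm.provenance)}")
    print(f"  value range: {norm.values.min().min():.3f} .. {norm.values.max().max():.3f}")
    off = report.correlations.to_numpy()
    off = off[off < 1 - 1e-12]
    print(f"  sample correlations: min {off.min():.4f}, median {float(__import__('numpy').median(off)):.4f}")
    print(f"  PC1/PC2 explained variance: {report.explained_variance[:2].round(3)}")
    if report.flagged_samples:
        print(f"  advisory flags: {report.flagged_samples}")
    else:
        print("  no outliers detected")


if __name__ == "__main__":
    main()
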