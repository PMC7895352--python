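# retrostress

Pipeline for calling differentially expressed retroelements and genes from
bulk RNA-seq count matrices of irradiated monocytes/macrophages, plus the
qPCR quantification arithmetic and sequence screens used to validate such
calls.

## The problem

Ionizing radiation de-represses transposable elements and endogenous
retroviruses (HERVs) in human monocytes (THP1) and monocyte-derived
macrophages (MDMs). Detecting this from RNA-seq means testing thousands of
gene *and* TE features (TE features named `name:family:class`, TEcount
style) across a small design — typically 3 cell-line replicates and 4
donors, each at 0 and 5 Gy — where low-expression features are dominated by
counting noise. `retrostress` implements that analysis as a tested,
reusable pipeline, together with a synthetic-data generator that emulates
the study design with known ground truth, so every stage can be verified by
parameter recovery.

## The procedure

Starting from an integer count matrix `K` (features × samples) and a sample
design with groups g = cell type × dose:

1. **Normalize**: `x = quantile_normalize(log2(cpm(K) + 2))`. Counts per
   million, a pedestal of 2 (so a zero count maps to exactly 1.0), log2,
   then quantile normalization (each value replaced by the cross-sample
   mean order statistic at its within-column rank; ties averaged).
2. **QC** (advisory): Tukey box-plot fences on sample medians, sample ×
   sample Pearson correlation, covariance-based PCA.
3. **Noise floor**: per group, the coefficient of variation
   CVᵢ = sᵢ/x̄ᵢ of each feature is smoothed against its mean x̄ᵢ with a
   robust lowess. In the well-measured regime CV declines ~linearly with
   the mean; below the noise floor shot noise lifts it off that trend. The
   breakpoint where the fitted curve departs "grossly" from the high-mean
   linear reference (deviation > max(τ·s, 5% of trend), sustained over ≥ 5
   grid points) is the group's noise threshold; the lowest across groups is
   the data's threshold T. Features with all values < T are discarded;
   surviving values < T are floored to T.
4. **DE cascade**: one-factor ANOVA across all groups per feature →
   Benjamini–Hochberg FDR across features (q < 0.05) → Tukey HSD post hoc
   on each requested pair (p < 0.05, studentized-range distribution on the
   pooled within-group mean square) → linear fold change FC = 2^|Δ| ≥ 1.5,
   where Δ is the log2 group-mean difference. A feature is called DE for a
   pair iff it passes all three, with direction sign(Δ).
5. **Summaries**: Venn region counts with direction concordance across
   comparisons; union-set hierarchical clustering (Euclidean/complete by
   default) for heatmap ordering.

qPCR arithmetic: ΔΔCt relative expression `fold = 2^-(ΔCt_treated −
ΔCt_control)` against a reference gene; reference-gene stability ranking
(median |ΔCq| + exact paired Wilcoxon); titration efficiency
`E = (10^(−1/slope) − 1)·100` with the 100 ± 10 % window; no-RT
contamination margin; RIP percent-of-input with dilution adjustment;
strand-specific sense/antisense ratios; volcano tables (p < 0.05,
fold > 2, strict).

Sequence screens: Hamming-distance scan for windows complementary to an
shRNA guide (substitutions only), and least-variable-window selection on a
multiple alignment (per-column entropy + gap penalty) for primer design.

## Worked example

```python
import retrostress as rs

result = rs.run_pipeline(rs.SimConfig(), seed=1)
print({g: round(b, 3) for g, b in result.noise_model.breakpoints().items()})
print(round(result.noise_model.combined_threshold, 3))
print(len(result.filtered.discarded), "discarded")
```

prints (seed 1):

```
{'MDM_0': 2.931, 'MDM_5': 2.879, 'THP1_0': 5.778, 'THP1_5': 2.978}
2.879
5901 discarded
```

The generator planted its noise regime below a log2-mean elbow of 3.0; the
detector recovers a threshold of 2.88, discarding 98.3 % of the planted
noise features while retaining 100 % of the signal features (the THP1_0
fit illustrates why the threshold is the *lowest* breakpoint across fits:
single groups can lose linearity spuriously in sparse high-mean regions).
On the constant-dispersion DE benchmark (`rs.de_benchmark_config()`,
20 000 features, 100 planted 4-fold TEs, NB dispersion 0.05) the full
cascade recovers 92 % of planted DE TEs at 1.1 % empirical FDR, and calls
nothing on a null simulation.

The same steps as a file-based analysis, each writing its tables under
`results/`:

```bash
python analysis/01_simulate_counts.py      # counts.tsv, design.tsv, truth.tsv
python analysis/02_normalize_qc.py         # normalized.tsv, qc_*.tsv
python analysis/03_noise_floor.py          # noise_model.json, filtered.tsv
python analysis/04_differential_expression.py  # de_results.tsv, calls_*.tsv
python analysis/05_venn_heatmap.py         # venn_summary.tsv, cluster_order.json
python analysis/06_qpcr_validation.py      # qpcr_*.tsv
python analysis/07_offtarget_screen.py     # offtarget_hits.tsv, conserved_window.tsv
```

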