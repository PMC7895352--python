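# Methods

## Scope and data model

The pipeline operates on an integer feature × sample count matrix in which
gene features carry plain ids and transposable-element features carry
`name:family:class` ids (the convention of TE-aware counters; anything not
matching exactly three non-empty colon-separated tokens is treated as a
gene). The sample design assigns each sample a cell type, a dose in Gy and
a replicate/donor id; the analysis factor is the cell type × dose group.
The default design mirrors a radiation study on human monocytes and
macrophages: THP1 at 0 and 5 Gy with 3 biological replicates each, and
MDMs from 4 donors at both doses (14 samples, 4 groups). Group labels are
`THP1_0`, `THP1_5`, `MDM_0`, `MDM_5`. Read alignment and TE counting are
out of scope; the pipeline starts at the count matrix.

## Normalization

`normalize()` applies, in order: counts per million (each column scaled to
10⁶), a pedestal of +2, log2, quantile normalization. Consequences relied
on downstream: every value ≥ 1 (zero count ↦ log2(2) = 1), within-column
ranks preserved, and all columns share the reference distribution (the
cross-column mean order statistics). Ties within a column receive the mean
of their tied-rank reference values — the deterministic, symmetric rule.
With integer counts, tie patterns differ between columns, so sorted column
vectors agree exactly only at ranks untied everywhere; within tie blocks
each column carries the block mean of the reference. Quantile
normalization under this rule is idempotent to machine precision.

Genes and TEs are analyzed as one joint matrix (they are counted into one
table and compete for the same library mass), and quantile normalization
is performed jointly across all samples rather than within cell type: the
normalization's job here is to erase sample-level distributional
differences before a single cross-group test, and a within-group variant
would reintroduce group/distribution confounding. Subsetting to TE-only
or gene-only features via the annotations is supported downstream.

## Sample QC

Three advisory checks (no sample is ever removed automatically):

* Tukey fences on sample medians: a sample is flagged when its median
  expression falls outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the
  distribution of sample medians. After quantile normalization all column
  distributions are identical, so this can only fire on data QC'd before
  normalization or with alternative chains.
* Pearson correlation: a sample is flagged when its mean correlation with
  the others falls below median − 3·MAD of the mean-correlation
  distribution or below an absolute floor (0.5). On clean replicate data
  the MAD is of order 10⁻³, so the 3·MAD arm is intrinsically
  hair-triggered; its flags are advisory by design and the absolute floor
  is the substantive check.
* Covariance-based PCA: samples as observations, features centered but not
  scaled, scores by SVD. Axis signs are fixed by making each component's
  largest-magnitude loading positive.

## Noise floor

Per group with n ≥ 2 replicates, each feature contributes (mean, CV) on
the normalized log2 scale (CV = n−1 SD / mean). The scatter is smoothed
with a robust lowess (tricube weights, span 0.3, 3 robustifying
iterations, evaluated on a 512-point grid over the observed mean range;
statsmodels implementation with a small `delta` for speed).

Departure from linearity is made operational as follows: an OLS line is
fit to the lowess *curve* over the top half of the mean range; `s` is the
RMS residual of the curve about that line inside the region; scanning the
grid from high to low mean, the breakpoint is the top of the first run of
≥ 5 consecutive grid points whose |curve − line| exceeds **both** τ·s
(τ = 3) and 5 % of the local line value. The relative floor is the
operationalization of "grossly": the lowess curve is orders of magnitude
smoother than the scatter it summarizes, so τ·s alone (≈ 10⁻⁴ on real
fits) would fire on negligible wiggles far above any real noise floor. On
idealized curves that are exactly linear above an elbow, the relative
floor changes nothing. If no persistent departure exists the breakpoint
falls back to the minimum observed mean (no filtering). All parameters
live in `NoiseParams`.

Per-group breakpoints are combined by their **minimum** by default — the
lowest mean at which any fit loses linearity. The maximum and mean are
available; the minimum is also the robust choice in practice, because a
single group's lowess can lose linearity spuriously in sparse high-mean
regions, and a max-combined threshold then discards real signal wholesale.

Filtering: a feature is kept iff at least one sample exceeds the
threshold; kept values below the threshold are floored to exactly the
threshold. The operation is idempotent and the kept-set size is
non-increasing in the threshold.

## Differential expression

One-factor ANOVA across all groups (vectorized across features; degenerate
all-identical features get F = 0, p = 1 and are never called), BH step-up
FDR across features, and for features with q < α (0.05) a Tukey HSD post
hoc per requested pair: q-statistic |Δ|/√(MS_within/2 · (1/n_a + 1/n_b)),
p from the studentized range distribution with k groups and N − k df
(scipy; the Tukey–Kramer form for unequal n). Computing Tukey p only for
BH survivors is both the stated cascade and a practical necessity
(studentized-range survival evaluations are expensive). The fold gate uses
FC = 2^|Δ| of log2-scale group means — the ratio of geometric means on the
original scale — with FC ≥ 1.5 and direction sign(Δ). The ANOVA spans all
sample groups jointly (one factor with four levels in the default design);
the post-hoc step then examines the specific pairs of interest. Default
comparisons: irradiated vs control within each cell type.

ANOVA and BH are cross-checked in the tests against scipy's `f_oneway`, an
explicit 10 000-shuffle permutation null, the classical F = t² identity,
and statsmodels' `fdr_bh`; Tukey is checked against `scipy.stats.tukey_hsd`,
the k = 2 identity with ANOVA, and a null-calibration test (the family-wise
p of each feature's widest pair is uniform under the null).

## Set summaries and clustering

Venn region counts for two call sets with direction concordance inside the
intersection; union sets deduplicated in first-seen order. Heatmap
ordering by agglomerative clustering of rows and columns (Euclidean
distance, complete linkage by default, correlation distance 1 − r as an
alternative), leaf order deterministic with ties resolved by input order.
The tested artifact is the ordering and merge trees; rendering is an
optional by-product of the analysis scripts.

## qPCR arithmetic

* ΔΔCt: ΔCt_c = Cq_target,c − Cq_ref,c; fold = 2^−(ΔCt_treated −
  ΔCt_control). Amplification is assumed exactly 2 per cycle, justified by
  gating primers on the titration window below; all fold/ratio operations
  are invariant to adding a constant to every Cq.
* Replicates collapse by arithmetic mean; undetermined Cq values are
  explicit (never sentinel numbers) and excluded with a warning.
* Reference-gene stability: per candidate gene, median |ΔCq| between
  paired exposed/control measurements and an exact two-sided Wilcoxon
  signed-rank p (≥ 5 pairs); ranked by median |ΔCq|, "stable" when
  p > 0.05. Six same-signed pairs give p = 2/64 = 0.03125 exactly.
* Titration: least squares Cq ~ log10(amount) over ≥ 3 amounts spanning
  ≥ 2 decades; E = (10^(−1/slope) − 1)·100, accepted in [90, 110].
* No-RT check: pass iff the −RT control is undetermined or ≥ 5 cycles
  later than +RT (boundary passes).
* RIP percent-of-input: the input aliquot measures fraction f of total
  RNA, so its Cq is shifted by log2 f before comparison; percent =
  100·2^(Cq_input + log2 f − Cq_bound). A larger measured fraction implies
  less total RNA and hence a larger percent for fixed Cq values.
* Strand ratios: antisense/sense = 2^(Cq_sense − Cq_antisense), valid for
  strand-tagged assays on the same amplicon (shared reference cancels).
* Volcano tables flag p < 0.05 and fold > 2.0, both strict.

## Sequence screens

Off-target search: every window of guide length whose subject sequence is
within `max_mismatch` substitutions (Hamming; no indels, no G:U wobble) of
the guide's reverse complement. `N` in the subject always counts as a
mismatch. The implementation is a vectorized sliding-window comparison;
the tests hold it equal to an independent brute-force scan. Conserved
window: per-column Shannon entropy of non-gap residues (nats) plus a gap
penalty (default ln 4, the maximum attainable nucleotide entropy) times
the gap fraction; the window minimizing the sliding mean wins, leftmost on
ties.

## Synthetic data generator

The generator emulates the study structure — not any real dataset — with
every planted quantity recorded in a truth table.

Counts are negative binomial, `NB(μ, φ)` with variance μ + φμ². Structure
is planted on the normalized scale where the pipeline operates: each
feature gets a target normalized mean m = log2(cpm + 2) and a target CV,
and φ is calibrated per feature (and per group, after planted fold
changes) so the realized log2-scale CV matches the target.

* **Signal regime** (67 % of 20 000 features by default): means
  2.7 + |N(0, 1.5)|, target CV on a planted linear trend
  c(m) = 0.20 − 0.012·m. A linear CV~mean decline in the clean regime is
  the situation in which the noise-floor procedure's linear reference is
  well posed; note it implies a log2-scale SD that *grows* with the mean
  (c·m), so power against fixed fold changes falls off at high expression
  — visible in the default pipeline's modest sensitivity.
* **Noise regime** (30 %): means uniform in [1.05, 1.7] with NB dispersion
  additionally floored at 0.3. The default library depth is *derived* so
  that the Poisson (shot-noise) CV floor crosses the planted line exactly
  at the elbow m = 3.0 (≈ 1.4 M counted reads/sample): below the elbow no
  feature can sit on the trend, which is precisely the phenomenon the
  noise-floor detector models. The noise means sit well below the elbow so
  that, at the detected threshold, their across-14-sample maxima stay
  below threshold with high probability — a regime chosen once so that the
  planted labels ("noise", "signal") match what an ideal filter should do.
* **High-expression block** (3 %, genes): absorbs the residual cpm mass so
  that the planted means of the other regimes hold exactly (Σcpm = 10⁶),
  mimicking the handful of dominant transcripts in real total-RNA
  libraries.
* **Differential expression**: 100 TE features (default) multiplied by
  4-fold in irradiated samples, 90 % up / 10 % down, concordant across
  both cell types.
* **Donor variability**: per-donor, per-feature log2-normal effects shared
  across doses within a donor (SD 0.2) for MDM samples. Under the
  CV-calibrated mode the donor variance is carved out of the target
  variance so the planted CV line still holds per group; donors correlate
  the 0/5 Gy MDM samples, which the one-factor ANOVA deliberately ignores
  (as does the procedure it implements).
* **Constant-dispersion mode** (`de_benchmark_config()`): one dispersion
  per regime (0.05 in signal), deeper libraries (5 M), no noise regime —
  the configuration for benchmarking the statistical cascade itself, where
  a flat log-scale variance isolates the tests from the mean-variance
  trend. `null_config()` plants nothing, for false-positive-rate checks.
* **qPCR**: Cq = base − log(quantity)/log(1 + E) + noise. Per-well noise
  (total SD 0.2 by default) is split into a component shared between the
  target and reference wells of one replicate (70 % of variance —
  template/loading error, exactly what reference-gene normalization
  cancels) and a well-specific remainder. With fully independent noise the
  ΔΔCt estimate would carry SD 0.2·√(4/3) ≈ 0.23 log2; the shared
  component is both the physical reality that motivates the ΔΔCt method
  and what makes triplicate fold estimates as tight as practitioners
  observe.
* **Sequences**: random transcripts with planted exact and one-mismatch
  complementary sites (accidental near-complementary windows are scrubbed
  so the manifest is exhaustive), and alignments with one planted
  conserved block, all coordinates recorded.

What the generator does **not** emulate: positional/GC bias, multimapping
ambiguity between TE copies, library-preparation batch effects, non-NB
zero inflation, and real TE-family correlation structure. Passing the
recovery tests therefore shows the procedures are correct and calibrated
under their own assumptions, not that those assumptions hold for any
particular real dataset.

## Numerical choices and degenerate inputs

Double precision throughout; no winsorizing. Quantile-normalization ties:
block means (above). Lowess: `delta` = 0.2 % of the mean range. Breakpoint
detection falls back to "no filtering" on degenerate flat curves, with a
warning. ANOVA with zero within- and between-group variance is flagged
degenerate (p = 1); zero within-group variance with signal gives p = 0.
BH clips at 1. Clustering guards round-off-negative distances at 0.
Undetermined Cq propagates as errors in ΔΔCt (the affected cell is named)
and as a pass in the no-RT check. All simulation entry points take a seed
and are fully deterministic given it.

## Problem sizes

Defaults were chosen at desk scale: 20 000 features × 14 samples for the
count studies, 20-seed sweeps for noise-floor recovery, 1000-run
simulations for qPCR recovery, 100 × 1 kb sequences for the off-target
oracle. The full test suite and the acceptance script each run in about a
minute on one CPU.

## Known limitations

* The noise-floor detector assumes the clean regime's CV~mean relation is
  approximately linear over the upper half of the mean range; strongly
  convex trends (e.g. constant log-scale dispersion, CV ∝ 1/m) shift the
  detected threshold upward. The relative-deviation floor and the
  min-combine rule mitigate but do not remove this.
* Tukey HSD p-values are computed only for BH survivors; the per-feature
  post-hoc p is not multiplicity-corrected across features (by design,
  matching the cascade it implements).
* The DE cascade ignores pairing (donor) structure; with few replicates
  its power against modest fold changes is low, and shrinkage/EB methods
  would do better on real data — they are deliberately out of scope.
* The qPCR arithmetic assumes perfect doubling by default; the
  efficiency-corrected ratio is available but relies on externally
  estimated per-primer efficiencies.
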