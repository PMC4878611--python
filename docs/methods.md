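# Methods

`repbench` implements a replicate-subsampling benchmark for two-condition
RNA-seq differential expression (DE). Its central question is empirical
experiment design: given a DE caller and a fold-change regime of interest,
how many biological replicates are needed before the caller's answer stops
changing? The package answers it by treating a caller's result on the *full*
replicate set as that caller's own reference truth, then measuring how
faithfully subsamples of the replicates reproduce it.

## Gold standards and the bootstrap subselection benchmark

For a gene × sample integer count matrix with conditions A and B, a caller
produces per-gene raw p-values; Benjamini–Hochberg (BH) adjustment is applied
over the defined p-values and a gene is "significantly differentially
expressed" (SDE) when its adjusted p ≤ α (default 0.05). The **gold
standard** for a caller is its SDE set on the full clean matrix.

A **bootstrap run** draws, *i* times (default 100), n_r replicates per
condition without replacement, re-runs the caller on each submatrix (size
factors recomputed per submatrix, since each subselection is an independent
experiment), and records the per-iteration SDE calls. Per iteration and per
fold-change threshold T, genes are restricted to the **threshold universe**
{g : |reference log2FC(g)| ≥ T} and cross-tabulated against the gold
standard: TP (SDE in both), FP (run only), FN (gold only), TN (neither).
Rates come from the mean counts across iterations:

    TPR = TP/(TP+FN),  FPR = FP/(FP+TN),  TNR = TN/(TN+FP),  FNR = FN/(FN+TP)

with standard deviations propagated from the count SDs by the first-order
delta method, neglecting count covariances: for R = a/(a+b),
sd(R) = sqrt((b·sd_a)² + (a·sd_b)²)/(a+b)². A rate with a zero denominator is
reported as missing, never as 0.

Confusion counting is done per iteration and then averaged; the per-gene
representative statistics (mean log2FC across iterations with infinite
values excluded, median adjusted p with the even-count median as midpoint)
are reported separately and are not used for the rate curves.

### Reference fold changes

Thresholding uses a caller-independent yardstick: median-of-ratios size
factors are estimated on the full matrix (reference genes are those with no
zero count in any sample; factors are medians of count/geometric-mean
ratios), counts are divided by their sample's factor, and the reference
log2FC is log2 of the ratio of mean normalized counts, condition 2 over
condition 1 (condition order fixed by the design file and recorded in the
output header). A gene with zero mean in exactly one condition has infinite
|log2FC| and belongs to every threshold universe (it genuinely changed
from/to zero); a gene with zero mean in both conditions carries log2FC 0
with a `both_zero` flag and appears only at T = 0. No pseudocount is added.

One caveat documented deliberately: median-of-ratios equivariance under
scaling a single sample by c is exact only for *relative* factors. The
per-gene geometric mean includes the scaled sample, so all factors pick up a
common c^(1/m); that constant cancels in every downstream ratio.

### Null-split false-positive test

Testing FPR against a tool's own gold standard is circular, so the package
also implements a stronger null test: two *disjoint* groups of n_r samples
are drawn without replacement from a single condition. With no true
expression change between the groups, every SDE call is a false positive.
The per-iteration false-positive fraction is summarised as median, quartiles
and central 95% limits over the iteration sweep (default n_r = 3..20,
i = 100).

### Breakpoint fit

TPR as a function of T typically shows a shallow high-T regime and a steep
low-T regime. `tpr_breakpoint` fits a continuous two-segment piecewise-linear
model by least squares over candidate knots on the T grid (ΔT = 0.1 by
convention, at least two points per segment), returning the knot minimising
total SSE; ties resolve to the smallest T and an all-tied (straight-line)
profile is flagged degenerate.

## The five built-in test statistics

For gene vectors x₁ (n₁ replicates) and x₂ (n₂ replicates):

* **Pooled t**: t = (x̄₁ − x̄₂)/sqrt(s₁₂²(1/n₁ + 1/n₂)) with
  s₁₂² = [(n₁−1)s₁² + (n₂−1)s₂²]/ν, ν = n₁+n₂−2; two-sided p from t_ν.
  Zero pooled variance: t = 0, p = 1 if the means agree, p = 0 otherwise.
* **Log-ratio t** (for log-normal-like data):
  t = (ln x̄₁ − ln x̄₂)/sqrt(s₁²/(n₁x̄₁²) + s₂²/(n₂x̄₂²)), approximately t_ν.
  Requires positive means in both groups; otherwise the result is missing
  (excluded from BH, never SDE), not silently substituted.
* **Mann–Whitney U** with the tie-corrected normal approximation,
  Var(U) = n₁n₂/12 · [(N+1) − Σ(t_k³−t_k)/(N(N−1))], no continuity
  correction (the continuity choice is unstated in the convention this
  follows; omitting it matches the plain large-sample formula).
* **Permutation test** on D = x̄₁ − x̄₂, resampling the pooled vector
  without replacement; p = #{|D*| > |D|}/B (strict inequality). An
  exhaustive mode enumerates all C(N, n₁) splits.
* **Studentized bootstrap test**: both groups are recentred to the pooled
  mean — the implementation of "resampling under the common-mean null"
  chosen here — then resampled with replacement; t* is the pooled t of each
  resample and p = #{|t*| > |t|}/B. A resample with zero pooled variance
  contributes t* = 0.

The strict-inequality resampling p can be exactly 0, which is degenerate
under BH; a `smooth` flag switches to (#+1)/(B+1). The default stays at the
plain fraction for fidelity, and every result file records the choice.
Matrix-path callers share one set of resampling indices across genes: per
gene the null distribution is identical in law to independent sampling, and
it turns a 7000-gene bootstrap into a handful of numpy gathers. Note that
BH is *not* idempotent in general (BH((0.25, 1)) = (0.5, 1) but
BH((0.5, 1)) = (1, 1)); the tests assert the true monotonicity properties
instead.

Built-in callers run on size-factor-normalized counts by default because the
external tools they stand in for normalize internally; `input_scale="raw"`
is available and recorded in every output.

## Concordance clustering with multiscale-bootstrap support

Caller agreement is measured on binary SDE vectors ordered by gene id.
Distance is 1 − Pearson r (range [0, 2]); constant vectors are rejected with
a named error and must be dropped explicitly (the pipeline logs and drops
them). Clustering is complete linkage. Branch support:

* **BP%** — fraction of gene-resampled (with replacement, same size)
  matrices whose clustering contains the branch's leaf set.
* **AU%** — multiscale bootstrap: BP is measured at resample sizes r·G for
  r ∈ {0.5, …, 1.4}; z_r = Φ⁻¹(1 − BP_r) is fit by ordinary least squares to
  v·√r + c/√r, and AU = (1 − Φ(v − c))·100. z is clamped to ±8 so the fit
  stays finite at BP near 0 or 1; saturated branches (BP ≡ 1) clamp to
  AU = 100 and never-recovered branches to AU = 0, both flagged. A row that
  becomes constant inside a bootstrap replicate is tolerated there by
  treating its undefined correlations as 0 (distance 1).

Scales and per-scale B (default 1000; the pipeline default is smaller) are
configuration, not constants.

## The synthetic experiment generator

The generator emulates a deliberately *best-case* experiment: a small,
well-annotated genome, clonal biology, and very tight replicates. Per gene,
baseline mean μ_g ~ log-normal(median 250, log-sd 1.0); NB dispersion
φ_g ~ gamma(shape 10, mean 0.003); a gene is truly DE with probability 0.65,
with |log2FC| ~ exponential(mean 1.0) and random sign applied to condition
2's mean. Per sample, a library-size factor s_j ~ log-uniform(0.7, 1.3)
multiplies the mean (thinning-equivalent, keeping counts integer and
NB-distributed), and counts are NB with var = μ + φμ² (φ = 0 degenerates to
Poisson). One mandatory seed drives everything bitwise-deterministically.

The defaults are frozen calibration values: `scripts/calibrate_generator.py`
sweeps the dispersion mean and reports the three properties the simulation
must reproduce — 7126 genes, all within-condition replicate pairs with
Pearson r > 0.97 on raw counts, and a log-ratio-t gold-standard SDE fraction
in [0.60, 0.75] at 42 replicates. Dispersion means of 0.01–0.02 (between-
replicate CV of 10–14% at high expression) violate both the correlation and
the SDE-fraction targets; 0.003 (CV ≈ 5.5%, plausible for clonal yeast
cultures grown in parallel) satisfies all three with margin across 20 seeds
and is the shipped default.

What the generator does *not* emulate: batch/lane structure (the emulated
design removed it by balanced blocking), bad replicates (a hook exists but
is off), mean-dependent dispersion trends, multi-isoform structure, and
spike-ins. Passing benchmarks here therefore demonstrate correctness of the
machinery and behaviour under near-ideal data, not tool performance on noisy
designs; with per-individual samples or higher biological variation every
power number would be worse.

## Problem sizes used in tests and the acceptance script

The shipped checks run at reduced scale, chosen so each exercises the full
code path with comfortable statistical margins: the null-split check uses
5000 genes, 12 replicates in one condition, n_r = 5, 100 iterations; the
power check uses 5000 genes, 40+40 replicates, a full-matrix gold standard
and 30 bootstrap iterations at n_r = 3; the calibration check runs the full
default 7126 × 84 experiment once. The two headline numbers the acceptance
script reports are the median null-split SDE percentage (expected ≈ 0%,
bounded by 5%) and the TPR for |reference log2FC| ≥ 2 at n_r = 3 (expected
well above 85%: roughly 420 of 5000 genes reach that threshold and their
effect sizes are large relative to the sampling noise of three tight
replicates).

## Numerical and design choices

* Counts are strictly integer; fractional input is rejected, not rounded.
* Missing p-values are excluded from the BH denominator and can never be
  SDE.
* Master seed → per-iteration child seeds via a single `default_rng(seed)`
  integer draw; child seeds are recorded so any iteration reproduces in
  isolation. Pipeline stages derive their seeds by hashing
  `"{seed}:{stage}"`, so adding a stage never shifts another stage's stream.
* The pipeline manifest contains no timestamps; a rerun with the same seed
  is checksum-identical.
* Tie-breaking in the breakpoint fit and linkage follows smallest-index /
  scipy's deterministic order and is documented rather than configurable.
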