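# Methods

This note documents the models, defaults and numerical conventions behind
each `ironsig` module, the design choices that were genuinely open, and what
the synthetic-data generators do and do not emulate.

## Quality control and normalization (`preprocess`)

A cell is retained iff its mitochondrial read fraction is **strictly below
0.20** and its molecule total is **strictly above 1,000**; both bounds are
read as strict inequalities, so a cell at exactly 20 % mito or exactly 1,000
molecules is removed. "Molecules" defaults to the total UMI-like count; a
`molecule_definition="genes"` switch counts distinct detected genes instead,
because the two readings of "RNA molecules detected" are both defensible.
Mitochondrial and ribosomal genes are identified by configurable
gene-symbol prefixes (defaults `mt-`, `Rps`/`Rpl`, mouse casing); matching
is exact and case-sensitive, since mouse and human symbol casing differ and
silent case-folding hides identifier errors. Cells with zero total counts
get a mito fraction of 0 and a degenerate flag rather than NaN.

Normalization is plain library-size log-normalization,
`ln(count·10⁴/total + 1)`. A variance-stabilizing transform with covariate
regression would also be defensible, but the downstream stages (rank-sum
testing, percentile thresholds, graph diffusion) depend only on a monotone,
size-factor-invariant transform, which this is: it maps 0 to 0, is strictly
increasing in the raw count at fixed library size, and is invariant to
scalar multiplication of a cell's counts.

## Differential expression and consensus selection (`signature_derivation`)

**Test.** Two-sided Wilcoxon rank-sum on normalized expression. When
C(n₁+n₂, n₁) ≤ `exact_enumeration_limit` (default 20,000) the p-value is
computed by full enumeration of the group assignments of the pooled
midranks — exact under ties — with the two-sided value defined as twice the
smaller tail mass of the rank-sum distribution, capped at 1. Otherwise a
normal approximation is used with the standard tie correction
(Σ(t³−t)/(n(n−1)) term in the variance) and a 0.5 continuity correction.
The null calibration of this approximation is verified empirically in the
acceptance suite (false-positive rate at α = 0.05 inside the binomial 95 %
band over 20 simulated null datasets).

**Prefilter.** Only genes detected (normalized value > 0) in at least 10 %
of either group *and* with |log fold change| ≥ ln 1.5 are tested; genes with
zero expression in both groups are skipped first. The fold-change threshold
is interpreted on the natural-log scale (≈ 0.405), matching the convention
of the common single-cell toolchains; both the base and the threshold are
configurable. The fold change itself is
`log((mean(expm1(x))_test + c) / (mean(expm1(x))_ref + c))` with
pseudocount c = 1.

**Multiplicity.** Adjustment is applied across tested genes within each
cell type; Bonferroni by default (the common toolchain default),
Benjamini–Hochberg selectable.

**Consensus rule.** Per cell type, genes with adjusted *P* < 0.05 and
positive fold change (direction "up"; "both" ranks by |log₂FC|) are sorted
by log₂ fold change descending — ties broken by smaller raw *p*, then gene
id, for determinism — and truncated to the top 500. The signature is the set
of genes present in at least 5 of the 10 declared major cell types, ordered
by (number of supporting cell types desc, mean within-list rank asc, gene
id). The list of major cell types must be supplied explicitly; the selection
is invariant to their order, and raising `min_cell_types` can only shrink
the signature.

## Smoothing, scoring, classification, enrichment (`signature_scoring`)

**Diffusion smoothing.** Cells are embedded with PCA (15 components by
default), a kNN graph (15 neighbours, self included) is built on the
embedding, the binary adjacency is symmetrized by averaging with its
transpose and row-normalized into a stochastic operator P, and expression is
replaced by X·(Pᵗ)ᵀ with t = 3 steps. This is deliberately a plain
kNN-diffusion re-implementation of adaptive-kernel diffusion imputation:
smoothing here only stabilizes per-cell signature scores, and the simple
operator preserves that role while being exactly testable (t = 0 is the
identity; constant genes are fixed points; rows of P sum to 1; smoothed
values stay inside each gene's original range).

**Scores and high calls.** A signature score is the unweighted mean of the
smoothed expression of the signature's present genes (absent genes are
reported; a signature with no present genes is an error). The high-call
threshold is the **linearly interpolated** 90th percentile of
reference-condition ("control") scores within the stratum — per cell type by
default, global as a switch — and a cell is high iff its score is
**strictly greater** than the threshold. The interpolation convention is
recorded with the thresholds because the call boundary depends on it. A
single-gene signature (e.g. CDKN1A-high) uses the same code path.

**Double positives.** Per donor (optionally per cell type), the number of
usable cells and of cells high in both signatures; cells with a missing call
in either signature are excluded and counted in a report.

**Preranked enrichment.** Classic weighted KS running sum with weight
p = 1: hits advance by |metric|ᵖ normalized by the set total, misses retreat
by 1/(N − n_set); ES is the running-sum extremum. The null permutes set
membership over gene labels (only a ranking is available, so phenotype
permutation is not applicable); the permutation p-value counts same-signed
permuted ES at least as extreme with the +1 correction, and NES divides ES
by the mean |same-sign permuted ES|. The ES agrees with an independent
external implementation (gseapy) to 1e-9 on random fixtures, and a fixed
seed reproduces the permutation p bit-for-bit. Large meta-analysis inputs
can be downsampled with `subsample_stratified` (uniform within study,
largest-remainder quotas).

## Beta-binomial association (`association_stats`)

Counts, not percentages, are modelled: y_i ~ BetaBinomial(n_i, a_i, b_i)
with mean μ_i = logit⁻¹(x_iβ) and common overdispersion ρ ∈ [0, 1), where
a = μ(1−ρ)/ρ and b = (1−μ)(1−ρ)/ρ. The design matrix carries an intercept,
a condition indicator and fixed-effect study dummies — the simplest faithful
form of "adjusting for differences across studies"; the reference study is
the first in sorted order and fitted means are invariant to that choice.
Below ρ = 1e-12 the likelihood is evaluated in its binomial closed form, and
the profile in ρ is continuous there.

Maximization is over (β, logit ρ) — the logit keeps the ρ bounds implicit —
by L-BFGS-B from a deterministic start (binomial GLM estimate for β,
ρ = 0.01), with a derivative-free Nelder–Mead polish if the quasi-Newton
line search stalls near machine precision. Standard errors come from the
numerically differentiated observed information (central differences).
Separation (an all-0 or all-n condition × study stratum) produces a warning
flag and a bounded estimate; non-convergence is flagged, never silent. The
condition effect is tested by Wald z and by likelihood ratio against the
condition-dropped refit (χ²₁); in deep tails the two p-values legitimately
diverge, so their agreement is asserted only at moderate significance.

## Relaxometry (`relaxometry`)

Echo times are milliseconds at every interface and seconds internally;
rates are reported in s⁻¹. The default estimator is the log-linear fit (OLS
of ln S on TE), exact on noiseless exponentials; `method="nonlinear"`
refines by least squares on the signal scale from the log-linear start, and
the two agree to 1e-6 relative on clean data. Echoes with signal at or
below the noise floor are excluded per voxel (late echoes at high R2* are
noise-dominated and bias log-linear fits); fewer than 3 usable echoes makes
a voxel invalid with reason "insufficient echoes", and negative fitted rates
are clamped to 0 and flagged so maps stay complete. Whole-volume mapping is
a vectorized masked OLS, verified voxel-by-voxel against the scalar fit.

ROI summaries average valid voxels only; the multi-ROI representative value
(the three-ROI clinical scheme) is the unweighted mean of ROI means. Iron
conversion is an affine map `slope·rate + intercept` whose coefficients must
be supplied by the user — no default coefficients ship, because the
published conversion is a calculator rather than a stated pair of numbers,
and inventing constants would fabricate a calibration. Both R2* and its
reciprocal T2* can be derived from the same map if a protocol reports T2*.

## Synthetic data (`synthetic_data`)

**Single-cell generator.** Counts are Gamma–Poisson (negative binomial)
with gene-wise log-normal baseline means (log-mean 0, log-sd 1), a single
dispersion 0.3, and per-cell log-normal size factors (log-sd 0.3). Defaults:
10 cell types × 2 conditions (control, iron_d2) × 150 cells, 1,000 genes.
The default planted biology mirrors the iron-exposure design: a 60-gene
program up-shifted by log₂FC 1.5 in 6 of 10 cell types at iron_d2 (the
consensus target), a 30-gene program in only 2 cell types (a decoy below the
support rule), and a 20-gene senescence-like program up-shifted by log₂FC 2
in a random 10 % of iron-condition cells. 3 % of genes are mitochondrial
(`mt-` prefix) with per-cell mito content drawn from Beta(2, 30) and the
mito gene means rescaled per cell to hit that target; 5 % are ribosomal
(`Rps`/`Rpl`). Gene-level sizes were chosen so that a default cell's library
(~1,500–2,000 counts) sits above the 1,000-molecule QC bound, as in a
typical nuclei run that passes filtering.

The generator does **not** emulate ambient RNA, doublets, batch mixtures
beyond the planted structure, gene–gene correlation, or realistic
zero-inflation beyond what the NB produces — so passing tests demonstrate
correctness of the algorithms under the assumed model, not robustness to
every artefact of real data.

**Cohort generator.** Per patient: study assigned round-robin across three
studies with logit effects (0, +0.3, −0.3), mean fraction
logit⁻¹(−2.2 + 1.0·condition + study effect) (≈ 10 % baseline), p drawn from
the Beta with that mean and ρ = 0.05, cell totals uniform in 300–800, y
binomial. ρ = 0 degenerates to the pure binomial.

**Phantom.** Concentric 2D layout broadcast through the volume: cortex
shell (R2* 40 s⁻¹) around a medulla core (20 s⁻¹), S₀ = 1000, background 0,
on a 32³ grid; ten echoes equally spaced 3.5–48.5 ms (the mouse R2*
protocol; the nine-echo 11–99 ms R2 protocol is a config away). Noise is
additive Gaussian on the magnitude signal by default — appropriate at the
simulated SNR — with a Rician option documenting the simplification.

All generators are pure functions of their config (which embeds the seed),
and ground truth round-trips to disk as JSON/CSV/NPZ.

## Problem sizes in the test and acceptance runs

Chosen as the smallest sizes at which the statistical claims are
well-powered: signature recovery at 300 cells per group (10 cell types,
1,000 genes); null calibration pooled over 20 simulated null datasets of
2 × 200 cells × 300 genes; beta-binomial recovery over 25 cohorts of
40 patients × 500 cells and type-I error over 200 null cohorts; rank-sum
exactness over all enumerable group sizes up to C(n₁+n₂, n₁) ≤ 5,000;
phantoms at 32×32×8. The acceptance script uses the same designs with seeds
derived from `--seed`.

## Known limitations

- The exact rank-sum path enumerates combinations in Python; it is meant for
  the small-group regime (C ≤ ~20,000), not as a fast general implementation.
- The diffusion operator uses a binary kNN kernel; no adaptive bandwidth or
  density correction.
- Study adjustment is fixed-effects only; no random-effect (GLMM) variant.
- The Wald SE uses a finite-difference Hessian; on nearly flat likelihoods
  (tiny ρ, few patients) it can be less stable than an analytic one.
- No DICOM ingestion, water/fat separation or motion correction on the MRI
  side; volumes are NIfTI/NPZ only.
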