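# ironsig

Tools for deriving and using a cross-cell-type **iron accumulation signature
(IAS)** from single-cell RNA counts, and for quantifying tissue iron from
multi-echo MRI — aimed at researchers studying the iron–senescence–fibrosis
axis who want each analysis step as a tested, reusable component.

Tissue injury drives iron accumulation that persists inside damaged and
senescent cells, and the transcriptional footprint of that accumulation is
shared across many cell types. This package implements the bespoke
computations that connect single-cell transcriptomics to non-invasive iron
imaging:

1. **Consensus signature derivation.** Within each major cell type (level-1
   annotation), iron-exposed cells are compared to controls by a two-sided
   Wilcoxon rank-sum test on log-normalized expression, restricted to genes
   detected in ≥ 10 % of cells with at least a 1.5-fold difference on the log
   scale. Significant genes (adjusted *P* < 0.05) are ranked by log₂ fold
   change; genes in the top 500 candidates of at least five of the ten major
   cell types form the signature. The rank-sum *p* is computed by **exact
   enumeration** of group assignments whenever C(n₁+n₂, n₁) is small enough
   (ties handled through the midrank distribution), otherwise by a tie- and
   continuity-corrected normal approximation.
2. **Signature scoring and classification.** Expression is smoothed by kNN
   graph diffusion (row-stochastic operator **P** on a PCA embedding, score
   matrix × **P**ᵗ), a cell's signature score is the mean smoothed expression
   of the signature genes, and a cell is *signature-high* when its score
   strictly exceeds the 90th percentile of reference-condition scores in its
   stratum. Cells high for two signatures at once (e.g. IAS-high and
   senescence-high) are tabulated per donor.
3. **Preranked enrichment.** Enrichment of a gene set in a ranked comparison
   (genes ordered by log₂ average fold change) uses the weighted
   Kolmogorov–Smirnov running-sum ES with a gene-label permutation null.
4. **Beta-binomial association.** Per-donor double-positive counts *y* of
   *n* cells follow *y* ~ BetaBinomial(*n*, μ, ρ) with
   logit μ = β₀ + β_cond·condition + β_study, capturing between-patient
   overdispersion while adjusting for study; fitted by maximum likelihood
   with Wald and likelihood-ratio tests of the condition effect.
5. **Relaxometry.** Voxelwise mono-exponential fits S(TE) = S₀·e^(−R₂*·TE)
   to multi-echo series (default protocol: ten echoes, 3.5–48.5 ms), ROI
   averaging over cortex/medulla masks, and a user-supplied affine
   calibration from relaxation rate (s⁻¹) to tissue iron.

Every stage is exercised on synthetic data with known ground truth
(negative-binomial counts with planted programs, beta-binomial cohorts,
mono-exponential phantoms), generated by `ironsig.synthetic_data`.

## Worked example

```python
from ironsig import synthetic_data as syn, preprocess as pp
from ironsig import signature_derivation as sd, association_stats as ast

# 10 cell types x (control, iron_d2) x 300 cells; a 60-gene program planted
# in 6 cell types and a 30-gene program in only 2 (below the consensus rule)
cfg = syn.ScSimConfig(seed=1, cells_per_type_per_condition=300)
counts, annot, truth = syn.simulate_sc_experiment(cfg)

metrics = pp.compute_qc_metrics(counts)
filtered, report = pp.apply_qc_filter(counts, metrics)   # <20% mito, >1000 molecules
norm = pp.lognormalize(filtered)
annot = annot.aligned_to(norm.cell_ids)

tables = {ct: sd.differential_expression(norm, annot, ct, "iron_d2", "control")
          for ct in cfg.cell_types}
result = sd.derive_consensus_signature(
    tables, sd.ConsensusParams(top_k=100, min_cell_types=5,
                               major_cell_types=cfg.cell_types))

table, _ = syn.simulate_patient_cohort(syn.CohortSimConfig(seed=1))
model = ast.fit_beta_binomial(table)
test = ast.test_condition_effect(model, table)
```

Output:

```
QC: kept 5653/6000 cells, dropped 50 ribosomal genes
signature: 59 genes, Jaccard vs planted program = 0.983
top entries: ['Ias002', 'Ias034', 'Ias008', 'Ias023', 'Ias055']
beta-binomial: condition effect = 0.789 (SE 0.182), rho = 0.0432, Wald p = 1.38e-05
```

The derived signature recovers 59 of the 60 genes planted across six cell
types (Jaccard 0.983) while excluding the 30-gene program confined to two
cell types; the cohort fit recovers a positive fibrotic-condition effect on
the double-positive fraction (true value 1.0, estimate within two standard
errors) with overdispersion close to the simulated ρ = 0.05.

A command-line interface mirrors the library
(`ironsig simulate-sc | qc | normalize | de | signature | classify |
doublepos | enrich | assoc | relaxo-fit | relaxo-roi | relaxo-calibrate`);
see `ironsig --help`.

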