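# Methods

This note documents the statistical model behind `gwaspath`, the defaults
that matter, the synthetic-data generator's assumptions, and the numerical
choices made where the design was genuinely open.

## Gene statistics and their nulls

A gene's association signal is summarised over its assigned SNPs (positional
rule: SNP s maps to gene g iff `[pos−w, pos+w]` overlaps `[start, end]`,
closed intervals, default w = 50,000 bp) by

* the minimum P-value, `min(p₁,…,pₙ)`, and
* the Fisher statistic, `T = −2 Σ ln pᵢ`.

Both depend on the number of SNPs and on the LD among them, so raw values
are not comparable across genes. They are converted to adjusted P-values
against a gene-specific null:

* **Phenotype permutation** (individual-level data): case-control labels
  are permuted B times (default 1,000) and the 1-df allelic trend test
  (Armitage χ² = n·r², r the dosage-phenotype correlation) recomputed for
  every SNP under every permutation. Only the ranks of the recomputed
  statistics matter, so any valid single-SNP engine would serve; the trend
  test is the GWAS default. Missing dosages are mean-imputed inside the
  permutation engine; a constant dosage column yields P = 1 with a warning.
* **Reference-panel simulation** (summary statistics only): Z-scores for
  the gene's SNPs are drawn from `MVN(0, Σ)` with Σ the Pearson correlation
  of reference-panel dosages (pairwise-complete over missing calls, unit
  diagonal), converted to two-sided P (`p = 2Φ(−|z|)`, computed on the log
  scale so Fisher statistics keep precision for extreme draws), and both
  gene statistics recomputed; default 10,000 replicates. Only SNPs shared
  between the summary statistics and the panel enter the statistic.

Both nulls use the smoothed counting estimator
`(1 + #{null at least as extreme}) / (B + 1)`, which is bounded below by
`1/(B+1)` and therefore safe to log-transform downstream; the raw
proportion `c/B` is available as an option. Adjusted P-values are discrete
on the grid `k/(B+1)` — at very large gene counts a
maximum-power KS test can detect this granularity, which is a property of
the estimator, not a calibration defect.

Two-sidedness of the simulated SNP P-values is a convention choice; it
matches how GWAS P-values are reported and makes the observed and simulated
statistics exchangeable under the null.

### LD matrix repair

Sample correlation matrices from finite panels are routinely
rank-deficient (duplicated or highly correlated SNPs, more SNPs than
samples). Before Cholesky sampling, eigenvalues below `psd_floor = 1e-8`
are clipped to the floor, the matrix is rescaled to unit diagonal, and the
repair is recorded in `LdMatrix.repair_log`. Monomorphic SNPs have
undefined correlations, set to 0 with a warning.

## Competitive pathway tests

Genes are ranked ascending by adjusted P-value; gene g receives
`q_g = rank_g / K` with average ranks for ties. Under the competitive null
(pathway membership independent of association) the q of a random gene set
behaves like uniform order statistics, up to two deliberate approximations:
ties (from the discreteness of the adjusted P-values) and
without-replacement sampling of ranks.

* **FM**: `−2 Σ_{g∈pathway} ln q_g ~ χ²(2m)` exactly for distinct
  independent uniforms. The without-replacement draw of m of K ranks
  carries a finite-population variance factor `(K−m)/(K−1)`; for
  `m/K ≤ 0.05` the effect on the 5% level is under half a point, which is
  why the type-I experiments run on a genomewide-scale universe
  (K = 18,477) rather than a small one. At m = 1000 the test is mildly
  conservative (~0.040–0.043 empirical at nominal 0.05) — an inherent
  property of the rank construction, visible in the tests.
* **ARTP**: `W(H) = Π_{h≤H} q₍h₎` over the pathway's ascending-sorted q,
  for each H in a candidate set (default {1,…,min(m,10)}; the grid is
  configurable since no canonical choice exists). Null replicates are
  random m-subsets of the universe (without replacement; with-replacement
  available for cross-checks). Each H gets an empirical P by the counting
  rule; the ARTP statistic is the minimum over H, and its own P-value is
  calibrated on the *same* replicate pool by ranking every replicate's
  minimum alongside the observed one — the standard single-pool device
  that avoids a nested simulation layer. Default B = 1,000; the smallest
  attainable P is `1/(B+1)`.
* **FDR**: Benjamini–Hochberg step-up across pathways, per method column
  (delegated to statsmodels).

Pathways are intersected with the study's gene universe before m is fixed;
pathways left empty are dropped with a warning.

## Prioritization and replication

Genes in pathways with FDR ≤ `fdr_max` (default 0.05) whose best SNP has
discovery P < `snp_p_min` (default 1e-4) and which are not on a
user-supplied known-locus exclusion list (gene ids and/or genomic regions —
no disease catalog is embedded) yield candidate SNPs; a SNP shared by
several selected genes is emitted once with all gene ids attached.
Replication cohorts are combined per SNP by fixed-effect inverse-variance
meta-analysis (`β = Σwᵢβᵢ/Σwᵢ`, `w = 1/se²`); family cohorts must be
pre-reduced to a (beta, se) pair. Discovery and replication P-values are
combined by Fisher's method against χ²(4). The reporting threshold for
highlighted combined P-values is a configuration knob (default 1e-5), never
hard-coded in the statistics. `replication_summary` counts unique SNPs
below α and reports the exact binomial tail `P(X ≥ k | n, α)`.

The bundled `data/t1d_replication.tsv` is a worked example: replication
P-values of 22 candidate SNPs from a type 1 diabetes follow-up; two entries
are recorded at 0.049 as stand-ins because the source reports them only as
below the 0.05 threshold (the replication count and its binomial tail are
unaffected).

## Synthetic data generator

* **Genotypes**: per gene, haplotypes come from a latent AR(1) Gaussian
  with parameter `ld_rho`, thresholded at each SNP's allele-frequency
  quantile (frequencies Uniform(0.05, 0.5) by default); a genotype is the
  sum of two independent haplotypes. This gives direct control of the
  latent LD structure the MVN null assumes; the realised dosage correlation
  is the tetrachoric-attenuated value (e.g. `2·arcsin(ρ)/π ≈ 0.71` at
  ρ = 0.9, maf 0.5), verified against a bivariate-normal orthant oracle.
  Genes sit 200 kb apart on one synthetic chromosome (SNPs 1 kb apart,
  at most 50 per gene), so the 50 kb window never bridges genes and the
  positional assignment recovers the generator's ground truth.
* **Summary statistics**: null genes get `Z ~ MVN(0, Σ̂_panel)`; a causal
  SNP with per-allele log-odds `effect` shifts its Z-mean by the trend-test
  noncentrality `δ = effect · sqrt(2f(1−f) · n · φ(1−φ))` (n total samples,
  φ case fraction) — the standard large-sample power formula, chosen so
  `effect` has the interpretable log-OR scale while keeping the √n scaling.
* **Cohorts**: individual-level genotypes from the same latent model with
  disease status from a logistic model targeting the configured case
  fraction (realised counts vary around the target; with `effect = 0`
  labels are independent of genotype).
* **Pathways**: gene sets sampled without replacement; sizes constant,
  geometric (default mean 17, a typical curated-database average, largest
  sets capped by the universe), or explicit; planted pathways are flagged.

What the generator does **not** emulate: realistic human LD maps and
recombination hotspots, overlapping gene windows (real genes share SNPs,
correlating gene statistics), allele-frequency spectra, population
structure, genotyping batch effects, or imputation uncertainty. Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under its stated model, not that any particular real-data
finding would reproduce.

## Problem sizes used by tests and the acceptance script

Type-I-error experiments use 1,000 random pathways per size on a
simulation-adjusted universe of 18,477 genes (1,350-sample reference
panel; n_sim = 10,000 in the acceptance script, 2,000 in the test suite)
and a permutation-adjusted cohort (B = 1,000; 18,477 genes in the test
suite, 5,000 for the size-50 acceptance target where the finite-population
factor is negligible). The permutation-vs-simulation concordance check uses
2,000 genes, 1,000 cases / 1,000 controls, `ld_rho ∈ {0, 0.5, 0.9}`,
B = 300 and n_sim = 1,000, with the cohort's controls as the reference
panel; the tests require Spearman correlation of at least 0.95 between the
two adjustment routes in every cell. The two-stage calibration check in the acceptance tests
(re-estimate a flagged cell with 8,000 pathways against the same 3-SE band)
trades no tolerance for extra precision.

## Known limitations

* The χ²(2m) null for FM is exact only for distinct uniform q; ties and
  finite-K rank sampling make it slightly conservative, increasingly so as
  m/K grows (see above).
* The MVN null assumes the reference panel's LD matches the study
  population's; a mismatched panel biases adjusted P-values (the generator
  can probe this by simulating with one `ld_rho` and analysing with a panel
  of another).
* Gene spans are taken as annotated start–end; transcript-level CDS
  reconciliation is out of scope, so callers should supply the span they
  intend.
* Strand/allele harmonisation across cohorts, imputation and liftover are
  out of scope; inputs are assumed pre-harmonised.
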