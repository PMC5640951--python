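# Methods

This note documents the statistical procedures implemented in pathbench, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Data model

A dataset is a genes × samples matrix of log2-scale expression values with
each sample labeled *treatment* or *control* (each cohort ≥ 2 samples, no
missing values). The same container holds an original dataset *D* and every
resampled sub-dataset *d*; resampling selects columns bit-exactly and never
recomputes values. Gene-set collections follow the GMT convention (id,
description, member symbols); gene identity is exact, case-sensitive string
match with no symbol aliasing. Collections are size-filtered (default
20–400 member genes, inclusive) *before* intersecting with the measured
genes — the filter describes the pathway database, not a particular array —
with the alternative order available to callers by re-applying
`filter_by_size` after `restrict_to_measured`.

## Per-gene statistics

Two-sample Student t with pooled variance (Welch by flag), two-sided
p-values, and the mean log2 fold change (treatment mean − control mean;
inputs are already log-scale). Genes with zero within-group variance get
t = ±∞ with p = 0 when the means differ (p = 1, t = 0 otherwise) and are
logged; enrichment scorers cap infinite statistics at the largest finite
magnitude so rankings and KS weights stay usable.

## Pathway statistics

- **ORA.** DE genes are those with t-test p below `de_alpha` (default 0.05),
  split by the sign of t. ORA as usually stated is direction-blind; to
  produce the up/down lists the benchmark requires, each direction gets its
  own upper-tail hypergeometric test of the overlap between the pathway and
  that direction's DE genes, over the universe of measured genes present in
  the collection. With no DE genes in a direction every tail is exactly 1.
- **AFC.** The pathway score is the arithmetic mean of member genes' mean
  fold changes.
- **GSA.** The maxmean statistic: s⁺ (mean positive part of member
  t-statistics) and s⁻ (mean negative part), keeping whichever is larger as
  a signed score; exact ties resolve to −s⁻.
- **GSEA.** Genes are ordered by the t-statistic (fold change by flag); the
  running sum gains |stat|^p / Σ_hits |stat|^p at member genes (weight
  exponent p = 1 by default, p = 0 giving the classical unweighted KS
  statistic) and loses 1/(N − N_hits) at non-members. The enrichment score
  is the signed extremum of the running sum; |deviation| ties (within 1e-9,
  a float-noise guard) resolve to the positive side. A set covering every
  measured gene leaves the miss decrement undefined and is an error. If all
  member weights are zero the hit increments fall back to equal weights.

## Permutation nulls

`p_up` is the probability that a null score is ≥ the observed score
(`p_down` with ≤), i.e. two one-sided tails of the same null.

- **Gene-label permutation** shuffles the assignment of per-gene statistics
  to gene identities; for GSEA this is realized as random hit-position sets,
  which is the same distribution and allows batch evaluation. One shared
  pool of B permutations (default B = 1000) serves all pathways.
- **Sample-label permutation** reassigns cohort labels (cohort sizes
  preserved) and recomputes every gene statistic. When the number of
  distinct assignments — C(n₁+n₂, n₁), halved for n₁ = n₂ because an
  assignment and its complement give the same split (10 for 3 vs 3) — is at
  most B, all of them are enumerated and p = #{null ≥ observed}/B_eff is an
  exact permutation p-value; the observed labeling is always among the
  enumerated assignments (for equal cohorts, the representative containing
  the first observed treatment sample is kept) and is scored through the
  identical numerical path, so p ≥ 1/B_eff > 0 holds bit-exactly. Otherwise
  assignments are sampled uniformly and the add-one estimator
  (b+1)/(B+1) keeps p in (0, 1].
- **Restandardization (GSA).** Sample-permutation null scores S\*_b are
  rescaled by the gene-permutation moments,
  S\*\*_b = μ_gene + σ_gene · (S\*_b − mean S\*)/sd S\*, following the
  published recipe; the gene-axis moments are estimated by Monte-Carlo gene
  permutation (equivalent in expectation to the analytic gene-sampling
  moments, and seed-controlled). The restandardized comparison is not an
  exact test, so the add-one estimator is always used.

## Ranking

Pathways are ranked per direction by ascending p, ties broken by descending
|score|, then lexicographic pathway id — fully deterministic. For
signed-score methods a pathway is eligible only for the list matching its
score's sign (exactly zero joins neither); ORA, tested separately per
direction, may appear in both lists. Lists are truncated to K (default 20;
20 and 50 in the benchmark grid).

## Resampling experiments

Sub-datasets are stratified draws without replacement: size n takes n/2 from
each cohort (proportional-to-cohort allocation, rounded, by option).
Replicates are sampled independently — duplicate sub-datasets may recur by
chance. Recall uses M = 500 replicates per size by default (configurable;
the shipped benchmarks use M = 100 for recall and M = 50 per dataset for
discrimination, sizes that keep a full run in seconds while leaving binomial
noise on s below ~0.03). Discrimination draws unmatched sub-dataset sets
from each dataset; ties in the recall comparison count as incorrect, exactly
as the strict inequalities in the definition demand, which yields s = 0 for
identical parent rankings as a hard identity. Sizes leaving fewer than 3
samples per permuted cohort are skipped (with a log note) for sample-label
methods, since so few distinct assignments remain that the null is
uninformative.

**Seeding.** A single master seed plus context keys derives every stream
(subsample draws keyed by dataset id, size and replicate index; permutation
nulls keyed by a CRC32 fingerprint of the dataset's value matrix and sample
ids). Content-keyed ranking seeds make each method a deterministic function
of (master seed, data): identical inputs always produce identical rankings,
which both realizes the s = 0 identity for bit-identical dataset pairs and
makes replicates order-independent and safe to parallelize.

## Synthetic data generator

The generator emulates normalized two-cohort microarray studies: gene g in
sample j is μ + σ·[√ρ·f_{s(g),j} + √(1−ρ)·ε_{g,j}] with standard-normal
factors and noise, where s(g) is the first pathway containing g (ρ > 0 gives
equicorrelated within-pathway noise, the co-expression structure that makes
gene-label nulls anti-conservative; genes outside any pathway are
independent). Perturbation is an additive location shift: a seed-chosen
fraction of a designated pathway's member genes gains ±δ log2 units in
treatment samples only (directions up/down/mixed; overlapping perturbed sets
accumulate their shifts). Defaults: 2000 genes, 100 disjoint 20-gene block
pathways, 60 + 60 samples, μ = 7 (a typical log2 microarray intensity),
σ = 1, ρ = 0, and a fixture design perturbing two pathways at δ = 1σ —
large enough to separate signal pathways in full-data rankings, small enough
that sub-dataset rankings remain noisy, which is the regime the recall
metric probes.

Under δ = 0 the cohorts are exchangeable by construction, so the generator
is a ground truth for permutation-null calibration: on such data the
pathway p-values of AFC, GSEA and GSA are uniform (verified by KS tests at
α = 0.001 across 20 independent replicates at B = 200). The
discrimination benchmark pairs two designs perturbing disjoint groups of
eight pathways each (4 up + 4 down at δ = 2σ), reflecting that distinct
diseases perturb many pathways in both directions; with this pair AFC
reaches s ≥ 0.97 at n = 24 while a bit-identical pair scores s = 0.

**What the generator does not model:** probe-level microarray noise,
background and batch effects, heavy-tailed or count (RNA-seq) distributions,
variance perturbations, between-pathway correlation beyond shared genes, and
covariate structure. Passing benchmarks on this generator demonstrate the
correctness and calibration of the machinery and the qualitative sample-size
behavior of the metrics — not method performance on real tissue data.

## Numerical choices and limitations

- Permutation resolution is 1/(B+1); B = 1000 by default (adequate for
  top-50 ranking), B = 200 in the shipped experiments.
- All experiment means are plain arithmetic means; no significance testing
  across methods is performed (comparisons are descriptive).
- The within-pathway factor model assigns multi-pathway genes to their first
  containing set; with the default disjoint block collection this is exact.
- Cross-dataset overlap for independently collected small/large studies is
  `recall(A_large, A_small)` per direction — no resampling involved.
- FDR control is deliberately absent: fixing the list length K replaces the
  significance threshold, keeping methods with different p-value scales
  comparable.
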