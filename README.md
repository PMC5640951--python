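# pathbench

Benchmark pathway-analysis (PA) methods **without a gold standard**, using two
mutually complementary resampling-based metrics — *recall* and
*discrimination* — together with reference implementations of six PA method
variants and a synthetic two-cohort expression generator.

The package is aimed at computational biologists who need to choose a PA
method for two-cohort (treatment vs control) transcriptomics studies, and at
method developers who want a reproducible, ground-truth-free harness for
comparing enrichment procedures, especially in the small-sample regime that
dominates public repositories.

## The evaluation strategy

Knowing which pathways are "truly" perturbed in a real experiment is usually
impossible, so pathbench evaluates methods by their behavior under controlled
resampling instead:

- **Recall (consistency).** Apply a method to a large dataset *D* (N samples)
  to get its top-K pathway list *A*; resample *D* without replacement into a
  small sub-dataset *d* (n < N samples) and get the list *a*. Then

  &nbsp;&nbsp;&nbsp;&nbsp;r(A, a) = ‖A ∩ a‖ / ‖A‖.

  A consistent method recovers much of its full-data answer from a fraction
  of the samples. Repeating over M sub-datasets per size n ∈ {6, 12, 24, 48}
  traces out how consistency degrades with sample size.

- **Discrimination (specificity).** Take two datasets *D*, *D′* from
  different conditions, with full-data lists *A*, *A′* and M sub-dataset
  lists *aᵢ*, *aᵢ′* each. A sub-dataset is *correctly associated* when its
  recall against its own parent strictly exceeds its recall against the
  other dataset, and

  &nbsp;&nbsp;&nbsp;&nbsp;s = [ ‖{aᵢ : r(A, aᵢ) > r(A′, aᵢ)}‖ + ‖{aᵢ′ : r(A′, aᵢ′) > r(A, aᵢ′)}‖ ] / 2M,

  with ties counted as incorrect — a method that returns the same pathways
  for every condition scores s = 0 no matter how high its recall. The metric
  generalizes to more than two conditions (own-parent recall must beat every
  other dataset's list).

Both metrics are computed separately for up- and down-regulated lists, with
the list length K fixed (20 or 50 by default) so methods that call different
numbers of pathways "significant" remain comparable.

## The pathway-analysis methods

Six variants are implemented, each returning ranked top-K up/down lists:

| Variant | Pathway statistic | Null distribution |
|---------|-------------------|-------------------|
| ORA | hypergeometric test on DE-gene overlap (DE split by t sign) | analytic |
| GSA | maxmean of per-gene t-statistics | restandardization (gene × sample permutation) |
| GSEA | weighted Kolmogorov–Smirnov enrichment score | gene-label permutation |
| GSEAs | same | sample-label permutation |
| AFC | mean of per-gene mean log2 fold changes | gene-label permutation |
| AFCs | same | sample-label permutation |

Sample-label nulls on very small cohorts are enumerated exactly (a 3 vs 3
dataset admits only 10 distinct label assignments); sampled nulls use the
add-one estimator (b+1)/(B+1) so p-values are never zero.

The methods are exposed both as functions (`pathbench.rank_pathways`) and as
scikit-learn-style estimators (`ORARanker`, `GSARanker`, `GSEARanker`,
`AFCRanker`) with `fit(X, y)` and fitted `ranking_` / `score_table_`
attributes that compose with sklearn tooling.

## Worked example

```python
import pathbench as pb

coll = pb.default_collection()           # 100 disjoint 20-gene sets, 2000 genes
design = pb.default_design(seed=11)      # 2 up-perturbed sets, delta = 1 sigma
D = pb.generate_dataset(design, coll)    # 60 treatment + 60 control samples

ranker = pb.AFCRanker(gene_sets=coll, k=5, n_permutations=1000)
ranking = ranker.rank_dataset(D, seed=0)
print("top up-regulated pathways:", ranking.up)

cfg = pb.method_config("afc", n_permutations=200)
for res in pb.run_recall_experiment(D, coll, cfg, sizes=[6, 24], M=50, K=20,
                                    master_seed=1):
    print(f"{res.method} {res.direction:>4} n={res.n:<3} mean recall = {res.mean:.3f}")
```

prints

```
top up-regulated pathways: ('S001', 'S002', 'S025', 'S087', 'S020')
afc   up n=6   mean recall = 0.341
afc down n=6   mean recall = 0.290
afc   up n=24  mean recall = 0.414
afc down n=24  mean recall = 0.388
```

The two genuinely perturbed pathways (S001, S002) head the up-regulated list;
the remaining entries are noise-ranked. Mean recall rises from 0.34 to 0.41
as the sub-dataset size grows from 6 to 24 samples — the sample-size effect
the strategy is designed to expose: at n = 6 only about a third of the
full-data top-20 list is recovered from a sub-dataset.

The same pipeline is scriptable from the shell:

```bash
pathbench simulate --design design.yaml --out-matrix M.tsv --out-pheno P.cls --out-gmt S.gmt
pathbench rank --method afc --matrix M.tsv --pheno P.cls --gmt S.gmt --k 20 --perms 1000 --seed 7 --out ranking.csv
pathbench evaluate --config config.yaml --out results/
pathbench summarize results/
```

`summarize` prints per-direction mean-recall matrices (sub-dataset size ×
method) with the row-wise maximum flagged `*…*` and minimum `_…_`.

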