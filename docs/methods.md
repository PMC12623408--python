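# Methods

## The classification model

The classifier operates on binary *gene-pair rules* `1[x_A < x_B]`
evaluated within each sample. Ties evaluate to 0 (strict `<`); each
unordered pair appears once, oriented with the lexicographically smaller
symbol first, since `(A<B)` and `(B<A)` are complementary features carrying
identical information to a tree learner. The central property — proved by
construction and asserted by tests — is that the rule matrix, and therefore
every prediction, is invariant to any strictly increasing transform applied
per sample (scaling, log, exp, affine, rank). This is what justifies merging
raw matrices from heterogeneous studies with **no** cross-sample
normalization or batch correction.

### Feature construction

*Gene ranking.* Within-sample gene ranks (average ranks for ties) feed a
Random Forest whose impurity importances rank genes, under two schemes:
*altogether* (one multiclass model) and *one-vs-rest* (one binary model per
class). Defaults: 2,000 trees for gene ranking; the top 85 altogether genes
and 100 genes per class at the function level. The bundled pipeline uses a
desk-scale 30 + 30 per list — on 600-gene synthetic cohorts larger lists
only add redundant pairs.

*Rule ranking and selection.* All C(n,2) pairs of the selected genes are
evaluated and ranked by the same two schemes, with per-sample weights
proportional to 1/(class size) so imbalanced cohorts do not dominate
(`inverse_frequency`, the default). Selection walks each ranked list
greedily (altogether first, then classes in sorted order; 100 rules per
list by default), skipping any rule that would repeat a gene more than
`gene_repetition_cap` times **within that list** (default 1). The cap is
per-list, not global: distinct class lists may legitimately reuse a gene,
and a selection of several hundred rules from a few hundred candidate genes
is only possible under the per-list reading. Duplicates across lists are
kept once but still consume the later list's quota.

*Shadow-feature pruning.* A Boruta-style filter appends a column-shuffled
shadow copy of every undecided feature, fits an importance forest (300
trees), and scores a "hit" for features beating the maximum shadow
importance. After iteration *t*, hit counts are tested two-sidedly against
Binomial(t, ½) with Bonferroni correction at α = 0.01: significantly many
hits confirms, significantly few rejects (rejected features leave the
candidate set). Features still undecided after `max_iterations` (default
25; 20 in the pipeline) are *tentative* and kept — conservative toward
signal retention. Note the test's premise: on a **fixed** random labeling a
chance-correlated feature is genuinely informative for that labeling, so
permutation-robustness improves with sample size; at the default 258-sample
design permuted labels essentially never confirm a feature.

### The forest

The final model is a bagging ensemble (default 1,000 trees) of CART trees
(`sqrt` feature subsampling) over the surviving binary rules, with
inverse-frequency class weighting. Bootstrap multiplicities are drawn by
the package itself and retained per tree, giving exact out-of-bag
bookkeeping for OOB accuracy and the proximity matrix
(`proximity(i,j)` = fraction of trees co-locating *i* and *j* in one leaf,
counted over trees where both are out-of-bag by default, `mode="all"`
optional). Class scores are **tree-vote fractions** — each tree votes its
leaf majority — so score rows sum to exactly 1 and a single-tree forest
yields 0/1 scores. Parameter search (`optimize_parameters`) is an
exhaustive grid scored by out-of-bag macro-averaged recall (balanced
accuracy), with ties broken toward fewer rules, then fewer trees.

Models serialize to a single JSON document (rules, per-tree node arrays,
leaf classes, in-bag counts, the training rule matrix, metadata); a
round-trip reproduces predictions bit-exactly because prediction traverses
the stored integer arrays directly.

### Prediction with missing genes

A rule is evaluable on a query matrix only when both genes are present.
Missing rules are imputed per sample from the training rule matrix stored
in the model. The default (`impute_knn`) takes the majority value among the
k = 5 training samples nearest in Hamming distance over the evaluable
rules, falling back to the global training majority on neighbour ties. A
plain `impute_majority` fill is provided but is biased under class
imbalance: the all-majority rule vector is essentially the largest class's
archetype, and with most rules imputed every query collapses onto that
class (measured on the default design: 0.54 accuracy — exactly the
majority-class frequency — vs 1.00 for kNN with the same 75% of rules
imputed). Prediction refuses when more than `max_missing_fraction`
(default 0.75) of rules are missing; the missing-gene experiment raises
this to 0.85 because deleting half the rule genes removes ~1 − 0.5² ≈ 75%
of rules in expectation and sampling noise straddles the default cap.

### Evaluation

Stratified splitting uses per-class `floor(fraction · n)` train counts
(clamped to leave ≥ 1 sample on each side; singleton classes are an
error). Confusion reports follow the caret conventions: per-class
one-vs-rest sensitivity/specificity/balanced accuracy/F1, overall accuracy
with exact Clopper–Pearson 95% CI, the no-information rate (largest class
frequency) and its one-sided binomial p-value P(Binom(n, NIR) ≥ correct).
Hard labels are the score argmax with lexicographic tie-break; ties are
flagged because mixture-like samples make hard labels misleading.

## The synthetic-data generator

The generator emulates what the analysis assumes about pooled public
cohorts of sorted brain/immune cells:

- **Class profiles**: per-gene log-mean ~ N(1, 1) (natural log of relative
  expression), with 20 disjoint marker genes per class elevated by
  `marker_effect` = 2.0 log-units (~7.4-fold).
- **Study batch**: per-(study, gene) multiplicative log-normal factors with
  σ = 0.5 (5 studies) — a family of within-gene distortions that visibly
  shifts per-study quantiles while leaving within-sample gene orderings
  largely driven by biology.
- **Counts**: negative binomial (dispersion r = 10) at a library size
  uniform in 0.5–1.5 M, the standard bulk RNA-seq noise model.
- **Imbalance**: default class sizes 32/140/46/27/13
  (astrocyte/microglia/neuron/endothelial/monocyte, 258 samples), the
  imbalance pattern of pooled sorted-cell cohorts.
- **Mixtures**: linear-scale weighted averages of class mean profiles with
  the same count noise — ambiguous, heterogeneous samples.
- **Single-cell mode**: per-cell libraries of 5–20 k with Bernoulli dropout
  applied after sampling; pseudo-bulk aggregation of dropout-free cells
  matches bulk expectation.
- **Reads**: two references, each a unique sequence plus a shared
  rRNA-like segment; uniform substrings with i.i.d. substitution errors,
  half reverse-complemented, source recorded in read names.

What it does **not** emulate: transcript-level effects (splicing, UMI
chemistry, gene length bias within a platform), correlated gene modules,
ambient RNA, doublets, or real cross-study gene-set differences. Passing
tests therefore demonstrate the pipeline's internal correctness and its
invariance/robustness properties, not field performance on real cohorts —
the synthetic marker structure is cleaner than real cell-type signatures,
which is why held-out accuracies here saturate at 1.0 rather than the high-
but-imperfect accuracies typical of real data.

## Read-origin module

Exact hash-set membership of canonical (strand-collapsed) k-mers replaces
engineered hash tables; semantics, not throughput, are the point, and the
module targets toy references, not whole genomes. k must be odd (no
reverse-complement palindromes) and ≥ 11. Per read with A-only / B-only /
shared hit counts (a, b, c): `A_only` if a ≥ min_hits (4) and a − b ≥
margin (2), symmetrically `B_only`; `both` if c ≥ min_hits with neither
unique count reaching min_hits; `neither` if a + b + c < min_hits; anything
else `ambiguous`. The margin-based rule is this package's own surrogate for
the external tools' undocumented ambiguity handling and is exposed as
parameters. The rRNA estimator counts a read when ≥ `min_hit_fraction`
(0.5) of its k-mers occur in the rRNA reference set; the QC experiment uses
k = 15 there because the estimator needs most k-mers of a true rRNA read to
survive sequencing error (survival ≈ (1−ε)^k per k-mer; at ε = 1% and
k = 25 a two-error read can lose over half its k-mers and the designed
fraction is under-estimated by ~0.03, while k = 15 recovers it within
binomial tolerance). At toy scale k = 15 remains specific (collision
probability against a few kb of unique sequence is ≪ 1).

## Reproducibility and problem sizes

One pipeline seed is expanded via `numpy.random.SeedSequence` into
independent per-stage streams, so adding a stage never perturbs earlier
ones; identical config + seed reproduces byte-identical artifacts (the run
manifest records SHA-256 checksums per artifact). The bundled analysis and
acceptance runs use the default 258-sample × 600-gene design with 30 + 30
top genes per ranking list, 2,000/500/300/1,000 trees for gene ranking /
rule ranking / pruning / the final forest — sizes chosen so the full study
retrains in well under a minute on one core while preserving every
qualitative property of the method.

## Known limitations

- Importance ranking uses impurity-based scores; permutation importances
  would be slower but less biased for correlated features.
- Boruta verdicts on fixed random labelings can confirm chance-correlated
  features at small sample sizes (see above); this is a property of the
  procedure, not a bug.
- kNN imputation consults the stored training rule matrix, so model files
  scale with n_train × n_rules.
- The read classifier has no quality-score weighting and no alignment; it
  is a QC screen, not a quantifier.
- `counts_to_tpm` is provided as a utility; the classifier itself never
  needs TPM.
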