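# cellpair

Rank-based **gene-pair-rule Random Forest** classification of the cell type
of origin for bulk and pseudo-bulk RNA-seq samples, with a k-mer
**read-origin quality control** module. The package is aimed at
transcriptomics analysts who need to verify what a cultured or immortalized
cell line actually resembles — e.g. whether a nominally microglial line
expresses a microglial or an astrocytic program — by pooling public
expression cohorts from heterogeneous platforms **without normalization or
batch correction**.

## The method

The unit feature is a *gene-pair rule*: within one sample, the binary
indicator

```
r(A,B) = 1[ x_A < x_B ]
```

for an ordered gene pair (A, B). Because a rule only compares values inside
a single sample, it is invariant to any strictly increasing per-sample
transform (library-size scaling, log, rank, platform calibration), which is
what lets count matrices and TPM matrices from different studies be merged
verbatim.

The workflow:

1. **Harmonize & filter** — map gene IDs to one symbol namespace, keep genes
   observed (non-zero) in ≥ 80% of samples, merge studies on the gene
   intersection with values copied bit-for-bit.
2. **Rank genes** by Random-Forest impurity importance on within-sample gene
   ranks, under an *altogether* (all classes jointly) and a *one-vs-rest*
   (one binary model per class) scheme; take the top genes from each list.
3. **Build rules** — all C(n,2) canonical pairs of the selected genes,
   evaluated per sample into a binary rule matrix.
4. **Rank & select rules** per scheme with inverse-class-frequency sample
   weights and a per-list gene-repetition cap that enforces rule diversity.
5. **Prune** with a shadow-feature (Boruta-style) test: features whose
   importance cannot beat their own shuffled copies are rejected.
6. **Train** a bagging ensemble of CART trees on the surviving binary rules.
   Class scores are tree-vote fractions, so each sample's scores sum to 1.
7. **Predict** on new matrices, imputing rules whose genes are absent from
   the query platform via nearest training samples (Hamming distance over
   the evaluable rules) — prediction survives a majority of rules missing.

Supporting modules: a seeded synthetic-data generator (multi-study
negative-binomial cohorts with per-study gene-wise batch distortion, class
imbalance, mixtures, single-cell dropout), pseudo-bulk aggregation of
annotated single-cell counts, caret-style confusion reports (exact binomial
CI, no-information-rate p-value), Random-Forest proximity matrices, and an
alignment-free two-reference read classifier (A / B / both / neither /
ambiguous) with an rRNA-fraction estimator.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. Training on the default design (5 cell classes, 5 studies, 258
samples with realistic imbalance — 140 microglia vs 13 monocytes — marker
effect 2.0 log-units, batch σ = 0.5):

```
$ python analysis/02_train_classifier.py
final model: 259 gene-pair rules
held-out overall accuracy: 1.0000
  astrocyte    balanced accuracy 1.0000
  ...
```

Scoring 50/50 astrocyte+microglia mixtures (an ambiguous, heterogeneous
sample) spreads the vote over the two components instead of committing:

```
$ python analysis/04_mixture_and_missing.py
mixtures: components in top-2 for 100% of samples; mean astrocyte score 0.344,
mean microglia score 0.584, max top score 0.709
missing-gene test: deleted 55 of 110 rule genes (195/259 rules imputed);
class recovery accuracy 1.0000
```

The read-origin QC run (30% of reads drawn from a conserved rRNA-like
segment shared by the two references, 1% sequencing error):

```
$ python analysis/05_read_origin_qc.py
A_only      39.90%
B_only      30.00%
both        30.00%
neither      0.10%
ambiguous    0.00%
truth agreement 99.9%; estimated rRNA fraction 0.298 (designed 0.300)
```

A high "both" fraction explained by the rRNA estimator — not by reads
unique to the foreign reference — is the signature of incomplete rRNA
depletion rather than cross-species contamination.

The same workflow is available as a CLI (`cellpair make-demo`, `cellpair
run`, `cellpair train/predict/evaluate`, `cellpair classify-reads`,
`cellpair pseudobulk`); `cellpair make-demo --seed 4 --out demo/` writes a
complete synthetic workspace with a ready `config.yaml`.

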