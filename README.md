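# covpat

Covariant pair and multi-site pattern mining in multiple sequence
alignments, with pattern-based sequence classification.

Point mutations in a population of related sequences (viral genotypes,
protein families) are rarely alone: a substitution at one site is often
accompanied by compensatory substitutions elsewhere.  `covpat` detects
these joint changes directly from an aligned FASTA file, with the residue
identities preserved, and turns them into classifiers.

For whom: anyone genotyping sequence sets, studying compensatory
mutations under drug or immune pressure, or looking for subpopulation
signatures in an alignment.  It is *not* a contact-prediction or
phylogeny-correction method (no average-product or inverse-covariance
machinery).

## The statistic

The atomic unit is the **site-residue element** `x(m)`: residue *m* at
aligned column *x* (1-based, written `139-Q`).  For two elements at
distinct columns the coupling strength is the **purity**

```
P = 2·n_ab / (n_a + n_b)
```

— the Sørensen–Dice coefficient of their occurrence sets (n_a, n_b
element counts, n_ab the co-occurrence count).  P = 0 for never-coupled
elements, P = 1 for identical occurrence sets, and P = 2/3 when all of one
element rides with half of the other; couplings are called at P ≥ 0.7 by
default.  A site pair is **confirmed** only when at least two element
pairs qualify simultaneously — one qualifying pair cannot represent a
substitution of one residue pair into another and is discarded as noise.

Confirmed pairs sharing an element are grouped; within each group the
**association degree** of an element is its average purity to the other
elements, and elements are removed (weakest first) until every degree is
≥ 0.7.  The survivors — at least three, one per column — form a
**covariant pattern**, reported as `(1-A 6-T 7-V)`.  Subset patterns are
dropped.  A sequence is classified into a pattern's cluster when **45% or
more** of the pattern's columns match; clusters are scored with
sensitivity/specificity/accuracy per class, and a stratified 10-fold
cross-validation harness estimates out-of-sample performance.

## Worked example

Simulate 500 sequences (length 60) in three classes planting 3-, 4- and
5-site patterns at carrier purity 0.9 over 5% noise, then detect:

```
$ covpat simulate --seed 7 --out-dir sim
wrote 500 sequences of length 60
planted A: (1-I 7-W 9-F)
planted B: (12-H 19-D 29-M 31-S)
planted C: (33-P 34-V 38-V 40-T 60-I)

$ covpat detect sim/synthetic.fasta --out-dir det
records: 500 kept, 0 discarded
informative sites: 20
pairs >= threshold: 162 (38 confirmed)
patterns: 6
  (33-A 34-S 38-M 40-N 60-W)
  (33-P 34-V 38-V 40-T 60-I)
  (12-C 19-W 29-Y 31-G)
  (12-H 19-D 29-M 31-S)
  (1-H 7-S 9-G)
  (1-I 7-W 9-F)
```

All three planted patterns are recovered verbatim, each alongside its
*complement* — the consensus residues at the same columns, carried by the
rest of the population (exactly as real genotype data yields a signature
for genotype B and a mirror signature for "not B").  Cross-validate the
patterns as classifiers:

```
$ covpat cv sim/synthetic.fasta sim/labels.tsv --seed 7
folds   10
macro_sensitivity   0.8987 +/- 0.0527
macro_specificity   1.0000 +/- 0.0000
macro_accuracy      0.9660 +/- 0.0176
```

Sensitivity tracks the simulated carrier fraction (0.9: the 10% of class
members planted without the pattern cannot be recalled), specificity is
perfect, and macro accuracy matches the analytic expectation
1 − (1 − 0.9)/3 ≈ 0.967 for three equal classes.  `covpat classify`
additionally writes per-cluster membership tables (`clusters.tsv`) and a
per-class report.

Outputs are plain TSV (`pairs.tsv` with counts and purities per element
pair, `patterns.tsv` with one pattern per row) and are byte-identical
across reruns with the same seed.  See `covpat <cmd> --help` for every
flag; `docs/methods.md` describes the model, its parameters and its
limitations in detail.

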