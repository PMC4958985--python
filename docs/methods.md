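# Methods

## The model

`covpat` detects sets of co-occurring substitutions in a multiple sequence
alignment and uses them to classify sequences.  Its atomic unit is the
*site-residue element* — the pair (aligned column, residue), written
`139-Q`.  Working with elements rather than columns keeps the identity of
the substitution: a covariance is not "columns 7 and 103 co-vary" but
"`7-D` travels with `103-I`, and `7-T` with `103-V`".

### Independent pair model

For two elements `a`, `b` at distinct columns with occurrence sets of
sizes `n_a`, `n_b` and co-occurrence count `n_ab`, the coupling strength
("purity") is the Sørensen–Dice coefficient

    P(a, b) = 2 n_ab / (n_a + n_b).

Anchor configurations: P = 0 when the elements never co-occur, P = 1 when
their occurrence sets are identical, and P = 2/3 when all of `a` co-occurs
with exactly half of `b`.  Since the all-with-half configuration is the
weakest arrangement one would still call a coupling, the rational
detection range is 2/3 < P ≤ 1; the default threshold is 0.7, compared
inclusively.  The statistic lives in a single function
(`pair_model.purity`) so an alternative co-occurrence measure can be
swapped in.

A covariance between two *columns* is confirmed only when at least two
distinct element pairs connect them at or above the threshold: a genuine
covariant substitution converts one residue pair into another, so both
states must be visible.  Site pairs carried by a single qualifying pair
are treated as noise and excluded from everything downstream.

### Correlated tandem model

Confirmed pairs sharing an element are joined into groups (connected
components of the element graph).  Each group becomes a symmetric matrix
of pairwise purities over its elements — *all* purities are recomputed
from the alignment, not only those of member pairs, and two elements at
one column get 0 (their occurrence sets are disjoint).  The *association
degree* of an element is the mean of the n−1 off-diagonal entries of its
row (self-purity is excluded; the divisor convention is recorded as a
module constant).  While the minimum degree is below the degree threshold
(default 0.7, the same intermediate correlation level as the pair
threshold, independently settable), the single element achieving the
minimum is removed and the degrees are recomputed.  Removal is one element
per round; batch removal was rejected because it changes results.
Tie-break among equal minima: largest column, then lexicographically
largest residue — deterministic and order-independent.

Termination uses ≥ threshold (strict > would never terminate on a matrix
sitting exactly at the threshold).  Survivors must be unique per column;
if two same-column elements both survive, the lower-degree one is removed
and pruning continues.  Because removing an articulation element can
disconnect a group, survivors are split along the confirmed-pair graph and
each component is re-pruned.  A pattern needs at least 3 elements — a
2-element survivor is just a pair, already reported by the pair model.
Finally, duplicates and proper-subset patterns are dropped, and patterns
are printed as `(1-A 6-T 7-V)` with 1-based column indices in the order of
the aligned data.

### Preprocessing

Two screens run first: (a) a sequence is kept only when strictly more than
one third of its positions match the plurality consensus (gap-vs-gap
counts as a match; the consensus is computed once and not revisited);
(b) a column enters the element model only when at least two distinct
non-gap residue types each occur in at least 5 sequences — the
element-count floor must hold per residue type for a covariance to be
observable, and gaps are indels, not substitution states, so they never
count as a type.  Sequences are screened before columns.  The consensus
tie-break (most frequent, then lexicographically smallest residue) is a
deterministic choice among equally defensible rules.

### Classification and evaluation

Every pattern characterises one subpopulation strongly, so a *loose* fit
suffices for membership: a sequence joins a pattern's cluster when at
least 45% of the pattern's columns carry the pattern's residues
(inclusive; gaps never match).  Clusters may overlap and a sequence may be
in several (a `best_only` mode restricts to the best match).  Against
known labels, membership in a class's cluster is a positive call and the
standard indexes Sen = TP/(TP+FN), Spe = TN/(TN+FP),
Acc = (TP+TN)/(TP+TN+FP+FN) are computed per class and macro-averaged.
The stratified k-fold harness (k = 10 default) re-detects patterns on each
training split, attributes each pattern to the majority class of its
training cluster, picks per class the pattern maximising training
accuracy (ties: larger pattern, then smaller first column), scores the
held-out split, and reports mean ± sd over folds.  A stratified
`subsample` supports different-scale runs (per-class sizes rounded half
up, floored at one).

## Synthetic data

The generator emulates exactly what the detector assumes: a consensus
background with iid per-column substitution noise (uniform over
alternative residues — deliberately no phylogeny, so no background
correlation), plus two or more classes each planting a tuple of elements
in a configured fraction of members (the *carriers*, chosen at random per
class; non-carriers keep pure background at those columns).  Gaps can be
inserted iid.  Design choice: at a planted column, noise never draws a
planted residue of any class.  This pins the ground truth — every planted
element occurs in exactly its carriers (at gap rate 0), so
`expected_pattern_purity` is an exact closed form
P = 2 n_ab/(n_a+n_b) over summed carrier counts, usable as a test oracle
rather than a Monte-Carlo estimate.

Default study conditions (`make_demo_config`): 500 sequences of length 60
in three classes (167/167/166) planting disjoint 3-, 4- and 5-site
patterns, carrier purity 0.9, substitution rate 0.05, no gaps, amino-acid
alphabet.  These sizes keep every analysis in this repository (including
the 10-fold cross-validation, which re-runs detection ten times) within a
couple of seconds on one CPU while leaving each residue type well above
the count floor of 5.

What passing on synthetic data does *not* show: robustness to
phylogenetic background correlation (real alignments are trees, not iid
noise), to misalignment, or to indel-rich regions.  The generator tests
the detector, not evolution.

Two behaviours of the full pipeline on synthetic data are worth knowing:

* a planted pattern is always accompanied by its *complement* pattern —
  the consensus residues at the same columns, carried by everyone else —
  just as real genotype data yields complementary signatures for the
  union of the remaining genotypes;
* at zero noise and carrier purity 1.0 the planted tuple and the other
  classes' consensus residues have identical occurrence sets, so the
  maximal reported pattern is a superset of the planted tuple (which is
  then removed as a subset).  With any realistic noise the planted tuple
  is recovered verbatim.

A consequence of defining carrier purity as the fraction carrying the
*full* tuple is that non-carriers carry none of it, can never reach the
45% match threshold, and are irreducible false negatives: the expected
macro accuracy of cross-validation on synthetic data is
1 − (1 − purity)/C for C equal classes (≈ 0.967 at purity 0.9 with three
classes), with sensitivity ≈ purity and specificity ≈ 1.  The evaluation
harness reports exactly this.  Real genotype data behaves like carrier
purity ≈ 0.99 with partial degradation, which is what the loose 45%
threshold absorbs.

## Numerical and degenerate-input choices

* All thresholds compare inclusively (≥).
* Degrees are exact float row means; ties in the pruning minimum are
  resolved by element identity, never by matrix position, so results are
  invariant under record permutation and element ordering.
* Sequences with a gap at one of a pair's columns simply carry no element
  there and drop out of that pair's counts.
* Fewer than two informative columns → no pairs, empty outputs, exit 0
  with a warning (not an error).
* An alignment whose records are all discarded by the consensus screen,
  an evaluation class without labeled members, and a CV class smaller
  than k are errors naming the offender.
* All randomness (generator, subsampling, fold shuffling) flows from
  explicit integer seeds; reruns are byte-identical.

## Known limitations

* The purity statistic does not correct for shared ancestry; clades
  produce genuine (if phylogenetic) co-occurrence, which is reported as
  covariance.  This is by design — the patterns are meant to track
  subpopulations — but it means the tool is not a contact-prediction
  method and does not compete with inverse-covariance approaches.
* Pattern mining is exhaustive per group; pathological groups with very
  many elements at similar degrees could be slow, though the confirmation
  rule keeps groups small in practice.
* The evaluation treats multi-cluster membership as independent positive
  calls per class; no single-label decision rule is imposed unless
  `best_only` is requested.
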