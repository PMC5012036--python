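# Methods

## Model

The method treats a hybrid (recipient) taxon h as one whose evolutionary
distances to the other taxa are a convex combination of the distances of
two donors i and j,

    d(k, h) ≈ α d(k, i) + (1 − α) d(k, j),

with the hybridization degree α the proportion of h's character content
attributed to donor i. The assumption is reasonable for additive-style
distances over mixed character content (e.g. Hamming distances over
presence-absence profiles when a recipient's homology-class memberships
are drawn partly from each donor's lineage); it is not a stochastic model
of character change, and the degree is a descriptive least-squares
quantity without a sampling distribution. No uncertainty is attached to
α; the residual LS, the deviation Δ² it is compared against, and the
four-point score Sc are reported per event as diagnostics.

## Estimation

Centring the convex relation with the row means S_l (computed over the
n − 3 active nodes besides h, i, j) turns it into a one-parameter
ordinary least-squares problem whose closed form is implemented directly.
Three properties shape the numerics:

* **Exactness.** If the convex relation holds exactly, the estimator
  returns α to machine precision and the residual is 0 (tested).
* **Shift invariance.** Adding a constant to any of the three rows
  d(·, h), d(·, i), d(·, j) leaves both α̂ and LS unchanged. A donor is
  therefore only identifiable up to taxa whose distance rows differ from
  it by a constant — in tree terms, up to its cherry sibling or the
  ancestral cluster it belongs to. Reported donors must be read with this
  equivalence in mind.
* **Degeneracy.** When d(k, i) − d(k, j) is constant over k (the donors
  form a cherry), the design variable X vanishes identically and α is not
  identifiable; the estimator returns NaN (guarded by a relative
  tolerance of 1e-9 × the largest distance) and the candidate is dropped
  rather than scored with an arbitrary ratio.

## Algorithm and tunable parameters

Agglomeration follows NJ with the Q-criterion pair choice (equivalent to
least-squares total-length minimisation over star configurations; the
equivalence is a tested property). Matrix reduction uses the half-sum
rule d(X, k) = (d(i,k) + d(j,k))/2. Under this rule an agglomerated node
behaves, on additive input, like a leaf whose pendant edge is extended by
the mean of the joined limb lengths; the tree builder carries that offset
per active node and subtracts it when the node's edge is finally
assigned, so leaf-to-leaf path lengths reproduce additive input exactly
(tested to 1e-9). Branch-length estimates use the standard NJ limb
formulas; negative estimates are written as-is to Newick output and
clamped to zero in path-length queries.

Detection parameters, with the defaults exposed through
`DetectionParameters` / `default_parameters`:

| parameter | meaning | default |
|---|---|---|
| `min_score` | minimum four-point deviation Sc a triplet must reach (same units as the distances) | 0 for ≤ 20 taxa, 0.1 above |
| `alpha_min`, `alpha_max` | admissible degree range, inside (0, 1) | (0.1, 0.9) for ≤ 20 taxa, (0.25, 0.75) above |

The two regimes mirror the analysis settings used for small language
groups versus a full 84-language matrix; the 20-taxon cutoff between
them is this package's choice. The acceptance test LS < Δ² is strict, as
printed in the source method: ties reject. Candidate ties on equal LS
break lexicographically on (donor1, donor2); pair-selection ties break
lexicographically on label pairs; the argmax of |Δ| breaks ties
lexicographically on h. All output is a deterministic function of the
input matrix.

Two numerical guards implement the exact-arithmetic meaning of the
printed rules: detection is skipped when |Δ| ≤ 1e-7 × the largest
distance (on additive data Δ is exactly 0 and LS < Δ² can never hold,
but machine-epsilon noise on both sides would otherwise produce spurious
events), and the degeneracy guard above. Detection requires more than
four active nodes; smaller matrices fall back to plain NJ with a
warning.

`iterate_removal` re-runs inference on the input matrix with all
previously detected recipients' member taxa removed, accumulating events
until a run adds nothing new or `max_rounds` is reached. This can
surface events whose signal was distorted by a removed recipient in the
first pass.

## Synthetic data

The generators are seeded (single `numpy.random.Generator` stream per
run; bit-reproducible) and serve both as test fixtures and as the
simulation study design.

* `random_additive_matrix`: random topology by uniform edge attachment,
  branch lengths uniform in (0.1, 1.0) by default; exact path-length
  matrices.
* `inject_hybrid`: distance-level convex mixture, the noise-free case of
  the estimation model.
* `simulate_cognate_database`: two lineages plus an outgroup; each
  character is partitioned into cognate sets consisting of singleton
  "innovator" taxa plus a shared lineage core, the outgroup always in
  its own set. Singleton innovations keep every taxon's profile distinct
  across characters, which is what makes donors identifiable; they are
  also the realistic analogue of private lexical innovations. A hybrid
  inherits, per character, the memberships of one parent: a fraction α
  of the characters (floor rounding, spread evenly down the list) from
  parent 1 and the rest from parent 2, or Bernoulli(α) draws in the
  stochastic mode. Defaults — 50 characters, 4 cognate sets per
  character, ~10 taxa — are a scaled-down reading of a real cognate
  database (84 languages, 200 meanings, 1315 cognate sets); an optional
  `missing_rate` removes whole taxon × character slots.
* `worked_example_database`: the canonical 8-taxon, 4-character,
  16-cognate-set balanced hybrid, constructed without randomness. Its
  mirror symmetry forces the estimated degree to be exactly 0.5.

What the generators do **not** emulate: sound change and form evolution
(forms are random strings with occasional one-letter variants), semantic
shift, correlated borrowing across meanings, and rate variation across
lineages. Passing tests therefore demonstrate the estimator's and
algorithm's behaviour under the stated mixture model, not performance on
real lexical data.

## Behaviour under the two injection models — a known limitation

The two generators probe different geometries, and the difference
matters:

* A **cognate-level** mixture hybrid shares about half its profile with
  each lineage and so differs from *both* — metrically it is repelled
  from the tree. In simulations (10 taxa, 50 characters, α uniform in
  [0.25, 0.75]) the recipient is detected in ≈98/100 runs with mean
  absolute degree error ≈0.03.
* A **distance-level** exactly convex hybrid is metrically a point *on
  the tree path* between its parents. The NJ Q criterion then frequently
  selects the pair (hybrid, nearer parent) before any pair containing a
  parent alone — and the detection rule, which only probes candidates
  outside the selected pair with donor 1 inside it, cannot flag a hybrid
  that sits in the pair. The hybrid is absorbed into a cluster (which is
  often detected later as an *ancestral* recipient, consistent with the
  method's reading that ancestral branches participate in hybridization)
  or triggers a reversed-role detection. Strict leaf-level recovery of
  (recipient, both parents) is therefore ≈50% in this regime, not near
  1. This is a property of the published decision rule, not of the
  implementation: at any pair containing a parent the detector recovers
  the exact triplet with LS = 0, and pair selection matches both the
  brute-force least-squares configuration scan and an independent NJ
  implementation. The corresponding acceptance test states the stricter
  expectation and is allowed to fail, documenting the gap.

## Other design choices

* After accepting a hybrid the pending join is *not* performed; pair
  selection restarts on the reduced matrix.
* Donors and recipients are whatever nodes are active at the detection
  step; reticulation records carry each node's member-taxon list, and
  the reported degree is the value at detection time (no re-estimation
  after removal).
* The per-meaning distance follows its source definition literally: a
  cognate set containing neither taxon contributes 0 to the numerator
  while being excluded from the denominator.
* Word trees are only built for characters attested (with forms) in at
  least four taxa; below four leaves all unrooted topologies coincide.
* Levenshtein distances are computed per Unicode code point with a
  direct dynamic program; word forms are compared orthographically, with
  no transliteration or sound-class mapping.
* PHYLIP distance matrices are read and written in a relaxed square
  dialect: full labels (no 10-character truncation), whitespace
  separated.
* In extended-Newick output each reticulation edge is written
  PhyloNetworks-style as `:length:support:gamma` with γ the degree; a
  donor that was itself removed by a later event has no node left in the
  tree and such an edge appears only in the TSV export.
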