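# Methods

## The evaluation problem

Protein function is described by Gene Ontology (GO) terms organised as a
directed acyclic graph in three aspects — Molecular Function (MFO),
Biological Process (BPO), Cellular Component (CCO).  An annotation is
implicitly an annotation of every ancestor term, so all annotation sets in
this package are kept ancestor-closed over the relations `is_a`, `part_of`,
`regulates`, `negatively_regulates` and `positively_regulates`.  Edges that
cross aspects are dropped at parse time: evaluation is strictly per aspect,
and cross-aspect propagation would leak annotations between aspects.

A prospective benchmark fixes an ontology and a snapshot of experimentally
validated annotations at a submission deadline t0, then scores predictions
against the annotations added between t0 and a later evaluation date te.
Per protein and aspect the pair falls into one of three knowledge settings:

* **NK** (no knowledge): no experimental non-root annotation in *any*
  aspect at t0;
* **LK** (limited knowledge): experimentally annotated in at least one
  other aspect but not this one;
* **PK** (partial knowledge): already annotated in this aspect; only the
  newly added terms `T_te \ T_t0` are ground truth, and the prior terms are
  removed from the prediction set before thresholding.

"Annotated" means carrying at least one non-root term: aspect roots are
true of every protein and carry no information, so they are kept in the
graph but excluded from ground truth, predictions, and all metrics.

## Information accretion

Terms are weighted by information accretion,
`ia(t) = -log2 Pr(t | Pa(t))`, the surprise of observing t on a protein
that already carries every parent of t.  The conditional probability is
estimated on the propagated t0 corpus as the ratio of the number of
proteins annotated with t to the number annotated with all of t's parents
(the denominator requires *all* parents — `Pa(t)` is a set).  Because
annotation sets are ancestor-closed, the information content of a closed
set is the plain sum of `ia` over its members, and the conditional content
of the newly added terms given the prior set is the sum over the
difference: `IC(B \ A | A) = IC(B) - IC(A)` exactly.  This additive
decomposition is what makes the PK setting scoreable with the same
machinery as NK/LK, and it is asserted to machine precision in the tests.

Choices: log base 2 (bits) by default, configurable.  Terms never observed
in the corpus are absent from the table and weigh 0 downstream with a
counted warning ("drop" smoothing); "add_one" Laplace smoothing
`(count+1)/(denominator+2)` is available when a value for every term is
preferred.  The table is computed once from the t0 corpus and frozen, so
every later snapshot is scored on the same scale.

## Metrics

For a threshold grid τ ∈ {0.01, …, 1.00} (step 0.01, configurable; the
conventional grid for this benchmark family) and per-protein prediction
sets `P_i(τ) = {t : score_i(t) ≥ τ}`:

* micro precision/recall pool weights across proteins:
  `pr = Σ_i W(P_i ∩ T_i) / Σ_i W(P_i)`, `rc = Σ_i W(P_i ∩ T_i) / Σ_i W(T_i)`;
* macro averages per-protein precision over the m(τ) proteins with at
  least one prediction and per-protein recall over all n evaluable
  proteins;
* `W` is 1 for unweighted metrics and `ia` for weighted ones;
* coverage is `m(τ)/n`;
* remaining uncertainty `ru(τ) = (1/n) Σ_i IA(T_i \ P_i)` and
  misinformation `mi(τ) = (1/n) Σ_i IA(P_i \ T_i)` (always IA-weighted; a
  per-m(τ) denominator is available behind a flag).

`Fmax = max_τ F1(τ)` over thresholds where precision is defined (m(τ)>0);
`Smin = min_τ sqrt(ru² + mi²)`.  Ties break toward the largest τ for
determinism.  The single-number challenge score is the IA-weighted micro
Fmax on the union of NK and LK entries, averaged over the three aspects.

Numerical conventions worth knowing:

* Prediction scores are max-propagated to ancestors by default so that
  thresholded sets are ancestor-closed; without this, precision is
  spuriously penalised for implied ancestors the predictor omitted.
* True/false-positive/negative weights are accumulated directly (never by
  subtraction), so the perfect predictor scores exactly Fmax = 1 and
  Smin = 0, and the empty predictor exactly recall = 0 and mi = 0.
* Under IA weighting a protein's truth (or prediction) set can carry zero
  total weight when all its terms were unobserved at t0.  Macro averages
  therefore run over proteins with positive denominator weight; for
  unweighted metrics this is identical to the m(τ)/n convention above.
  The macro-averaging denominators are a documented convention of this
  package (both denominators are reported in the outputs to keep the
  choice auditable).
* A predictor that outputs only a PK protein's prior terms has no
  evaluable predictions: precision is undefined at every threshold and the
  reported Fmax is 0.

Bootstrap confidence intervals resample the evaluable protein list with
replacement (same size, percentile CI, default B = 5000 at level 0.95).
The seed is mandatory; identical seeds give bit-identical intervals.
Replicates on which a metric is undefined are recorded as missing, and
more than 50% missing is an error.

## Baselines

All four baselines use only information frozen at t0 and emit scores in
[0, 1]:

* **Naive** — every term scores its corpus frequency (count of proteins
  annotated with it over corpus size), identically for every target; the
  corpus is propagated on its own ontology, restricted to the target
  ontology, and re-propagated there to restore connectivity.
* **Non-experimental evidence** — every term annotated at t0 under *any*
  evidence code scores 1.0, measuring how well electronic/computational
  annotations anticipate later experimental validation.
* **Alignment transfer** — from a 12-column tabular alignment file, each
  query inherits every term of its hit subjects at the maximum percent
  identity over subjects bearing the term, divided by 100.  No E-value
  filtering is applied by the reader (configurable upstream).
* **Embedding k-NN transfer** — per-term max over the k nearest reference
  proteins in embedding space.  Euclidean distances d become similarities
  `(dmax - d)/dmax × 100` with dmax the maximum over all target-reference
  pairs in the run (recorded in the output header for reproducibility);
  cosine similarities are min-max scaled to [0, 100].  Both k = 3 and
  k = 5 are conventional; k is a parameter.

## Synthetic worlds

The generator builds everything the pipeline consumes so that every test is
hermetic: a random rooted DAG per aspect (each term linking to one or two
shallower parents, mostly `is_a` with some `part_of`), proteins annotated
by power-law-skewed term sampling closed upward, and two-snapshot growth
that realises all three knowledge settings in declared proportions.

Default conditions (chosen once): 3 aspects × 40 terms, 200 proteins;
growth fractions NK 0.10 / LK 0.12 / PK 0.45 of proteins (some PK proteins
also gain first terms in a second aspect and land in LK there), which
makes PK dominate the evaluable annotations as it does in real
prospective corpora; 10% of new annotations cite a publication dated after
t0, matching the roughly one-tenth share of strictly-unpublished
annotations in recent benchmark snapshots; term popularity skew 1.2 so
that information accretion spans a wide range.  The generator's ledger of
intended settings is cross-checked against the partitioner before a world
is returned, and all fixture files re-parse to the in-memory objects
exactly.

The simulated predictor scores each candidate term
`q·1[true] + (1-q)·U(0,1)` over the true terms plus popularity-sampled
decoys: quality q = 1 reproduces the truth exactly at score 1.0, q = 0 is
independent of the truth, and the expected score separation is monotone in
q — the property the degradation tests rely on.  Scores are quantized to
the evaluation grid so that grid sweeps and exhaustive distinct-score
sweeps coincide.

What the worlds do *not* emulate: real sequences (alignment identities are
simulated from annotation overlap, not alignments), biased curation and
annotation errors, ontology evolution between snapshots, and realistic
corpus sizes.  Passing tests therefore demonstrate the correctness of the
bookkeeping and metrics, not predictor performance on real data.

## Problem sizes

Test and acceptance runs use desk-scale worlds (25–40 terms per aspect,
60–200 proteins, bootstrap B ≤ 2000 in tests and B = 1000 in the
acceptance script) — the package's own choice of fixture scale; all
computations are linear in proteins × terms × grid points and scale to
full corpora.

## Known limitations

* The macro-averaging denominators and the 0.01 grid are conventions;
  both are configurable and recorded in outputs, but comparisons across
  tools should confirm matching conventions.
* GAF input carries assignment dates, not publication dates, so the
  publication-date restriction only filters records from sources that
  provide reference dates (the 6-column TSV dialect does).
* `common_subgraph` keeps the newest graph's edges; terms orphaned by the
  intersection are removed and reported rather than re-attached.
* No term-centric evaluation, no submission-size caps, and no normalized
  Smin variants.
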