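# Methods

## Model

mirdwalk ranks candidate miRNAs for a query disease by random walk with
restart (RWR) on a heterogeneous network. The network joins a miRNA
functional-similarity block MM, a disease phenotype-similarity block DD and
a binary association block A into one symmetric weight matrix

    W = [[ MM'  A  ],
         [ A^T  DD' ]]

with MM', DD' the similarity blocks after thresholding at τ and removal of
the diagonal. Association edges are unweighted (weight 1) while similarity
edges keep their score; the two edge classes are combined unscaled. The
transition matrix T is the row normalization of W; a vertex whose edges are
all removed receives a self-transition of 1, which preserves
row-stochasticity without introducing a teleportation term the model does
not otherwise have.

The walk for query disease d starts uniformly on d's known miRNAs and
iterates p ← (1−M)·Tᵀp + M·p₀. The model assumes (i) functionally similar
miRNAs share diseases, so similarity edges are informative for association;
(ii) association evidence is binary — curated databases record presence,
not strength; (iii) relevance is global network proximity to the seed set,
not merely direct adjacency: the fixed point M(I−(1−M)Tᵀ)⁻¹p₀ sums over all
walk paths from the seeds with geometric damping.

Scores are read at miRNA vertices only; disease-vertex occupancy is
discarded. miRNAs already associated with the query disease are removed
before ranking, and ties are broken by lexicographic id so output is
deterministic.

A disease with no known miRNA raises an explicit "no seed" error: seeding
from phenotype neighbors (the extension needed for such diseases) is out of
scope.

## Parameters

| parameter  | meaning                                   | default | notes |
|------------|-------------------------------------------|---------|-------|
| `M`        | restart probability, dimensionless (0,1]  | 0.7     | best-performing value in the 0.1–0.9 sweep range; larger M weights short paths from the seeds more heavily |
| `tau`      | similarity threshold in [0,1]             | 0.0     | a neutral default keeping every positive similarity edge; the thresholding rule is exposed because sparse networks may benefit from pruning weak edges |
| `epsilon`  | L1 convergence tolerance                  | 1e-10   | the update contracts by (1−M) per step, so with M ≥ 0.1 convergence to 1e-10 takes at most ~220 iterations |
| `max_iter` | iteration budget                          | 1000    | ample for any M ≥ 0.1; exhausting it warns (returns `converged=False`) rather than raising, since the result is still a valid lower-accuracy estimate |
| `k`        | cross-validation folds                    | 5       | pairs (not miRNAs or diseases) are the unit of fold assignment |

## Cross-validation protocol

For each fold the association matrix, the network and the seed vectors are
rebuilt from training pairs only; an internal assertion verifies the
rebuilt matrix is exactly zero at every held-out position. Positives for a
(disease, fold) evaluation are that disease's held-out pairs; negatives are
all miRNAs never associated with the disease anywhere in the dataset. No
negative sampling is performed — curated association sets have no verified
negatives, so "never observed" is the only available convention, and it
means some reported "false positives" may be real undiscovered
associations. A disease is skipped in a fold (with a warning) when it has
no training positive to seed from or no held-out positive to measure.

Both a per-disease AUC (that disease's scores concatenated across folds)
and a pooled global AUC (all scores concatenated) are reported, since a
single overall number and per-disease behavior answer different questions.
Raw steady-state scores are pooled without per-query renormalization;
score scales differ slightly across queries with different seed counts, so
the pooled AUC runs a little below the mean per-record AUC.

The ROC curve sweeps the threshold over every distinct score with a
strictly-greater comparison; the trapezoidal area then equals
P(score_pos > score_neg) + ½·P(tie) exactly, which the tests verify against
a brute-force pairwise computation and against scikit-learn.

## Synthetic benchmark

The generator plants the modeling hypothesis directly: miRNAs and diseases
are assigned round-robin to `n_modules` modules, module i of miRNAs is
matched one-to-one to module i of diseases, similarities are clipped-normal
with mean `sim_in` within modules and `sim_out` between (noise sd
`sim_noise`), and associations are Bernoulli with probability `p_in` for
matched pairs and `p_out` otherwise. Clipped-normal noise is the simplest
symmetric perturbation respecting the [0, 1] score range.

The default benchmark — 100 miRNAs, 20 diseases, 4 modules, sim_in/out =
0.6/0.1, noise 0.05, p_in/out = 0.5/0.01 — gives each disease ≈13 observed
associations, comfortably supporting five-fold cross-validation. The null
configuration used for calibration sets sim_in = sim_out = 0.3 and
p_in = p_out = 0.1: no planted signal, similar network density, ≈10
associations per disease so the CV protocol still runs.

What the generator does **not** emulate: the heavy-tailed degree
distribution of curated association databases, the empirical score
distribution of real similarity matrices, diseases sharing miRNAs across
modules, and annotation bias (well-studied diseases having more recorded
associations). Passing the benchmark shows the pipeline recovers clean
modular signal without leakage; it does not certify performance on real
data, where signal-to-noise and bias structure differ.

### Behavior under the benchmark, and the role of M

With full data the walk separates matched-module from cross-module miRNAs
perfectly (truth-recovery AUC 1.0). Under cross-validation the pooled AUC
plateaus near 0.90 for structural reasons: roughly half of each matched
module is unobserved and therefore counted as negatives that are
statistically exchangeable with the held-out positives, and a few
cross-module miRNAs are genuinely linked to the query's sibling diseases by
the `p_out` noise and correctly receive high scores. On this generator the
restart probability has almost no effect (paired M = 0.7 vs M = 0.1
difference of −0.0007 ± 0.006 over 50 seeds): local one-hop similarity and
global multi-hop structure carry the same module signal, so damping depth
is irrelevant. On real data, where long paths accumulate noise, moderate-
to-high M is the better-performing regime; reproducing that preference
requires noise structure this generator deliberately omits.

## Numerical choices and degenerate inputs

* Similarity files: asymmetries ≤ 1e-6 are repaired as (S+Sᵀ)/2 with a
  warning; larger asymmetry, values outside [0, 1] (beyond 1e-9 slack) or a
  non-unit diagonal are errors. Labels are case-sensitive and never
  normalized. Label order is fixed by lexicographic sort so matrix indices
  are reproducible for any input line order.
* The final walk vector is clipped at 0 and renormalized to absorb float
  drift before the simplex invariant is checked.
* An all-zero weight matrix is an "empty network" error; a single isolated
  vertex merely self-loops.
* An empty candidate set (every miRNA already known for the query) returns
  an empty ranking with a warning rather than an error.
* Ties in ranking and in ROC construction are handled deterministically
  (lexicographic ids; diagonal tie segments in the ROC).

## Known limitations

* Diseases without any known miRNA cannot be queried.
* Negatives in evaluation are unverified non-associations, so measured AUC
  understates performance whenever undiscovered true associations rank
  highly.
* Raw pooled scores are not calibrated across queries; use per-disease
  rankings, not cross-disease score comparisons.
* The synthetic benchmark is a clean planted-block world; conclusions about
  real curated datasets require the real similarity and association inputs.
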