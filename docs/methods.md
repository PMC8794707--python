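# Methods

`netsynergy` models how drugs act on a disease through a signed, directed
protein–protein interaction network, and how two drugs combine. It has
four computational layers — knowledge base, expression restrictions,
mechanism-of-action (MoA) ensemble sampling, and relationship scoring
with a combination decision layer — plus a synthetic-data layer that
generates every input with known ground truth. This note records the
models, the numerical choices, and what the validation does and does not
establish.

## The network model

A network is a set of proteins (keyed by UniProtKB accession) and signed
directed edges: +1 for activation, −1 for inhibition. Interaction files
are SIF-like TSV; the mapping from type tokens to signs is a *dialect*
table (default: `activates`/`stimulates`/`activation` → +1,
`inhibits`/`represses`/`inhibition` → −1) that callers can replace.
Records a dialect declares undirected expand into two directed edges of
the same sign, because propagation is inherently directed. Self-loops
are allowed and propagate like any other edge. Node insertion order is
the canonical order for all numeric work, which is what makes every
downstream computation bit-reproducible from the same input files.

## Signal propagation

Each protein carries an activity `s_i ∈ [−1, 1]`. A drug is a *stimulus*:
its target proteins are clamped at their action sign (+1 activated, −1
inhibited) every iteration. All other activities evolve towards a fixed
point of

    s_i = tanh( Σ_j w_ji · sign_ji · s_j + b_i )

where `w_ji ≥ 0` are per-edge weights, `sign_ji` the edge signs, and
`b_i` per-node biases. The hyperbolic tangent is chosen because it is
saturating, odd, and maps onto the required (−1, 1) codomain.

**Numerics.** The literal synchronous update of this map oscillates with
period 2 on most signed recurrent networks (a well-known property of
parallel-update Hopfield-type dynamics). We therefore iterate the damped
scheme

    s ← s + γ · ( tanh(W s + b) − s ),   γ = 0.5 by default,

whose fixed points are *identical* to the undamped map's and which
converges in practice in 20–60 steps. Convergence is declared when the
fixed-point residual `max_i |tanh(Ws+b)_i − s_i|` drops below `tol`
(default 1e−6) within `max_steps` (default 200). If the budget is hit,
the average of the last two iterates is returned and the activity map is
flagged `converged=False` — oscillation is reported, never hidden.
Correctness of the fixed points is checked against an independent dense
root finder (`scipy.optimize.root`) on random small networks in the
contraction regime, where the fixed point is provably unique; agreement
is required to 1e−9 and measured at ~1e−12.

## MoA ensemble sampling

A *solution* is one assignment of weights and biases. Solutions are
sampled by stochastic local search (simulated-annealing-style): weights
initialise from U(0.5, 1.4), biases near zero, and proposals mix
Gaussian perturbations of a random 15% of parameters with occasional
re-draws of a few weights. The objective blends the discrete compliance
accuracy with a hinge penalty `Σ max(0, δ − margin)/δ` that supplies
search signal from failing terms; δ = 0.1 is the compliance margin,
reusing the reversal magnitude threshold. During the search, propagation
runs at a coarse tolerance (1e−4, 80 steps) — enough to resolve signs
at the 0.1 threshold — and accepted parameters are re-evaluated at full
precision.

**Compliance.** A training pair (drug profile → effector states, with
causal or therapeutic polarity) is compliant when propagation of its
input gives every output effector the required sign (stated sign for
causal, negated for therapeutic) with magnitude ≥ δ. Accuracy is the
compliant fraction; expression restrictions, when supplied, each add one
term evaluated under the disease-condition simulation — soft terms
folded into accuracy, not hard clamps, so the search remains feasible
when restrictions conflict with the training set.

**Cross-validation and acceptance.** Each sampling attempt estimates a
cross-validated accuracy: pairs are split into deterministic folds by
index (`i mod k`, default k = 5), the search is re-run on each training
portion, and the held-out pairs are scored; the attempt's final model is
fit on all pairs. Attempts are accepted when the CV estimate reaches the
threshold (≥ 0.90 by default; the comparator is configurable). The
ensemble's per-protein mean activity over accepted solutions is the
*predicted protein activity*, and the induced subnetwork on proteins
with |mean activity| ≥ 0.01 is the drug's MoA subnetwork.

## Expression restrictions

Differential-expression tables enter at the statistics level (transcript
id, protein accession, log2 fold change, adjusted p). Records pass the
filter when `adj_p < 0.01` and `|logFC| > 2`, both strict. Passing
records collapse to one signed restriction per protein; proteins whose
transcripts disagree in direction are discarded and reported, and
zero-logFC records carry no direction. Rows without a protein mapping
are dropped with a count rather than guessed. The differential
statistics themselves are an upstream input (a GEO2R/limma export); the
package does not recompute them.

## Relationship scoring

A drug–motive relationship is summarised by network-proximity features:
the mean over targets of the shortest undirected hop distance to the
nearest effector (unreachable pairs use the node count as sentinel), a
z-score of that distance against random target sets matched within
logarithmic degree bins (positive = closer than chance), the
target–effector overlap fraction, and the two set sizes. A one-hidden-
layer feed-forward classifier (scikit-learn `MLPClassifier`, 8 tanh
units, L-BFGS) trained on labelled positive/negative (targets,
effectors) pairs converts features to a score = 100 × positive-class
probability.

Scores are banded lower-inclusively: ≥ 78 HIGH (+++, p < 0.05),
71–78 MEDIUM-HIGH (++), 47–71 MEDIUM (+), < 47 LOW (−, p ≥ 0.20). The
lower-inclusive reading resolves the published bands' overlapping
interval notation and is the only assignment consistent with the
published boundary cells (71 is "++", 47 is "+"). Empirical p-values can
also be calibrated per network as the right-tail fraction of scores from
random degree-matched target sets (step function, monotone
non-increasing; at least 100 null sets).

The scorer is trained on whole target profiles; single-target queries
reuse the same scorer, which may understate individual targets — a
documented property of this design, not corrected.

## Combination decision rules

*Drug level*: a combination is additive for a motive when its score
strictly exceeds both components' scores and reaches the HIGH band
(≥ 78). Ties are never additive. *Target level*: a target is selected
for a motive when its solo score already shows a positive predicted
relationship (≥ 47), the combination strictly improves on it, and the
combination is itself ≥ 47. The solo-score condition is required to
reproduce the published target table (it excludes targets whose
combination scores are high but whose solo relationship is absent).

*Reversal*: an effector is reversed by a treatment when the treatment's
activity has the opposite sign to the effector's disease state with
magnitude ≥ τ (default 0.1). For two treatments the motive's effectors
partition into both / A-only / B-only / neither; percentages are stored
at full precision and rounded half-up only at presentation, so the
partition identity (sum = 100) is exact. A-only/B-only statistics come
from separate monotherapy ensembles sampled with the same seed schedule —
an explicit choice where the original decomposition is ambiguous.

## Synthetic studies and what they show

The original study's numeric scores and percentages depend on a
proprietary network and training collection and are out of reach; the
package instead validates each statistic's *definition and recovery
behaviour* on synthetic studies with planted truth.

**Network**: preferential-attachment-flavoured signed digraphs — exact
edge count, endpoints drawn ∝ degree+1, inhibitory fraction as
specified.

**Disease**: per motive, a *primary regulator* is planted — a node of
moderate degree (≤ 85th percentile; mechanisms are dedicated pathways,
not promiscuous hubs) whose directed reach within 2 hops covers the
motive; depth and degree cap relax automatically for large motives
(the published-shape template with motives of 85/33/50/84/31 effectors
and 229 unique proteins generates on a 400-node network). Effectors are
drawn from that pool, with cross-motive sharing controlled either by an
expected overlap fraction or an exact union size. Disease signs come
from propagating a +1 stimulus on the primary regulators under freshly
drawn hidden parameters (weights U(0.6, 1.4), zero biases). Secondary
regulators covering ≥ half of the chosen effectors are added, so every
planted regulator reaches at least half its motive by directed paths.

**Drugs**: targets inhibit planted regulators of one motive (the sign
that reverses the disease stimulus), plus optional random decoys. The
drug's expected reversals are computed by hidden-parameter propagation
and recorded as ground truth.

**Training sets** emulate a curated pharmacology collection: a small
repertoire of target-disjoint stimulus profiles recurs across pairs
(a drug appears in several condition records; distinct drugs hit
distinct targets), and outputs are *robust* effects — hidden-parameter
activity ≥ 0.5 whose sign is reproduced at the 0.1 threshold by at least
7 of 8 random parameter draws from the model family. This mirrors the
fact that curated training knowledge records strong, replicated effects,
and it is what makes a ≥ 90% cross-validated accuracy achievable: fully
independent random pairs are not mutually predictive in this model
class (held-out compliance 0.4–0.8 even at perfect training fit, failing
by attractor sign flips under unseen stimuli).

**DE tables** are generated at the statistics level with exact
bookkeeping: a specified number of filter-passing rows, conflicted
proteins contributing two opposite-sign passing rows each, so the
expected restriction count is `n_pass − 2·n_conflicts`.

Seeding: every generator derives its stream from the caller's seed
through a declared per-generator counter, so adding a generator never
perturbs existing streams; benchmark sub-seeds derive from one master
seed via `numpy` `SeedSequence`.

**Benchmark conditions** (in `netsynergy.benchmarks`): the recovery
benchmark uses 30-node/110-edge networks, motives of 6 and 5 effectors,
a 3-target decoy-free drug, 20 training pairs over 3 stimuli with one
output each, 5-fold CV at threshold 0.9, ensembles of 100 accepted
solutions, medians over 5 studies. The planted-score benchmark uses
300-node/480-edge networks (sparse enough that proximity is
informative), a scorer trained on 10 planted-positive vs 10
random-negative pairs, 100 degree-matched null sets, medians over 20
studies. These sizes keep a full validation run within a few minutes on
one CPU while leaving each statistic's behaviour measurable.

**What passing shows — and does not.** Passing establishes that the
implemented definitions are internally correct (oracle agreement,
partition identities, bookkeeping), and that when the data-generating
process matches the model class, the pipeline recovers planted
mechanisms (median reversal recall ≥ 80% with ≈ 0 false reversals) and
distinguishes planted drugs from degree-matched chance (median ≥ 95th
percentile). It does not show that real curated networks satisfy these
assumptions: real interaction signs are noisy and incomplete, real
training knowledge is biased towards studied pathways, and real
regulators need not sit two hops above their effectors. Individual
synthetic studies can also be degenerate (a drug with almost no true
reversals); the medians absorb these by design.

## Known limitations

- The propagation model is one declared realisation of a
  perceptron-over-network family; layer structure, update rule and
  solution count of the original methodology are not public.
- Whether expression restrictions were hard or soft constraints in the
  original models is unstated; soft terms are our choice.
- The stochastic search has no optimality guarantee; acceptance rates
  degrade on training sets with strong differential-response structure
  (stimuli sharing targets but requiring opposite outcomes).
- Undirected proximity features cannot express upstream/downstream
  direction; a mechanism planted on high-degree hubs in a dense graph is
  invisible to them.
- Score bands and their p-values are taken from the published
  calibration; the package's own empirical calibration is network-
  specific and will not reproduce those published p-values.
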