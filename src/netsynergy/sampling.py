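"""Ensemble sampling of signed signal-propagation models (mechanism of
action, "MoA", models).

The network is treated as a recurrent perceptron-like system: each
protein carries an activity in [-1, 1], evolving towards a fixed point
of the synchronous map

    s_i  =  tanh( sum_j  w_ji * sign_ji * s_j  +  b_i )

from an all-zero start, with drug-target (stimulus) proteins clamped at
their action sign (the iteration is damped — see :func:`_iterate` — so
it settles on a fixed point of this map rather than oscillating).
A *solution* is one assignment of non-negative edge
weights and node biases.  Solutions are drawn by stochastic local search
(simulated-annealing-style perturbations) so that propagation complies
with a training set of known input->output signal pairs, accepted only
when their cross-validated accuracy clears a threshold; the retained
ensemble's mean activities are the predicted protein activities that
define the drug's MoA subnetwork.

Expression restrictions enter as soft compliance terms: the
disease-condition simulation must reproduce each restriction's sign, and
each restriction contributes one term to the accuracy alongside the
training pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence, Union

import numpy as np

from .errors import (
    EmptyEnsembleError,
    EmptyTrainingSetError,
    MissingTargetProteinError,
    NoCompliantSolutionError,
)
from .expression import ExpressionRestriction
from .knowledge_base import (
    DrugTargetProfile,
    EffectorState,
    ProteinNetwork,
    ProteinRef,
    write_graphml,
)

__all__ = [
    "PropagationParameters",
    "ActivityMap",
    "TrainingPair",
    "MoASolution",
    "MoAEnsemble",
    "MoANetwork",
    "propagate",
    "evaluate_solution_accuracy",
    "sample_solutions",
    "aggregate_activities",
    "extract_moa_subnetwork",
    "random_parameters",
    "save_ensemble",
    "load_ensemble",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_STEPS = 200
DEFAULT_DELTA = 0.1  # compliance / reversal magnitude threshold


@dataclass
class PropagationParameters:
    """Per-edge weights and per-node biases of one propagation model.

    ``weights`` aligns with ``network.edges`` and ``biases`` with
    ``network.node_order``.  Weights are magnitudes (>= 0); the edge sign
    is carried by the network itself.  ``transfer`` is a saturating odd
    function mapping onto (-1, 1); the hyperbolic tangent by default.
    """

    weights: np.ndarray
    biases: np.ndarray
    transfer: Callable[[np.ndarray], np.ndarray] = np.tanh
    max_steps: int = DEFAULT_MAX_STEPS
    tol: float = DEFAULT_TOL
    damping: float = 0.5

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("edge weights must be finite and non-negative")
        if not np.all(np.isfinite(self.biases)):
            raise ValueError("node biases must be finite")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must lie in (0, 1]")

    def copy(self) -> "PropagationParameters":
        return PropagationParameters(
            self.weights.copy(),
            self.biases.copy(),
            self.transfer,
            self.max_steps,
            self.tol,
            self.damping,
        )


def random_parameters(
    network: ProteinNetwork,
    rng: np.random.Generator,
    weight_low: float = 0.4,
    weight_high: float = 1.4,
    bias_scale: float = 0.05,
    **kwargs,
) -> PropagationParameters:
    """Random initial parameters: weights ~ U(low, high), small biases."""
    return PropagationParameters(
        weights=rng.uniform(weight_low, weight_high, network.n_edges),
        biases=rng.normal(0.0, bias_scale, network.n_nodes),
        **kwargs,
    )


@dataclass
class ActivityMap:
    """Per-protein predicted activity in [-1, 1].

    ``converged`` is False when the synchronous iteration hit its step
    budget; the returned values are then the average of the last two
    iterates (oscillation is reported, never hidden).
    """

    activities: dict[str, float]
    converged: bool = True

    def __getitem__(self, accession: str) -> float:
        return self.activities[accession]

    def get(self, accession: str, default: float | None = None):
        return self.activities.get(accession, default)

    def __contains__(self, accession: str) -> bool:
        return accession in self.activities

    def items(self):
        return self.activities.items()

    def __len__(self):
        return len(self.activities)


@dataclass(frozen=True)
class TrainingPair:
    """A known input (drug) -> output (condition effectors) signal pair.

    ``polarity`` is ``"causal"`` when the drug induces the listed states
    and ``"therapeutic"`` when it reverses them.
    """

    input: DrugTargetProfile
    output: tuple[EffectorState, ...]
    polarity: str = "causal"

    def __init__(self, input, output, polarity="causal"):
        output = tuple(output)
        if not output:
            raise ValueError("training pair output must be non-empty")
        if polarity not in ("causal", "therapeutic"):
            raise ValueError(f"unknown polarity {polarity!r}")
        object.__setattr__(self, "input", input)
        object.__setattr__(self, "output", output)
        object.__setattr__(self, "polarity", polarity)


@dataclass
class MoASolution:
    params: PropagationParameters
    accuracy: float
    cv_accuracy: float

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.cv_accuracy <= 1.0):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class MoAEnsemble:
    """Accepted propagation solutions for one stimulus."""

    solutions: list[MoASolution]
    stimulus: DrugTargetProfile | None
    restrictions: tuple[ExpressionRestriction, ...]
    seed: int
    n_attempts: int = 0


# ---------------------------------------------------------------------------
# Propagation core
# ---------------------------------------------------------------------------

def _signed_incidence(network: ProteinNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edge (source_idx, target_idx, sign) arrays in canonical edge order."""
    idx = network.node_index()
    src = np.fromiter(
        (idx[e.source.accession] for e in network.edges), dtype=int,
        count=network.n_edges,
    )
    dst = np.fromiter(
        (idx[e.target.accession] for e in network.edges), dtype=int,
        count=network.n_edges,
    )
    sgn = np.fromiter((e.sign for e in network.edges), dtype=float,
                      count=network.n_edges)
    return src, dst, sgn


def _propagation_matrix(
    network: ProteinNetwork, params: PropagationParameters
) -> np.ndarray:
    """Dense matrix M with M[i, j] = sum of w*sign over edges j -> i."""
    n = network.n_nodes
    m = np.zeros((n, n))
    src, dst, sgn = _signed_incidence(network)
    np.add.at(m, (dst, src), params.weights * sgn)
    return m


def _iterate(
    m: np.ndarray,
    biases: np.ndarray,
    clamp_mask: np.ndarray,
    clamp_values: np.ndarray,
    transfer: Callable,
    max_steps: int,
    tol: float,
    damping: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Damped synchronous iteration from zero; supports a batch of columns.

    Each step moves the state a fraction ``damping`` towards the
    synchronous update ``transfer(M s + b)``; the fixed points are those
    of the undamped map, but damping suppresses the period-2 oscillation
    recurrent signed networks are prone to.  ``clamp_mask``/``clamp_values``
    have shape (n, k): clamped entries are held fixed every step.
    Convergence is declared when the fixed-point residual
    ``max |transfer(M s + b) - s|`` over free entries drops below
    ``tol``.  Returns (state (n, k), converged); a non-converged state is
    the average of the last two iterates.
    """
    state = np.where(clamp_mask, clamp_values, 0.0)
    prev = state
    b = biases[:, None]
    for _ in range(max_steps):
        target = transfer(m @ state + b)
        target = np.where(clamp_mask, clamp_values, target)
        if np.max(np.abs(target - state)) < tol:
            return state, True
        prev = state
        state = state + damping * (target - state)
    return (state + prev) / 2.0, False


def _clamp_column(
    network: ProteinNetwork,
    stimulus: DrugTargetProfile | None,
    clamps: Sequence[tuple[str, float]] = (),
) -> tuple[np.ndarray, np.ndarray]:
    idx = network.node_index()
    n = len(idx)
    mask = np.zeros(n, dtype=bool)
    vals = np.zeros(n)
    if stimulus is not None:
        for protein, action in stimulus.targets:
            j = idx.get(protein.accession)
            if j is None:
                raise MissingTargetProteinError(
                    f"stimulus protein {protein.accession} not in network"
                )
            mask[j] = True
            vals[j] = float(action)
    for acc, value in clamps:
        acc = acc.accession if hasattr(acc, "accession") else acc
        j = idx.get(acc)
        if j is None:
            raise MissingTargetProteinError(f"clamp protein {acc} not in network")
        if not (-1.0 <= value <= 1.0):
            raise ValueError("clamp values must lie in [-1, 1]")
        mask[j] = True
        vals[j] = float(value)
    return mask, vals


def propagate(
    network: ProteinNetwork,
    params: PropagationParameters,
    stimulus: DrugTargetProfile | None = None,
    clamps: Sequence[tuple[str, float]] = (),
) -> ActivityMap:
    """Propagate a stimulus through the network under one parameter set.

    Stimulus proteins are held at their action sign (+1/-1) every
    iteration; additional ``clamps`` hold proteins at arbitrary values in
    [-1, 1].  Deterministic for fixed inputs; all outputs lie in [-1, 1].
    """
    mask, vals = _clamp_column(network, stimulus, clamps)
    m = _propagation_matrix(network, params)
    state, converged = _iterate(
        m, params.biases, mask[:, None], vals[:, None],
        params.transfer, params.max_steps, params.tol, params.damping,
    )
    acts = dict(zip(network.node_order, np.clip(state[:, 0], -1.0, 1.0)))
    return ActivityMap(acts, converged)


# ---------------------------------------------------------------------------
# Training-set compliance
# ---------------------------------------------------------------------------

class _CompiledTerms:
    """Training pairs + restrictions pre-indexed for fast re-evaluation.

    One batch column per training pair (its stimulus clamps) plus, when
    restrictions are present, one column for the disease-condition
    simulation.  Each *term* is (column, node, required sign); a term
    complies when required_sign * activity >= delta.
    """

    def __init__(
        self,
        network: ProteinNetwork,
        training_set: Sequence[TrainingPair],
        restrictions: Sequence[ExpressionRestriction] = (),
        disease_stimulus: DrugTargetProfile | None = None,
        delta: float = DEFAULT_DELTA,
    ):
        if not training_set and not restrictions:
            raise EmptyTrainingSetError("no training pairs and no restrictions")
        idx = network.node_index()
        n = network.n_nodes
        self.network = network
        self.delta = float(delta)
        self.n_pairs = len(training_set)

        cols: list[tuple[np.ndarray, np.ndarray]] = []
        pair_terms: list[tuple[int, int, float]] = []  # (col, node, req_sign)
        for k, pair in enumerate(training_set):
            mask, vals = _clamp_column(network, pair.input)
            cols.append((mask, vals))
            flip = -1.0 if pair.polarity == "therapeutic" else 1.0
            for st in pair.output:
                j = idx.get(st.protein.accession)
                if j is None:
                    raise MissingTargetProteinError(
                        f"output effector {st.protein.accession} not in network"
                    )
                pair_terms.append((k, j, flip * st.disease_sign))

        self.restriction_terms: list[tuple[int, int, float]] = []
        if restrictions:
            if disease_stimulus is None:
                raise ValueError(
                    "restrictions require a disease_stimulus to simulate"
                )
            mask, vals = _clamp_column(network, disease_stimulus)
            cols.append((mask, vals))
            rcol = len(cols) - 1
            for r in restrictions:
                j = idx.get(r.protein.accession)
                if j is None:
                    continue  # restriction outside the network: no term
                self.restriction_terms.append((rcol, j, float(r.sign)))

        self.clamp_mask = np.stack([c[0] for c in cols], axis=1)
        self.clamp_vals = np.stack([c[1] for c in cols], axis=1)
        pt = np.array(pair_terms, dtype=float).reshape(-1, 3)
        self.pt_col = pt[:, 0].astype(int)
        self.pt_node = pt[:, 1].astype(int)
        self.pt_sign = pt[:, 2]
        self.pair_of_term = self.pt_col  # one column per pair by layout
        self.n_terms = self.n_pairs + len(self.restriction_terms)

    def evaluate(self, params: PropagationParameters) -> tuple[float, float]:
        """Return (accuracy, hinge penalty).

        Accuracy is the compliant fraction over terms: each training pair
        is one term (compliant when *all* its outputs comply) and each
        in-network restriction is one term.  The hinge penalty sums
        ``max(0, delta - margin) / delta`` over output terms — zero for a
        fully compliant solution — and is used only to guide the search.
        """
        m = _propagation_matrix(self.network, params)
        state, _ = _iterate(
            m, params.biases, self.clamp_mask, self.clamp_vals,
            params.transfer, params.max_steps, params.tol, params.damping,
        )
        margins = []
        n_ok = 0
        if self.n_pairs:
            out_margin = self.pt_sign * state[self.pt_node, self.pt_col]
            ok = out_margin >= self.delta
            pair_ok = np.ones(self.n_pairs, dtype=bool)
            np.logical_and.at(pair_ok, self.pair_of_term, ok)
            n_ok += int(pair_ok.sum())
            margins.append(out_margin)
        for col, node, sign in self.restriction_terms:
            mgn = sign * state[node, col]
            n_ok += bool(mgn >= self.delta)
            margins.append(np.array([mgn]))
        allm = np.concatenate(margins) if margins else np.array([self.delta])
        hinge = float(
            np.clip(self.delta - allm, 0.0, None).sum() / self.delta
        )
        return n_ok / self.n_terms, hinge

    def pair_compliance(self, params: PropagationParameters) -> np.ndarray:
        """Boolean compliance per training pair (restrictions excluded)."""
        m = _propagation_matrix(self.network, params)
        state, _ = _iterate(
            m, params.biases, self.clamp_mask, self.clamp_vals,
            params.transfer, params.max_steps, params.tol, params.damping,
        )
        out_margin = self.pt_sign * state[self.pt_node, self.pt_col]
        ok = out_margin >= self.delta
        pair_ok = np.ones(self.n_pairs, dtype=bool)
        np.logical_and.at(pair_ok, self.pair_of_term, ok)
        return pair_ok


def evaluate_solution_accuracy(
    params: PropagationParameters,
    training_set: Sequence[TrainingPair],
    network: ProteinNetwork,
    delta: float = DEFAULT_DELTA,
    restrictions: Sequence[ExpressionRestriction] = (),
    disease_stimulus: DrugTargetProfile | None = None,
) -> float:
    """Fraction of compliant input->output relationships.

    A training pair complies when, after propagating its input, every
    output effector's activity matches the required sign (the stated sign
    for causal pairs, its negation for therapeutic pairs) with magnitude
    >= ``delta``.  Restrictions, when given, add one term each, evaluated
    under the ``disease_stimulus`` simulation.
    """
    if not training_set:
        raise EmptyTrainingSetError("training set is empty")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    terms = _CompiledTerms(
        network, training_set, restrictions, disease_stimulus, delta
    )
    return terms.evaluate(params)[0]


# ---------------------------------------------------------------------------
# Stochastic solution sampling
# ---------------------------------------------------------------------------

#: Propagation settings used while searching: coarser than the final
#: evaluation, enough to resolve sign and the 0.1 magnitude threshold.
_SEARCH_MAX_STEPS = 80
_SEARCH_TOL = 1e-4


def _anneal(
    terms: _CompiledTerms,
    network: ProteinNetwork,
    rng: np.random.Generator,
    n_iter: int,
    max_steps: int,
    tol: float,
) -> tuple[PropagationParameters, float]:
    """Simulated-annealing-style local search maximising compliance.

    The objective blends the discrete accuracy with a clipped-margin soft
    score that provides search signal below the compliance threshold.
    Candidates are evaluated with coarse propagation settings for speed;
    the returned parameters carry the caller's ``max_steps``/``tol`` and
    the returned accuracy is re-measured at that full precision.
    """
    params = random_parameters(
        network, rng,
        weight_low=0.5, weight_high=1.4, bias_scale=0.02,
        max_steps=_SEARCH_MAX_STEPS, tol=_SEARCH_TOL,
    )
    n_e, n_n = network.n_edges, network.n_nodes
    acc, hinge = terms.evaluate(params)
    score = acc - 0.02 * hinge
    best, best_acc = params.copy(), acc
    t0, t1 = 0.1, 0.005
    it = 0
    while best_acc < 1.0 and it < n_iter:
        temp = t0 * (t1 / t0) ** (it / max(n_iter - 1, 1))
        cand = params.copy()
        if rng.random() < 0.2:
            # exploration move: re-draw a few weights from the prior
            k = max(1, n_e // 10)
            which = rng.integers(0, n_e, size=k)
            cand.weights[which] = rng.uniform(0.0, 1.6, size=k)
        else:
            k = max(1, int(0.15 * (n_e + n_n)))
            which = rng.integers(0, n_e + n_n, size=k)
            step = rng.normal(0.0, 0.25 * temp / t0 + 0.08, size=k)
            for w, s in zip(which, step):
                if w < n_e:
                    cand.weights[w] = max(0.0, cand.weights[w] + s)
                else:
                    cand.biases[w - n_e] = float(
                        np.clip(cand.biases[w - n_e] + s, -0.5, 0.5)
                    )
        c_acc, c_hinge = terms.evaluate(cand)
        c_score = c_acc - 0.02 * c_hinge
        if c_score >= score or rng.random() < np.exp((c_score - score) / temp):
            params, score = cand, c_score
            if c_acc > best_acc:
                best, best_acc = cand.copy(), c_acc
        it += 1
    best.max_steps = max_steps
    best.tol = tol
    best_acc = terms.evaluate(best)[0]
    return best, best_acc


def _cv_folds(n_pairs: int, cv_folds: int) -> list[np.ndarray]:
    """Deterministic stratified-by-index folds: fold f gets pairs i with
    i % cv_folds == f."""
    idx = np.arange(n_pairs)
    return [idx[idx % cv_folds == f] for f in range(cv_folds)]


def sample_solutions(
    network: ProteinNetwork,
    training_set: Sequence[TrainingPair],
    n_accept: int,
    seed: int,
    cv_folds: int = 5,
    accuracy_threshold: float = 0.90,
    restrictions: Sequence[ExpressionRestriction] = (),
    disease_stimulus: DrugTargetProfile | None = None,
    stimulus: DrugTargetProfile | None = None,
    delta: float = DEFAULT_DELTA,
    n_iter: int = 500,
    n_iter_cv: int | None = None,
    max_attempts: int | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    tol: float = DEFAULT_TOL,
    threshold_comparator: str = ">=",
) -> MoAEnsemble:
    """Draw an ensemble of training-compliant propagation solutions.

    Each attempt runs an independent stochastic local search; its
    cross-validated accuracy is estimated by re-running the search on
    ``cv_folds - 1`` folds and scoring the held-out pairs, and the
    attempt is accepted when that estimate clears ``accuracy_threshold``
    (``>=`` by default; set ``threshold_comparator=">"`` for a strict
    comparison).  ``cv_folds=1`` skips cross-validation and uses the
    training accuracy directly.  Reproducible for a fixed ``seed``.
    """
    if n_accept < 1:
        raise ValueError("n_accept must be >= 1")
    if cv_folds < 1:
        raise ValueError("cv_folds must be >= 1")
    if not training_set:
        raise EmptyTrainingSetError("training set is empty")
    cmp = {
        ">=": lambda a, b: a >= b,
        ">": lambda a, b: a > b,
    }[threshold_comparator]
    training_set = list(training_set)
    n_pairs = len(training_set)
    cv_folds = min(cv_folds, n_pairs)
    full_terms = _CompiledTerms(
        network, training_set, restrictions, disease_stimulus, delta
    )
    folds = _cv_folds(n_pairs, cv_folds) if cv_folds > 1 else []
    fold_terms = [
        (
            _CompiledTerms(
                network,
                [training_set[i] for i in np.setdiff1d(np.arange(n_pairs), held)],
                restrictions,
                disease_stimulus,
                delta,
            ),
            held,
        )
        for held in folds
        if len(held) and len(held) < n_pairs
    ]

    if max_attempts is None:
        max_attempts = max(4 * n_accept, 20)
    if n_iter_cv is None:
        n_iter_cv = n_iter
    solutions: list[MoASolution] = []
    best_seen = 0.0
    attempts = 0
    while len(solutions) < n_accept and attempts < max_attempts:
        attempt_ss = np.random.SeedSequence(seed, spawn_key=(attempts,))
        streams = attempt_ss.spawn(len(fold_terms) + 1)
        if fold_terms:
            held_ok = 0
            for (tr_terms, held), ss in zip(fold_terms, streams[:-1]):
                fold_params, _ = _anneal(
                    tr_terms, network, np.random.default_rng(ss),
                    n_iter_cv, max_steps, tol,
                )
                comp = full_terms.pair_compliance(fold_params)
                held_ok += int(comp[held].sum())
            cv_acc = held_ok / n_pairs
        else:
            cv_acc = None
        final_params, train_acc = _anneal(
            full_terms, network, np.random.default_rng(streams[-1]),
            n_iter, max_steps, tol,
        )
        if cv_acc is None:
            cv_acc = train_acc
        best_seen = max(best_seen, cv_acc)
        attempts += 1
        if cmp(cv_acc, accuracy_threshold):
            solutions.append(MoASolution(final_params, train_acc, cv_acc))
    if not solutions:
        raise NoCompliantSolutionError(best_seen)
    return MoAEnsemble(
        solutions=solutions,
        stimulus=stimulus,
        restrictions=tuple(restrictions),
        seed=seed,
        n_attempts=attempts,
    )


# ---------------------------------------------------------------------------
# Ensemble aggregation and MoA subnetwork
# ---------------------------------------------------------------------------

def aggregate_activities(
    ensemble: MoAEnsemble,
    network: ProteinNetwork,
    stimulus: DrugTargetProfile | None = None,
) -> ActivityMap:
    """Per-protein arithmetic mean of propagation over all accepted
    solutions, under ``stimulus`` (defaulting to the ensemble's)."""
    if not ensemble.solutions:
        raise EmptyEnsembleError("ensemble has no accepted solutions")
    stimulus = stimulus if stimulus is not None else ensemble.stimulus
    total = np.zeros(network.n_nodes)
    converged = True
    for sol in ensemble.solutions:
        amap = propagate(network, sol.params, stimulus)
        total += np.fromiter(
            (amap[acc] for acc in network.node_order),
            dtype=float, count=network.n_nodes,
        )
        converged &= amap.converged
    mean = total / len(ensemble.solutions)
    return ActivityMap(dict(zip(network.node_order, mean)), converged)


@dataclass
class MoANetwork:
    """An MoA subnetwork: nodes with non-null predicted activity."""

    network: ProteinNetwork
    activity: dict[str, float]

    def to_graphml(self, path: Union[str, Path]) -> None:
        write_graphml(self.network, path, {"activity": self.activity})

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["protein\tmean_activity"]
        lines += [
            f"{acc}\t{self.activity[acc]:.6f}"
            for acc in self.network.node_order
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def extract_moa_subnetwork(
    network: ProteinNetwork,
    mean_activity: ActivityMap | Mapping[str, float],
    nonnull_delta: float = 0.01,
) -> MoANetwork:
    """Induced subnetwork on proteins with |mean activity| >= nonnull_delta."""
    if nonnull_delta < 0:
        raise ValueError("nonnull_delta must be >= 0")
    items = (
        mean_activity.items()
        if hasattr(mean_activity, "items")
        else dict(mean_activity).items()
    )
    keep = {
        acc: val
        for acc, val in items
        if abs(val) >= nonnull_delta and acc in network
    }
    return MoANetwork(network.induced_subnetwork(keep), keep)


# ---------------------------------------------------------------------------
# Ensemble serialisation (single JSON archive)
# ---------------------------------------------------------------------------

def load_ensemble(
    path: Union[str, Path],
    stimulus: DrugTargetProfile | None = None,
) -> MoAEnsemble:
    """Load an ensemble archive written by :func:`save_ensemble`.

    The stimulus profile is stored by name only; pass the profile object
    to re-attach it for aggregation.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    restrictions = tuple(
        ExpressionRestriction(ProteinRef(r["accession"]), r["sign"])
        for r in doc["restrictions"]
    )
    solutions = [
        MoASolution(
            PropagationParameters(
                np.asarray(s["weights"]),
                np.asarray(s["biases"]),
                max_steps=s["max_steps"],
                tol=s["tol"],
            ),
            s["accuracy"],
            s["cv_accuracy"],
        )
        for s in doc["solutions"]
    ]
    return MoAEnsemble(
        solutions=solutions,
        stimulus=stimulus,
        restrictions=restrictions,
        seed=doc["seed"],
        n_attempts=doc.get("n_attempts", 0),
    )


def save_ensemble(ensemble: MoAEnsemble, path: Union[str, Path]) -> None:
    doc = {
        "seed": ensemble.seed,
        "n_attempts": ensemble.n_attempts,
        "stimulus": ensemble.stimulus.drug_name if ensemble.stimulus else None,
        "restrictions": [
            {"accession": r.protein.accession, "sign": r.sign}
            for r in ensemble.restrictions
        ],
        "solutions": [
            {
                "weights": sol.params.weights.tolist(),
                "biases": sol.params.biases.tolist(),
                "max_steps": sol.params.max_steps,
                "tol": sol.params.tol,
                "accuracy": sol.accuracy,
                "cv_accuracy": sol.cv_accuracy,
            }
            for sol in ensemble.solutions
        ],
    }
    Path(path).write_text(json.dumps(doc) + "\n", encoding="utf-8")
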