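"""Target-set <-> effector-set relationship scoring.

A drug's target set and a motive's effector set are summarised by
network-proximity features (shortest undirected distances, a z-score
against degree-matched random target sets, and set overlap); a small
feed-forward classifier trained on known positive and negative
(drug, condition) pairs converts the features into a 0-100 relationship
score, read as 100 x the estimated probability of a functional
relationship.  Scores are banded into the categories

    >= 78          HIGH         (+++)   p < 0.05
    71 - 78        MEDIUM-HIGH  (++)    0.05 - 0.10
    47 - 71        MEDIUM       (+)     0.10 - 0.20
    <  47          LOW          (-)     p >= 0.20

with lower-inclusive boundaries (a score of exactly 71 is "++" and 47 is
"+").  Empirical p-values may also be calibrated per network from random
degree-matched target sets.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import (
    DegenerateTrainingSetError,
    EmptySetError,
    InsufficientNullError,
    InvalidScoreError,
)
from .knowledge_base import ProteinNetwork

__all__ = [
    "ProximityFeatures",
    "RelationshipScore",
    "ScoreCalibration",
    "RelationshipScorer",
    "BAND_THRESHOLDS",
    "CATEGORY_P_BANDS",
    "categorize_score",
    "p_band_for_category",
    "compute_proximity_features",
    "train_relationship_scorer",
    "score_relationship",
    "calibrate_score_pvalues",
]

#: Score band thresholds: (high, medium_high, medium), lower-inclusive.
BAND_THRESHOLDS: tuple[float, float, float] = (78.0, 71.0, 47.0)

#: Canonical p-value band per category.
CATEGORY_P_BANDS: dict[str, str] = {
    "+++": "<0.05",
    "++": "0.05-0.10",
    "+": "0.10-0.20",
    "-": ">=0.20",
}


def categorize_score(
    value: float, thresholds: tuple[float, float, float] = BAND_THRESHOLDS
) -> str:
    """Band a 0-100 score: ``+++``, ``++``, ``+`` or ``-``.

    Boundaries are lower-inclusive: ``>=78 -> +++``, ``[71, 78) -> ++``,
    ``[47, 71) -> +``, ``<47 -> -``.
    """
    if not (0.0 <= value <= 100.0):
        raise InvalidScoreError(f"score {value!r} outside [0, 100]")
    high, med_high, med = thresholds
    if value >= high:
        return "+++"
    if value >= med_high:
        return "++"
    if value >= med:
        return "+"
    return "-"


def p_band_for_category(category: str) -> str:
    return CATEGORY_P_BANDS[category]


@dataclass(frozen=True)
class ProximityFeatures:
    """Network-proximity summary of a (targets, effectors) pair.

    ``mean_min_distance`` averages, over mapped targets, the shortest
    undirected hop count to the nearest mapped effector; pairs in
    disjoint components use the sentinel distance = network node count.
    ``degree_matched_z`` is positive when the targets sit closer to the
    effectors than degree-matched random sets.
    """

    mean_min_distance: float
    degree_matched_z: float
    overlap_fraction: float
    target_count: int
    effector_count: int

    def __post_init__(self):
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.mean_min_distance < 0:
            raise ValueError("mean_min_distance must be >= 0")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                1.0 / (1.0 + self.mean_min_distance),
                float(np.clip(self.degree_matched_z, -10.0, 10.0)),
                self.overlap_fraction,
                math.log1p(self.target_count),
                math.log1p(self.effector_count),
            ]
        )


@dataclass(frozen=True)
class RelationshipScore:
    value: float
    category: str
    p_band: str

    def __post_init__(self):
        if not (0.0 <= self.value <= 100.0):
            raise InvalidScoreError(f"score {self.value!r} outside [0, 100]")


@dataclass
class ScoreCalibration:
    """Empirical score -> p mapping from a null of random target sets.

    ``p_value(s)`` is the fraction of null scores >= s: a right-tail
    step function, monotone non-increasing in the score.
    """

    null_scores: np.ndarray
    band_thresholds: tuple[float, float, float] = BAND_THRESHOLDS

    def __post_init__(self):
        self.null_scores = np.sort(np.asarray(self.null_scores, dtype=float))
        h, mh, m = self.band_thresholds
        if not (h > mh > m):
            raise ValueError("band thresholds must be strictly decreasing")

    @property
    def n_null(self) -> int:
        return len(self.null_scores)

    def p_value(self, score: float) -> float:
        n = self.n_null
        return float(n - np.searchsorted(self.null_scores, score, "left")) / n


# ---------------------------------------------------------------------------
# Proximity features
# ---------------------------------------------------------------------------

def _accessions(proteins: Iterable) -> set[str]:
    return {
        p.accession if hasattr(p, "accession") else str(p) for p in proteins
    }


def _multi_source_hops(network: ProteinNetwork, sources: set[str]) -> dict[str, int]:
    """Hop distance of every node to the nearest source (undirected BFS)."""
    adj: dict[str, list[str]] = {a: [] for a in network.node_order}
    for e in network.edges:
        s, t = e.source.accession, e.target.accession
        adj[s].append(t)
        adj[t].append(s)
    dist = {a: 0 for a in sources}
    queue = deque(sources)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _degree_bins(network: ProteinNetwork, base: float = 2.0) -> dict[str, int]:
    """Nodes binned by floor(log2(1 + undirected degree))."""
    deg = {a: 0 for a in network.node_order}
    for e in network.edges:
        deg[e.source.accession] += 1
        deg[e.target.accession] += 1
    return {
        a: int(math.floor(math.log(1 + d, base))) for a, d in deg.items()
    }


def _matched_random_set(
    members: Sequence[str],
    bins: Mapping[str, int],
    by_bin: Mapping[int, Sequence[str]],
    rng: np.random.Generator,
) -> list[str]:
    """Replace each member by a random node from the same degree bin."""
    out = []
    for a in members:
        pool = by_bin[bins[a]]
        out.append(pool[rng.integers(len(pool))])
    return out


def compute_proximity_features(
    network: ProteinNetwork,
    targets: Iterable,
    effectors: Iterable,
    n_null: int = 1000,
    seed: int = 0,
    _hops: Mapping[str, int] | None = None,
) -> ProximityFeatures:
    """Proximity features of a target set against an effector set.

    Distances are hop counts on the undirected view of the network;
    unreachable targets use the sentinel distance = node count.  The
    degree-matched z-score compares the observed mean distance with
    ``n_null`` random target sets of the same size drawn from logarithmic
    degree bins (positive z = closer than random).  A precomputed
    effector-distance map may be passed to amortise repeated calls.
    """
    t_all = _accessions(targets)
    e_all = _accessions(effectors)
    if not t_all or not e_all:
        raise EmptySetError("target and effector sets must be non-empty")
    t_map = sorted(a for a in t_all if a in network)
    e_map = sorted(a for a in e_all if a in network)
    if not t_map or not e_map:
        raise EmptySetError(
            "no member of the target or effector set maps to the network"
        )
    sentinel = float(network.n_nodes)
    hops = _multi_source_hops(network, set(e_map)) if _hops is None else _hops

    def mean_dist(members: Sequence[str]) -> float:
        return float(
            np.mean([hops.get(a, sentinel) for a in members])
        )

    observed = mean_dist(t_map)
    bins = _degree_bins(network)
    by_bin: dict[int, list[str]] = {}
    for a, b in bins.items():
        by_bin.setdefault(b, []).append(a)
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            mean_dist(_matched_random_set(t_map, bins, by_bin, rng))
            for _ in range(n_null)
        ]
    )
    sd = float(null.std())
    z = 0.0 if sd == 0 else float((null.mean() - observed) / sd)
    return ProximityFeatures(
        mean_min_distance=observed,
        degree_matched_z=z,
        overlap_fraction=len(set(t_map) & set(e_map)) / len(t_map),
        target_count=len(t_map),
        effector_count=len(e_map),
    )


# ---------------------------------------------------------------------------
# Scorer
# ---------------------------------------------------------------------------

@dataclass
class RelationshipScorer:
    """A trained feature -> score predictor with optional calibration."""

    model: Pipeline
    n_null_features: int
    seed: int
    calibration: ScoreCalibration | None = None

    #: Archive format version (bumped when the feature spec changes).
    FORMAT_VERSION = 1

    def score_features(self, features: ProximityFeatures) -> float:
        proba = self.model.predict_proba(features.to_vector()[None, :])[0, 1]
        return float(100.0 * proba)

    def save(self, path) -> None:
        """Persist as a single versioned archive (weights + calibration)."""
        import joblib

        joblib.dump(
            {
                "format_version": self.FORMAT_VERSION,
                "model": self.model,
                "n_null_features": self.n_null_features,
                "seed": self.seed,
                "null_scores": (
                    None
                    if self.calibration is None
                    else self.calibration.null_scores
                ),
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "RelationshipScorer":
        import joblib

        doc = joblib.load(path)
        if doc.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(
                f"unsupported scorer archive version "
                f"{doc.get('format_version')!r}"
            )
        calibration = (
            None
            if doc["null_scores"] is None
            else ScoreCalibration(doc["null_scores"])
        )
        return cls(
            doc["model"], doc["n_null_features"], doc["seed"], calibration
        )


def _features_for_pairs(
    network: ProteinNetwork,
    pairs: Sequence[tuple[Iterable, Iterable]],
    n_null: int,
    seed: int,
) -> np.ndarray:
    rows = []
    for i, (targets, effectors) in enumerate(pairs):
        f = compute_proximity_features(
            network, targets, effectors, n_null=n_null, seed=seed + i
        )
        rows.append(f.to_vector())
    return np.array(rows)


def train_relationship_scorer(
    positive_pairs: Sequence[tuple[Iterable, Iterable]],
    negative_pairs: Sequence[tuple[Iterable, Iterable]],
    network: ProteinNetwork,
    seed: int = 0,
    n_null_features: int = 100,
    hidden_units: int = 8,
) -> RelationshipScorer:
    """Train the relationship scorer on labelled (targets, effectors) pairs.

    Features are proximity summaries; the predictor is a single hidden
    layer feed-forward network whose positive-class probability, scaled
    by 100, is the relationship score.  Reproducible for a fixed seed.
    """
    if not positive_pairs or not negative_pairs:
        raise DegenerateTrainingSetError(
            "both positive and negative pairs are required"
        )
    if min(len(positive_pairs), len(negative_pairs)) < 5:
        raise DegenerateTrainingSetError(
            "need at least 5 pairs per class to train the scorer"
        )
    x_pos = _features_for_pairs(network, positive_pairs, n_null_features, seed)
    x_neg = _features_for_pairs(
        network, negative_pairs, n_null_features, seed + len(positive_pairs)
    )
    x = np.vstack([x_pos, x_neg])
    y = np.array([1] * len(x_pos) + [0] * len(x_neg))
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(hidden_units,),
                    activation="tanh",
                    solver="lbfgs",
                    max_iter=2000,
                    random_state=seed,
                ),
            ),
        ]
    )
    model.fit(x, y)
    return RelationshipScorer(model, n_null_features, seed)


def score_relationship(
    scorer: RelationshipScorer,
    network: ProteinNetwork,
    targets: Iterable,
    effectors: Iterable,
    feature_seed: int | None = None,
) -> RelationshipScore:
    """Score a (targets, effectors) pair: value in [0, 100] with its
    category band and p band (empirical when the scorer is calibrated)."""
    f = compute_proximity_features(
        network,
        targets,
        effectors,
        n_null=scorer.n_null_features,
        seed=scorer.seed if feature_seed is None else feature_seed,
    )
    value = scorer.score_features(f)
    category = categorize_score(value)
    if scorer.calibration is not None:
        p = scorer.calibration.p_value(value)
        if p < 0.05:
            band = "<0.05"
        elif p < 0.10:
            band = "0.05-0.10"
        elif p < 0.20:
            band = "0.10-0.20"
        else:
            band = ">=0.20"
    else:
        band = p_band_for_category(category)
    return RelationshipScore(value, category, band)


def calibrate_score_pvalues(
    scorer: RelationshipScorer,
    network: ProteinNetwork,
    effectors: Iterable,
    n_null: int,
    seed: int = 0,
    target_size: int = 5,
) -> ScoreCalibration:
    """Empirical p-values from scores of random degree-matched target sets.

    ``p(score)`` is the fraction of null target sets scoring >= score;
    the mapping is stored as a step function and attached to the scorer.
    """
    if n_null < 100:
        raise InsufficientNullError("calibration requires n_null >= 100")
    e_map = sorted(a for a in _accessions(effectors) if a in network)
    if not e_map:
        raise EmptySetError("no effector maps to the network")
    rng = np.random.default_rng(seed)
    nodes = network.node_order
    bins = _degree_bins(network)
    by_bin: dict[int, list[str]] = {}
    for a, b in bins.items():
        by_bin.setdefault(b, []).append(a)
    hops = _multi_source_hops(network, set(e_map))
    sentinel = float(network.n_nodes)
    scores = np.empty(n_null)
    for i in range(n_null):
        base = [nodes[j] for j in rng.choice(len(nodes), size=target_size,
                                             replace=False)]
        members = _matched_random_set(base, bins, by_bin, rng)
        observed = float(np.mean([hops.get(a, sentinel) for a in members]))
        null = np.array(
            [
                float(np.mean([
                    hops.get(a, sentinel)
                    for a in _matched_random_set(members, bins, by_bin, rng)
                ]))
                for _ in range(scorer.n_null_features)
            ]
        )
        sd = float(null.std())
        z = 0.0 if sd == 0 else float((null.mean() - observed) / sd)
        f = ProximityFeatures(
            mean_min_distance=observed,
            degree_matched_z=z,
            overlap_fraction=len(set(members) & set(e_map)) / len(members),
            target_count=len(members),
            effector_count=len(e_map),
        )
        scores[i] = scorer.score_features(f)
    calibration = ScoreCalibration(scores)
    scorer.calibration = calibration
    return calibration
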