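"""Synthetic study generators with known ground truth.

Every upstream input of the pipeline can be generated here with its
ground truth recorded, so the full pipeline is testable offline:

* scale-free-flavoured signed directed networks;
* disease characterisations whose motives have *planted upstream
  regulators* — hub nodes with directed paths to every chosen effector —
  and disease signs assigned by propagating a disease stimulus under
  hidden propagation parameters;
* drugs whose targets inhibit those planted regulators (plus decoys);
* training sets whose outputs are computed by propagation under the
  hidden parameters, so a perfectly compliant solution exists by
  construction;
* differential-expression tables with known post-filter bookkeeping.

Seeding: each generator derives its random stream from the caller's seed
through a declared per-generator counter (`_STREAMS`), so adding a new
generator never perturbs the streams of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import InvalidSpecError, UnknownMotiveError
from .expression import DifferentialExpressionRecord
from .knowledge_base import (
    DiseaseCharacterisation,
    DrugTargetProfile,
    EffectorState,
    InteractionEdge,
    Motive,
    ProteinNetwork,
    ProteinRef,
)
from .sampling import (
    DEFAULT_DELTA,
    PropagationParameters,
    TrainingPair,
    propagate,
)

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "generate_disease",
    "generate_drug",
    "generate_training_set",
    "generate_de_table",
    "write_de_table",
    "MRCC_SHAPE_MOTIVE_SIZES",
]

#: Declared per-generator substream counters (stable across versions).
_STREAMS = {"network": 0, "disease": 1, "drug": 2, "training": 3, "de": 4}

#: Published mRCC effector counts per motive, used as a shape template.
MRCC_SHAPE_MOTIVE_SIZES: tuple[int, ...] = (85, 33, 50, 84, 31)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping of one synthetic study.

    ``hidden_params`` generated every training output and the disease
    signs; ``planted_regulators`` lists, per motive, the upstream nodes
    every motive effector is reachable from; ``expected_reversed`` is
    filled in by :func:`generate_drug` from hidden-parameter propagation.
    """

    hidden_params: PropagationParameters
    planted_regulators: dict[str, set[str]]
    disease_stimulus: DrugTargetProfile
    disease_signs: dict[str, int]
    motive_effectors: dict[str, set[str]]
    expected_reversed: dict[str, dict[str, set[str]]] = field(
        default_factory=dict
    )
    expected_restriction_count: int | None = None


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def generate_network(
    n_nodes: int,
    n_edges: int,
    frac_inhibitory: float,
    seed: int,
) -> ProteinNetwork:
    """Preferential-attachment-flavoured signed directed graph.

    Exactly ``n_edges`` distinct directed (source, target) pairs, no
    self-loops; endpoints drawn with probability proportional to
    (degree + 1), so early nodes become hubs.  Each edge is inhibitory
    with probability ``frac_inhibitory``.  Bit-reproducible per seed.
    """
    if n_nodes < 2:
        raise InvalidSpecError("n_nodes must be >= 2")
    if not (0.0 <= frac_inhibitory <= 1.0):
        raise InvalidSpecError("frac_inhibitory must lie in [0, 1]")
    if not (1 <= n_edges <= n_nodes * (n_nodes - 1)):
        raise InvalidSpecError(
            f"n_edges must lie in [1, {n_nodes * (n_nodes - 1)}]"
        )
    rng = _rng(seed, "network")
    width = len(str(n_nodes - 1))
    names = [f"SYN{i:0{max(width, 3)}d}" for i in range(n_nodes)]
    out_w = np.ones(n_nodes)
    in_w = np.ones(n_nodes)
    used: set[tuple[int, int]] = set()
    pairs: list[tuple[int, int]] = []
    misses = 0
    while len(pairs) < n_edges:
        if misses > 50:
            # dense regime: enumerate the remaining pairs and draw directly
            remaining = [
                (i, j)
                for i in range(n_nodes)
                for j in range(n_nodes)
                if i != j and (i, j) not in used
            ]
            take = rng.choice(
                len(remaining), size=n_edges - len(pairs), replace=False
            )
            for k in sorted(take):
                pairs.append(remaining[k])
                used.add(remaining[k])
            break
        src = int(rng.choice(n_nodes, p=out_w / out_w.sum()))
        dst = int(rng.choice(n_nodes, p=in_w / in_w.sum()))
        if src == dst or (src, dst) in used:
            misses += 1
            continue
        misses = 0
        used.add((src, dst))
        pairs.append((src, dst))
        out_w[src] += 1
        in_w[dst] += 1
    signs = np.where(rng.random(n_edges) < frac_inhibitory, -1, 1)
    refs = [ProteinRef(nm) for nm in names]
    edges = [
        InteractionEdge(refs[s], refs[t], int(sg), provenance="synthetic")
        for (s, t), sg in zip(pairs, signs)
    ]
    return ProteinNetwork(nodes=refs, edges=edges)


# ---------------------------------------------------------------------------
# Disease
# ---------------------------------------------------------------------------

def _hidden_parameters(
    network: ProteinNetwork, rng: np.random.Generator
) -> PropagationParameters:
    return PropagationParameters(
        weights=rng.uniform(0.6, 1.4, network.n_edges),
        biases=np.zeros(network.n_nodes),
    )


def generate_disease(
    network: ProteinNetwork,
    motive_sizes: Sequence[int],
    overlap_frac: float,
    seed: int,
    n_unique: int | None = None,
    motive_names: Sequence[str] | None = None,
    n_regulators: int = 3,
    activity_floor: float = 0.01,
    effector_depth: int = 2,
    regulator_degree_pct: float = 85.0,
    name: str = "synthetic-disease",
) -> tuple[DiseaseCharacterisation, SyntheticTruth]:
    """Motif-structured disease with planted upstream mechanisms.

    Per motive, a *primary regulator* is planted: a node of moderate
    degree (at most the ``regulator_degree_pct`` percentile, so the
    mechanism is a dedicated pathway rather than a promiscuous hub)
    whose directed reach within ``effector_depth`` hops covers the whole
    motive; the depth, and then the degree cap, relax automatically when
    a large motive needs a wider pool.  Motive effectors are drawn from
    that pool, re-using earlier motives' effectors to hit either an
    expected shared fraction ``overlap_frac`` or, when ``n_unique`` is
    given, an exact union size.  Up to ``n_regulators - 1`` *secondary
    regulators* are then planted per motive: nodes whose reach covers at
    least half of the chosen effectors, so every planted regulator has
    directed paths to >= 50% of its motive.

    Disease signs come from propagating the disease stimulus (+1 on all
    primary regulators) under freshly drawn hidden parameters; nodes
    below ``activity_floor`` in magnitude are not eligible as effectors.
    """
    sizes = [int(s) for s in motive_sizes]
    if any(s < 1 for s in sizes):
        raise InvalidSpecError("motive sizes must be >= 1")
    if sum(sizes) > network.n_nodes:
        raise InvalidSpecError("sum of motive sizes exceeds node count")
    if n_unique is not None and not (
        max(sizes) <= n_unique <= sum(sizes)
    ):
        raise InvalidSpecError("n_unique must lie in [max(sizes), sum(sizes)]")
    if motive_names is None:
        motive_names = [f"motive-{i + 1}" for i in range(len(sizes))]
    if len(motive_names) != len(sizes):
        raise InvalidSpecError("motive_names must match motive_sizes")

    rng = _rng(seed, "disease")
    hidden = _hidden_parameters(network, rng)
    g = network.to_directed_graph()
    degree = dict(g.degree())
    degree_cap = float(np.percentile(list(degree.values()),
                                     regulator_degree_pct))

    def reach(node: str, depth: int) -> set[str]:
        """Nodes reachable from ``node`` by directed paths of <= depth."""
        seen = {node}
        frontier = {node}
        for _ in range(depth):
            frontier = {
                v for u in frontier for _, v in g.out_edges(u)
            } - seen
            if not frontier:
                break
            seen |= frontier
        seen.discard(node)
        return seen

    # plant one primary regulator per motive, distinct across motives
    taken: set[str] = set()
    primaries: dict[str, str] = {}
    pools: dict[str, set[str]] = {}
    depths: dict[str, int] = {}
    for mname, size in zip(motive_names, sizes):
        found = False
        for capped in (True, False):
            if found:
                break
            for depth in range(effector_depth, network.n_nodes + 1):
                candidates = []
                for node in g.nodes:
                    if node in taken:
                        continue
                    if capped and degree[node] > degree_cap:
                        continue
                    if len(reach(node, depth) - taken) >= size + 1:
                        candidates.append(node)
                if candidates:
                    candidates.sort()
                    r0 = candidates[int(rng.integers(len(candidates)))]
                    primaries[mname] = r0
                    pools[mname] = reach(r0, depth) - taken
                    depths[mname] = depth
                    taken.add(r0)
                    found = True
                    break
                # widening the depth cannot help once reach saturates
                if all(
                    len(reach(node, depth)) >= network.n_nodes - 1
                    for node in g.nodes
                    if node not in taken
                ):
                    break
        if not found:
            raise InvalidSpecError(
                f"cannot plant a regulator covering {size} effectors for "
                f"motive {mname!r}; use a denser or larger network"
            )

    stimulus = DrugTargetProfile(
        "disease-stimulus",
        [(ProteinRef(primaries[m]), +1) for m in motive_names],
    )
    activity = propagate(network, hidden, stimulus)

    # pick effectors per motive with the requested sharing structure
    dups_needed = (
        sum(sizes) - n_unique if n_unique is not None else None
    )
    prev_union: set[str] = set()
    motives: list[Motive] = []
    signs: dict[str, int] = {}
    effector_sets: dict[str, set[str]] = {}
    regulators: dict[str, set[str]] = {}
    for mi, (mname, size) in enumerate(zip(motive_names, sizes)):
        # the activity floor can thin a structurally sufficient pool;
        # deepen the primary regulator's reach until enough remain
        while True:
            eligible = {
                a
                for a in pools[mname]
                if a not in taken and abs(activity[a]) >= activity_floor
            }
            if mi == 0:
                n_dup = 0
            elif dups_needed is not None:
                n_dup = min(dups_needed, size, len(eligible & prev_union))
            else:
                n_dup = min(
                    int(round(overlap_frac * size)),
                    len(eligible & prev_union),
                )
            dup_pool = sorted(eligible & prev_union)
            fresh_pool = sorted(eligible - prev_union)
            if len(fresh_pool) >= size - n_dup:
                break
            depths[mname] += 1
            wider = reach(primaries[mname], depths[mname]) - set(
                primaries.values()
            )
            if wider <= pools[mname]:
                raise InvalidSpecError(
                    f"motive {mname!r}: only {len(fresh_pool)} fresh "
                    f"eligible effectors for {size - n_dup} required"
                )
            pools[mname] = wider
        members = [
            dup_pool[i] for i in rng.choice(len(dup_pool), n_dup,
                                            replace=False)
        ] if n_dup else []
        members += [
            fresh_pool[i]
            for i in rng.choice(len(fresh_pool), size - n_dup, replace=False)
        ]
        if dups_needed is not None:
            dups_needed -= n_dup
        states = []
        for a in members:
            sign = +1 if activity[a] > 0 else -1
            signs[a] = sign
            states.append(EffectorState(ProteinRef(a), sign))
        motives.append(Motive(mname, states))
        effector_sets[mname] = set(members)
        prev_union |= set(members)
        regulators[mname] = {primaries[mname]}

    if dups_needed:
        raise InvalidSpecError(
            f"could not realise requested union size: {dups_needed} shared "
            f"effectors short (not enough eligible overlap)"
        )

    # plant secondary regulators: cover >= half of the chosen effectors
    for mname, size in zip(motive_names, sizes):
        need = (size + 1) // 2
        eff = effector_sets[mname]
        candidates = [
            node
            for node in g.nodes
            if node not in taken
            and node not in prev_union
            and degree[node] <= degree_cap
            and len(reach(node, depths[mname]) & eff) >= need
        ]
        candidates.sort()
        n_extra = min(n_regulators - 1, len(candidates))
        if n_extra > 0:
            picks = rng.choice(len(candidates), n_extra, replace=False)
            for i in picks:
                regulators[mname].add(candidates[i])
                taken.add(candidates[i])

    disease = DiseaseCharacterisation(name, motives)
    truth = SyntheticTruth(
        hidden_params=hidden,
        planted_regulators={m: set(r) for m, r in regulators.items()},
        disease_stimulus=stimulus,
        disease_signs=signs,
        motive_effectors=effector_sets,
    )
    return disease, truth


# ---------------------------------------------------------------------------
# Drugs
# ---------------------------------------------------------------------------

def generate_drug(
    network: ProteinNetwork,
    truth: SyntheticTruth,
    motive: str,
    n_targets: int,
    decoy_frac: float,
    seed: int,
    name: str | None = None,
    tau: float = DEFAULT_DELTA,
) -> DrugTargetProfile:
    """A drug aimed at one motive's planted mechanism.

    ``round((1 - decoy_frac) * n_targets)`` targets inhibit planted
    regulators of the motive (the action sign that reverses the +1
    disease stimulus); the rest are random decoy nodes, also inhibited.
    The truth's ``expected_reversed`` bookkeeping is updated from
    hidden-parameter propagation of the drug stimulus.
    """
    if motive not in truth.planted_regulators:
        raise UnknownMotiveError(f"unknown motive {motive!r}")
    if n_targets < 1:
        raise InvalidSpecError("n_targets must be >= 1")
    if not (0.0 <= decoy_frac <= 1.0):
        raise InvalidSpecError("decoy_frac must lie in [0, 1]")
    rng = _rng(seed, "drug")
    regs = sorted(truth.planted_regulators[motive])
    n_real = int(round((1.0 - decoy_frac) * n_targets))
    if n_real > len(regs):
        raise InvalidSpecError(
            f"{n_real} planted targets requested but motive {motive!r} has "
            f"only {len(regs)} planted regulators"
        )
    real = [regs[i] for i in rng.choice(len(regs), n_real, replace=False)]
    all_regs = {r for rs in truth.planted_regulators.values() for r in rs}
    decoy_pool = sorted(set(network.node_order) - all_regs - set(real))
    n_decoy = n_targets - n_real
    if n_decoy > len(decoy_pool):
        raise InvalidSpecError("not enough nodes for the requested decoys")
    decoys = [
        decoy_pool[i] for i in rng.choice(len(decoy_pool), n_decoy,
                                          replace=False)
    ]
    if name is None:
        name = f"drug-{motive}-s{seed}"
    profile = DrugTargetProfile(
        name, [(ProteinRef(a), -1) for a in real + decoys]
    )

    activity = propagate(network, truth.hidden_params, profile)
    reversed_by_motive: dict[str, set[str]] = {}
    for mname, members in truth.motive_effectors.items():
        rev = set()
        for a in members:
            val = activity[a]
            if abs(val) >= tau and np.sign(val) == -truth.disease_signs[a]:
                rev.add(a)
        reversed_by_motive[mname] = rev
    truth.expected_reversed[name] = reversed_by_motive
    return profile


# ---------------------------------------------------------------------------
# Training pairs
# ---------------------------------------------------------------------------

def generate_training_set(
    network: ProteinNetwork,
    truth: SyntheticTruth,
    n_pairs: int,
    effectors_per_pair: int,
    seed: int,
    output_margin: float = 0.5,
    n_stimuli: int | None = None,
    n_probes: int = 8,
    probe_delta: float = DEFAULT_DELTA,
) -> list[TrainingPair]:
    """Input->output pairs computed under the hidden parameters.

    The pairs emulate a curated pharmacology training collection:

    * a limited repertoire of ``n_stimuli`` stimulus profiles (small
      target sets with random action signs) recurs across the pairs, the
      way a drug appears in several condition records — consecutive
      stimuli draw *disjoint* target sets from the planted regulators
      and network hubs, like drugs of distinct classes;
    * each pair states ``effectors_per_pair`` responses of its stimulus,
      chosen among *robust* effects: nodes whose hidden-parameter
      activity magnitude is at least ``output_margin`` and whose response
      sign is reproduced (with magnitude >= ``probe_delta``) by at least
      ``n_probes - 1`` of ``n_probes`` random parameter draws from the
      model family — well-established effects rather than borderline
      ones, as a curated knowledge base would contain;
    * polarity is causal or therapeutic at random (therapeutic pairs
      state the reversed sign).

    The hidden parameters comply with every pair by construction.
    """
    if n_pairs < 1:
        raise InvalidSpecError("n_pairs must be >= 1")
    if n_stimuli is None:
        n_stimuli = max(3, min(n_pairs // 5, 8))
    rng = _rng(seed, "training")
    nodes = network.node_order
    all_regs = sorted(
        {r for rs in truth.planted_regulators.values() for r in rs}
    )
    degree = {a: 0 for a in nodes}
    for e in network.edges:
        degree[e.source.accession] += 1
    hubs = sorted(degree, key=degree.get, reverse=True)
    # planted regulators first: the mechanisms of interest are covered by
    # the repertoire the way modelled drugs appear in a real training set
    pool = list(dict.fromkeys(all_regs + hubs))[: max(10, len(all_regs))]
    probes = [
        PropagationParameters(
            rng.uniform(0.5, 1.4, network.n_edges),
            np.zeros(network.n_nodes),
        )
        for _ in range(n_probes)
    ]

    # build the stimulus repertoire with its robust-response candidates
    stimuli: list[DrugTargetProfile] = []
    candidates: list[list[tuple[str, int]]] = []
    cursor = 0
    while len(stimuli) < n_stimuli:
        n_t = int(rng.integers(1, 3))
        if cursor + n_t > len(pool):
            raise InvalidSpecError(
                "not enough distinct pool proteins for the requested "
                "stimulus repertoire; lower n_stimuli"
            )
        members = pool[cursor:cursor + n_t]
        cursor += n_t
        actions = [int(a) for a in rng.choice([-1, 1], size=n_t)]
        profile = DrugTargetProfile(
            f"train-stimulus-{len(stimuli)}",
            [(ProteinRef(a), act) for a, act in zip(members, actions)],
        )
        activity = propagate(network, truth.hidden_params, profile)
        probe_maps = [propagate(network, p, profile) for p in probes]
        cand = []
        for a in nodes:
            if a in members or abs(activity[a]) < output_margin:
                continue
            sgn = 1 if activity[a] > 0 else -1
            n_ok = sum(
                1 for pm in probe_maps if sgn * pm[a] >= probe_delta
            )
            if n_ok >= n_probes - 1:
                cand.append((a, sgn))
        if len(cand) < effectors_per_pair + 1:
            continue  # stimulus too weak; move on through the pool
        stimuli.append(profile)
        candidates.append(cand)

    pairs: list[TrainingPair] = []
    for i in range(n_pairs):
        j = i % n_stimuli
        cand = candidates[j]
        take = rng.choice(len(cand), effectors_per_pair, replace=False)
        therapeutic = bool(rng.random() < 0.5)
        outputs = []
        for t in take:
            acc_name, act_sign = cand[t]
            stated = -act_sign if therapeutic else act_sign
            outputs.append(EffectorState(ProteinRef(acc_name), stated))
        pairs.append(
            TrainingPair(
                stimuli[j],
                outputs,
                "therapeutic" if therapeutic else "causal",
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def generate_de_table(
    n_rows: int,
    n_pass: int,
    n_conflict_proteins: int,
    seed: int,
) -> tuple[list[DifferentialExpressionRecord], int]:
    """A DE table with known post-filter bookkeeping.

    Exactly ``n_pass`` rows pass the default filter (adj_p < 0.01 and
    |logFC| > 2).  Each of ``n_conflict_proteins`` proteins contributes
    two passing rows with opposite logFC signs (and is therefore
    discarded at collapse); every other passing protein contributes one.
    Returns the records (shuffled) and the expected restriction count,
    ``n_pass - 2 * n_conflict_proteins``.
    """
    if n_pass > n_rows:
        raise InvalidSpecError("n_pass cannot exceed n_rows")
    if n_conflict_proteins < 0 or 2 * n_conflict_proteins > n_pass:
        raise InvalidSpecError(
            "need n_pass >= 2 * n_conflict_proteins passing rows"
        )
    rng = _rng(seed, "de")
    records: list[DifferentialExpressionRecord] = []
    tx = 0
    prot = 0

    def next_protein() -> ProteinRef:
        nonlocal prot
        prot += 1
        return ProteinRef(f"DEP{prot:05d}")

    def next_tx() -> str:
        nonlocal tx
        tx += 1
        return f"TX{tx:06d}"

    def passing_row(protein: ProteinRef, sign: int):
        return DifferentialExpressionRecord(
            next_tx(), protein,
            logFC=float(sign * rng.uniform(2.2, 6.0)),
            adj_p=float(rng.uniform(1e-6, 0.009)),
        )

    n_clean = n_pass - 2 * n_conflict_proteins
    for _ in range(n_clean):
        records.append(passing_row(next_protein(), int(rng.choice([-1, 1]))))
    for _ in range(n_conflict_proteins):
        p = next_protein()
        records.append(passing_row(p, +1))
        records.append(passing_row(p, -1))
    for _ in range(n_rows - n_pass):
        p = next_protein()
        mode = rng.random()
        sign = int(rng.choice([-1, 1]))
        if mode < 0.4:  # fails on p only
            lfc, adj_p = sign * rng.uniform(2.2, 6.0), rng.uniform(0.02, 1.0)
        elif mode < 0.8:  # fails on logFC only
            lfc, adj_p = sign * rng.uniform(0.0, 1.8), rng.uniform(1e-6, 0.009)
        else:  # fails on both
            lfc, adj_p = sign * rng.uniform(0.0, 1.8), rng.uniform(0.02, 1.0)
        records.append(
            DifferentialExpressionRecord(next_tx(), p, float(lfc),
                                         float(adj_p))
        )
    order = rng.permutation(len(records))
    return [records[i] for i in order], n_clean


def write_de_table(
    records: Sequence[DifferentialExpressionRecord],
    path: Union[str, Path],
) -> None:
    """Write records in the pipeline's TSV layout."""
    lines = ["transcript_id\tprotein_accession\tlogFC\tadj_p"]
    for r in records:
        acc = r.protein.accession if r.protein else ""
        lines.append(f"{r.transcript_id}\t{acc}\t{r.logFC:.6g}\t{r.adj_p:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
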