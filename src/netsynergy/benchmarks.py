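"""Validation benchmarks with planted ground truth.

The headline numbers of the original mRCC study depend on a proprietary
protein network and training set, so the pipeline's correctness is
instead established on synthetic studies where the truth is known:

* propagation against an independent dense fixed-point solver;
* recovery of a planted drug mechanism by ensemble sampling
  (reversal recall and false-reversal rate against hidden-parameter
  propagation);
* a planted drug's relationship score against degree-matched random
  target sets;
* the reversal-partition identity against per-protein enumeration;
* restriction derivation against generator bookkeeping.

Every benchmark here is deterministic given its seed and is shared by
the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .knowledge_base import (
    DrugTargetProfile,
    InteractionEdge,
    ProteinNetwork,
    ProteinRef,
)
from .expression import derive_restrictions
from .pipeline import compute_reversed_proteins, reversal_coverage
from .sampling import (
    PropagationParameters,
    _propagation_matrix,
    aggregate_activities,
    propagate,
    sample_solutions,
)
from .scoring import (
    _degree_bins,
    _matched_random_set,
    score_relationship,
    train_relationship_scorer,
)
from .synthetic import (
    generate_de_table,
    generate_disease,
    generate_drug,
    generate_network,
    generate_training_set,
)

__all__ = [
    "dense_fixed_point_oracle",
    "propagation_oracle_benchmark",
    "RecoveryResult",
    "moa_recovery_benchmark",
    "planted_score_benchmark",
    "reversal_partition_benchmark",
    "restriction_count_benchmark",
]


def _subseeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


# ---------------------------------------------------------------------------
# Propagation vs dense fixed-point oracle
# ---------------------------------------------------------------------------

def dense_fixed_point_oracle(
    network: ProteinNetwork,
    params: PropagationParameters,
    stimulus: DrugTargetProfile,
) -> np.ndarray:
    """Solve ``s = tanh(M s + b)`` on the free nodes with scipy's dense
    root finder; clamped (stimulus) nodes held at their action sign.

    This is an independent route to the fixed point that never runs the
    package's own iteration.
    """
    idx = network.node_index()
    n = network.n_nodes
    m = _propagation_matrix(network, params)
    clamp = np.zeros(n)
    clamped = np.zeros(n, dtype=bool)
    for ref, action in stimulus.targets:
        clamp[idx[ref.accession]] = action
        clamped[idx[ref.accession]] = True
    free = ~clamped

    def residual(x):
        s = clamp.copy()
        s[free] = x
        return np.tanh(m @ s + params.biases)[free] - x

    sol = optimize.root(residual, np.zeros(int(free.sum())), method="hybr",
                        tol=1e-13)
    if not sol.success:
        raise RuntimeError(f"oracle root finder failed: {sol.message}")
    s = clamp.copy()
    s[free] = sol.x
    return s


def propagation_oracle_benchmark(seed: int, n_networks: int = 100) -> float:
    """Worst absolute propagation error vs the dense oracle over random
    small (<= 5 node) contraction-regime networks."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        n = int(rng.integers(2, 6))
        n_edges = int(rng.integers(1, n * (n - 1) + 1))
        names = [f"P{i}" for i in range(n)]
        seen, edges = set(), []
        while len(edges) < n_edges:
            s, t = int(rng.integers(n)), int(rng.integers(n))
            if s == t or (s, t) in seen:
                continue
            seen.add((s, t))
            edges.append(
                InteractionEdge(
                    ProteinRef(names[s]), ProteinRef(names[t]),
                    int(rng.choice([-1, 1])),
                )
            )
        net = ProteinNetwork(
            nodes=[ProteinRef(x) for x in names], edges=edges
        )
        params = PropagationParameters(
            rng.uniform(0.2, 1.0, net.n_edges),
            rng.normal(0.0, 0.1, net.n_nodes),
            tol=1e-12, max_steps=2000,
        )
        # scale into the contraction regime so the fixed point is unique
        m = np.abs(_propagation_matrix(net, params))
        row = m.sum(axis=1).max()
        if row > 0.9:
            params.weights *= 0.9 / row
        stim = DrugTargetProfile(
            "probe", [(ProteinRef(names[0]), int(rng.choice([-1, 1])))]
        )
        amap = propagate(net, params, stim)
        oracle = dense_fixed_point_oracle(net, params, stim)
        err = max(abs(amap[a] - o) for a, o in zip(net.node_order, oracle))
        worst = max(worst, err)
    return worst


# ---------------------------------------------------------------------------
# Planted-mechanism recovery by ensemble sampling
# ---------------------------------------------------------------------------

#: Study conditions of the recovery benchmark (one synthetic study).
RECOVERY_CONDITIONS = dict(
    n_nodes=30,
    n_edges=110,
    frac_inhibitory=0.3,
    motive_sizes=(6, 5),
    overlap_frac=0.1,
    drug_targets=3,
    decoy_frac=0.0,
    n_pairs=20,
    effectors_per_pair=1,
    n_stimuli=3,
    cv_folds=5,
    accuracy_threshold=0.90,
)


@dataclass
class RecoveryResult:
    seed: int
    n_accepted: int
    n_attempts: int
    n_expected_reversals: int
    recall: float
    false_reversal_rate: float


def moa_recovery_benchmark(
    seed: int,
    n_seeds: int = 5,
    n_accept: int = 100,
    max_attempts: int = 400,
) -> list[RecoveryResult]:
    """Recovery of a planted drug mechanism, one study per sub-seed.

    Each study plants hidden propagation parameters, a disease with
    upstream regulators, and a drug inhibiting one motive's regulators;
    an ensemble of ``n_accept`` training-compliant solutions
    (cross-validated accuracy >= 0.9) is sampled, and its mean-activity
    reversals are compared with the hidden-parameter reversals: recall
    over the expected reversed effectors, false-reversal rate over the
    effectors not expected to reverse.
    """
    results = []
    for study_seed in _subseeds(seed, n_seeds):
        c = RECOVERY_CONDITIONS
        net = generate_network(
            c["n_nodes"], c["n_edges"], c["frac_inhibitory"], study_seed
        )
        disease, truth = generate_disease(
            net, list(c["motive_sizes"]), c["overlap_frac"], study_seed
        )
        drug = generate_drug(
            net, truth, disease.motive_names[0], c["drug_targets"],
            c["decoy_frac"], study_seed,
        )
        pairs = generate_training_set(
            net, truth, c["n_pairs"], c["effectors_per_pair"], study_seed,
            n_stimuli=c["n_stimuli"],
        )
        ensemble = sample_solutions(
            net, pairs, n_accept=n_accept, seed=study_seed,
            cv_folds=c["cv_folds"],
            accuracy_threshold=c["accuracy_threshold"],
            stimulus=drug, max_attempts=max_attempts,
        )
        amap = aggregate_activities(ensemble, net)
        reversed_by_motive = compute_reversed_proteins(disease, amap)
        expected = truth.expected_reversed[drug.drug_name]
        all_expected = set().union(*expected.values())
        all_reversed = set().union(*reversed_by_motive.values())
        all_effectors = set().union(
            *(disease.motive(m).accessions for m in disease.motive_names)
        )
        recall = (
            len(all_expected & all_reversed) / len(all_expected)
            if all_expected
            else float("nan")
        )
        negatives = all_effectors - all_expected
        false_rate = (
            len(all_reversed - all_expected) / len(negatives)
            if negatives
            else 0.0
        )
        results.append(
            RecoveryResult(
                seed=study_seed,
                n_accepted=len(ensemble.solutions),
                n_attempts=ensemble.n_attempts,
                n_expected_reversals=len(all_expected),
                recall=recall,
                false_reversal_rate=false_rate,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Planted drug score vs degree-matched random target sets
# ---------------------------------------------------------------------------

def planted_score_benchmark(
    seed: int,
    n_seeds: int = 20,
    n_random_sets: int = 100,
) -> list[float]:
    """Percentile of a planted drug's relationship score among random
    degree-matched target sets of the same size, one study per sub-seed."""
    percentiles = []
    for study_seed in _subseeds(seed, n_seeds):
        net = generate_network(300, 480, 0.3, study_seed)
        disease, truth = generate_disease(
            net, [6, 5], overlap_frac=0.1, seed=study_seed
        )
        rng = np.random.default_rng(study_seed)
        motive = disease.motive_names[0]
        n_targets = min(3, len(truth.planted_regulators[motive]))
        drug = generate_drug(net, truth, motive, n_targets, 0.0, study_seed)
        effectors = disease.motive(motive).accessions
        positives, negatives = [], []
        for m in disease.motive_names:
            regs = sorted(truth.planted_regulators[m])
            eff = disease.motive(m).accessions
            k = min(2, len(regs))
            for _ in range(5):
                take = [
                    regs[i] for i in rng.choice(len(regs), k, replace=False)
                ]
                positives.append((take, eff))
                rand = [
                    net.node_order[i]
                    for i in rng.choice(net.n_nodes, 3, replace=False)
                ]
                negatives.append((rand, eff))
        scorer = train_relationship_scorer(
            positives, negatives, net, seed=study_seed
        )
        planted = score_relationship(
            scorer, net, drug.accessions, effectors
        ).value
        bins = _degree_bins(net)
        by_bin: dict[int, list[str]] = {}
        for a, b in bins.items():
            by_bin.setdefault(b, []).append(a)
        members = sorted(drug.accessions)
        null_scores = []
        for _ in range(n_random_sets):
            random_set = _matched_random_set(members, bins, by_bin, rng)
            null_scores.append(
                score_relationship(scorer, net, random_set, effectors).value
            )
        null_scores = np.asarray(null_scores)
        percentiles.append(100.0 * float(np.mean(null_scores < planted)))
    return percentiles


# ---------------------------------------------------------------------------
# Reversal-partition identity
# ---------------------------------------------------------------------------

def reversal_partition_benchmark(
    seed: int, n_trials: int = 50
) -> tuple[float, float]:
    """Random activity maps on synthetic diseases: returns the worst
    |partition sum - 100| and the fraction of (motive, protein) decisions
    agreeing with a per-protein enumeration oracle."""
    rng = np.random.default_rng(seed)
    worst_sum_err = 0.0
    agree = 0
    total = 0
    for t in range(n_trials):
        net = generate_network(40, 140, 0.3, seed + t)
        disease, _ = generate_disease(
            net, [8, 6], overlap_frac=0.2, seed=seed + t
        )
        amap_a = {a: float(rng.uniform(-1, 1)) for a in net.node_order}
        amap_b = {a: float(rng.uniform(-1, 1)) for a in net.node_order}
        report = reversal_coverage(disease, amap_a, amap_b, tau=0.1)
        for motive in disease.motives:
            pct = report.percentages[motive.name]
            worst_sum_err = max(
                worst_sum_err, abs(sum(pct.values()) - 100.0)
            )
            # per-protein enumeration oracle
            for st in motive.effectors:
                acc = st.protein.accession
                rev_a = (
                    abs(amap_a[acc]) >= 0.1
                    and np.sign(amap_a[acc]) == -st.disease_sign
                )
                rev_b = (
                    abs(amap_b[acc]) >= 0.1
                    and np.sign(amap_b[acc]) == -st.disease_sign
                )
                in_a = acc in report.reversed_by_a[motive.name]
                in_b = acc in report.reversed_by_b[motive.name]
                agree += (rev_a == in_a) and (rev_b == in_b)
                total += 1
    return worst_sum_err, agree / total


# ---------------------------------------------------------------------------
# Restriction derivation vs generator bookkeeping
# ---------------------------------------------------------------------------

def restriction_count_benchmark(seed: int, n_tables: int = 20) -> int:
    """Total absolute error between derived restriction counts and the
    generator's expected counts over random DE-table specifications."""
    rng = np.random.default_rng(seed)
    total_err = 0
    for t in range(n_tables):
        n_rows = int(rng.integers(100, 800))
        n_pass = int(rng.integers(10, min(80, n_rows)))
        n_conflict = int(rng.integers(0, n_pass // 2 + 1))
        records, expected = generate_de_table(
            n_rows, n_pass, n_conflict, seed + t
        )
        derived = derive_restrictions(records)
        total_err += abs(len(derived) - expected)
    return total_err
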