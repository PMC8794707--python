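"""Signal propagation, training compliance and ensemble sampling."""

import numpy as np
import pytest
from scipy import optimize

from netsynergy.errors import (
    EmptyEnsembleError,
    EmptyTrainingSetError,
    MissingTargetProteinError,
    NoCompliantSolutionError,
)
from netsynergy.knowledge_base import (
    DrugTargetProfile,
    EffectorState,
    InteractionEdge,
    ProteinNetwork,
    ProteinRef,
)
from netsynergy.sampling import (
    MoAEnsemble,
    MoASolution,
    PropagationParameters,
    TrainingPair,
    _propagation_matrix,
    aggregate_activities,
    evaluate_solution_accuracy,
    extract_moa_subnetwork,
    propagate,
    sample_solutions,
)
from netsynergy.synthetic import (
    generate_disease,
    generate_drug,
    generate_network,
    generate_training_set,
)

from conftest import make_network


def dense_fixed_point(network, params, stimulus):
    """Independent oracle: solve s = tanh(M s + b) on the free nodes with a
    dense root finder, clamped nodes held at their stimulus values."""
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

    sol = optimize.root(residual, np.zeros(free.sum()), method="hybr",
                        tol=1e-13)
    assert sol.success
    s = clamp.copy()
    s[free] = sol.x
    return s


def contraction_params(network, rng):
    """Random weights scaled so the propagation map is a contraction
    (unique fixed point; both oracle and iteration must land on it)."""
    weights = rng.uniform(0.2, 1.0, network.n_edges)
    params = PropagationParameters(weights, rng.normal(0, 0.1, network.n_nodes))
    m = np.abs(_propagation_matrix(network, params))
    row = m.sum(axis=1).max()
    if row > 0.9:
        params.weights *= 0.9 / row
    return params


def random_small_network(rng):
    n = int(rng.integers(2, 6))
    n_edges = int(rng.integers(1, n * (n - 1) + 1))
    names = [f"P{i}" for i in range(n)]
    seen, edges = set(), []
    while len(edges) < n_edges:
        s, t = rng.integers(n), rng.integers(n)
        if s == t or (s, t) in seen:
            continue
        seen.add((s, t))
        edges.append(
            InteractionEdge(
                ProteinRef(names[s]), ProteinRef(names[t]),
                int(rng.choice([-1, 1])),
            )
        )
    return ProteinNetwork(nodes=[ProteinRef(x) for x in names], edges=edges)


class TestPropagate:
    def test_isolated_clamped_node(self):
        net = make_network([], extra_nodes=["A"])
        params = PropagationParameters(np.zeros(0), np.zeros(1))
        stim = DrugTargetProfile("d", [(ProteinRef("A"), -1)])
        amap = propagate(net, params, stim)
        assert amap["A"] == -1

    def test_single_inhibitory_edge_hand_value(self):
        net = make_network([("A", "B", -1)])
        params = PropagationParameters(np.ones(1), np.zeros(2))
        stim = DrugTargetProfile("d", [(ProteinRef("A"), -1)])
        amap = propagate(net, params, stim)
        # B receives -1 * (-1) = +1, so settles at tanh(1)
        assert amap["B"] == pytest.approx(np.tanh(1.0), abs=1e-6)

    def test_two_cycle_matches_dense_solver(self, rng):
        net = make_network([("A", "B", 1), ("B", "A", -1)])
        params = contraction_params(net, rng)
        stim = DrugTargetProfile("d", [(ProteinRef("A"), 1)])
        amap = propagate(net, params, stim)
        oracle = dense_fixed_point(net, params, stim)
        for acc, expect in zip(net.node_order, oracle):
            assert amap[acc] == pytest.approx(expect, abs=1e-6)

    def test_small_topologies_match_fixed_point_oracle(self, rng):
        """Propagation agrees with an independent dense root finder on a
        sample of random <=5-node topologies."""
        worst = 0.0
        for _ in range(30):
            net = random_small_network(rng)
            params = contraction_params(net, rng)
            params.tol = 1e-12
            stim = DrugTargetProfile(
                "d", [(ProteinRef(net.node_order[0]), int(rng.choice([-1, 1])))]
            )
            amap = propagate(net, params, stim)
            oracle = dense_fixed_point(net, params, stim)
            err = max(
                abs(amap[a] - o) for a, o in zip(net.node_order, oracle)
            )
            worst = max(worst, err)
        assert worst < 1e-9

    def test_outputs_bounded_and_clamps_held(self, rng):
        net = generate_network(25, 90, 0.4, seed=3)
        for trial in range(10):
            params = PropagationParameters(
                rng.uniform(0, 2.5, net.n_edges), rng.normal(0, 0.5, net.n_nodes)
            )
            stim = DrugTargetProfile(
                "d", [(ProteinRef(net.node_order[trial]), -1)]
            )
            clamp_acc = net.node_order[trial + 5]
            amap = propagate(net, params, stim, clamps=[(clamp_acc, 0.25)])
            values = [amap[a] for a in net.node_order]
            assert all(-1 <= v <= 1 for v in values)
            assert amap[net.node_order[trial]] == -1
            assert amap[clamp_acc] == 0.25

    def test_deterministic(self, rng):
        net = generate_network(20, 60, 0.3, seed=4)
        params = PropagationParameters(
            rng.uniform(0, 2, net.n_edges), rng.normal(0, 0.2, net.n_nodes)
        )
        stim = DrugTargetProfile("d", [(ProteinRef(net.node_order[0]), 1)])
        a1 = propagate(net, params, stim)
        a2 = propagate(net, params, stim)
        assert a1.activities == a2.activities

    def test_missing_stimulus_protein_rejected(self, chain_network):
        params = PropagationParameters(np.ones(3), np.zeros(4))
        stim = DrugTargetProfile("d", [(ProteinRef("MISSING"), -1)])
        with pytest.raises(MissingTargetProteinError):
            propagate(chain_network, params, stim)


def toy_training_setup(seed=21):
    net = generate_network(30, 110, 0.3, seed=seed)
    disease, truth = generate_disease(net, [6, 5], overlap_frac=0.1, seed=seed)
    pairs = generate_training_set(net, truth, 15, 2, seed=seed)
    return net, disease, truth, pairs


class TestAccuracy:
    def test_generating_params_are_fully_compliant(self):
        net, disease, truth, pairs = toy_training_setup()
        assert evaluate_solution_accuracy(truth.hidden_params, pairs, net) == 1.0

    def test_zero_weights_comply_with_nothing(self):
        net, disease, truth, pairs = toy_training_setup()
        dead = PropagationParameters(
            np.zeros(net.n_edges), np.zeros(net.n_nodes)
        )
        assert evaluate_solution_accuracy(dead, pairs, net) == 0.0

    def test_matches_per_pair_recount(self, rng):
        net, disease, truth, pairs = toy_training_setup()
        params = PropagationParameters(
            rng.uniform(0, 1.5, net.n_edges), rng.normal(0, 0.1, net.n_nodes)
        )
        fast = evaluate_solution_accuracy(params, pairs, net)
        # brute-force: one propagate call per pair
        n_ok = 0
        for pair in pairs:
            amap = propagate(net, params, pair.input)
            flip = -1 if pair.polarity == "therapeutic" else 1
            ok = all(
                flip * st.disease_sign * amap[st.protein.accession] >= 0.1
                for st in pair.output
            )
            n_ok += ok
        assert fast == pytest.approx(n_ok / len(pairs))

    def test_empty_training_set_rejected(self):
        net, *_ = toy_training_setup()
        params = PropagationParameters(
            np.ones(net.n_edges), np.zeros(net.n_nodes)
        )
        with pytest.raises(EmptyTrainingSetError):
            evaluate_solution_accuracy(params, [], net)


class TestSampling:
    def test_zero_threshold_accepts_exactly_n(self):
        net, disease, truth, pairs = toy_training_setup()
        ens = sample_solutions(
            net, pairs, n_accept=3, seed=1, cv_folds=1,
            accuracy_threshold=0.0, n_iter=40,
        )
        assert len(ens.solutions) == 3

    def test_same_seed_is_bit_identical(self):
        net, disease, truth, pairs = toy_training_setup()
        e1 = sample_solutions(net, pairs, n_accept=2, seed=9, cv_folds=2,
                              accuracy_threshold=0.5, n_iter=60)
        e2 = sample_solutions(net, pairs, n_accept=2, seed=9, cv_folds=2,
                              accuracy_threshold=0.5, n_iter=60)
        for s1, s2 in zip(e1.solutions, e2.solutions):
            assert np.array_equal(s1.params.weights, s2.params.weights)
            assert np.array_equal(s1.params.biases, s2.params.biases)
            assert s1.cv_accuracy == s2.cv_accuracy

    def test_compliant_solution_found_at_high_threshold(self):
        net, disease, truth, pairs = toy_training_setup()
        ens = sample_solutions(
            net, pairs, n_accept=1, seed=2, cv_folds=5,
            accuracy_threshold=0.9, max_attempts=12,
        )
        assert len(ens.solutions) >= 1
        assert all(s.cv_accuracy >= 0.9 for s in ens.solutions)

    def test_raising_threshold_never_accepts_more(self):
        net, disease, truth, pairs = toy_training_setup()
        kwargs = dict(n_accept=50, seed=3, cv_folds=2, n_iter=60,
                      max_attempts=8)
        low = sample_solutions(net, pairs, accuracy_threshold=0.3, **kwargs)
        high = sample_solutions(net, pairs, accuracy_threshold=0.7, **kwargs)
        assert len(high.solutions) <= len(low.solutions)

    def test_budget_exhaustion_reports_best(self):
        net, disease, truth, pairs = toy_training_setup()
        with pytest.raises(NoCompliantSolutionError) as err:
            sample_solutions(
                net, pairs, n_accept=1, seed=4, cv_folds=1,
                accuracy_threshold=1.1, n_iter=10, max_attempts=2,
            )
        assert 0 <= err.value.best_accuracy <= 1


class TestAggregation:
    def test_identical_solutions_equal_single_map(self):
        net, disease, truth, pairs = toy_training_setup()
        stim = pairs[0].input
        sol = MoASolution(truth.hidden_params, 1.0, 1.0)
        ens = MoAEnsemble([sol, sol, sol], stim, (), seed=0)
        mean = aggregate_activities(ens, net)
        single = propagate(net, truth.hidden_params, stim)
        for acc in net.node_order:
            assert mean[acc] == pytest.approx(single[acc])

    def test_mean_matches_recompute_oracle(self, rng):
        net, disease, truth, pairs = toy_training_setup()
        stim = pairs[0].input
        sols = [
            MoASolution(
                PropagationParameters(
                    rng.uniform(0, 1.5, net.n_edges),
                    rng.normal(0, 0.1, net.n_nodes),
                ),
                1.0,
                1.0,
            )
            for _ in range(5)
        ]
        ens = MoAEnsemble(sols, stim, (), seed=0)
        mean = aggregate_activities(ens, net)
        maps = [propagate(net, s.params, stim) for s in sols]
        for acc in net.node_order:
            expected = np.mean([m[acc] for m in maps])
            assert mean[acc] == pytest.approx(expected)

    def test_empty_ensemble_rejected(self):
        net, *_ = toy_training_setup()
        ens = MoAEnsemble([], None, (), seed=0)
        with pytest.raises(EmptyEnsembleError):
            aggregate_activities(ens, net)


class TestEnsembleArchive:
    def test_save_load_roundtrip_preserves_aggregation(self, tmp_path):
        from netsynergy.sampling import load_ensemble, save_ensemble

        net, disease, truth, pairs = toy_training_setup()
        stim = pairs[0].input
        ens = sample_solutions(net, pairs, n_accept=2, seed=7, cv_folds=1,
                               accuracy_threshold=0.5, n_iter=60,
                               stimulus=stim)
        path = tmp_path / "ensemble.json"
        save_ensemble(ens, path)
        back = load_ensemble(path, stimulus=stim)
        assert len(back.solutions) == len(ens.solutions)
        m1 = aggregate_activities(ens, net)
        m2 = aggregate_activities(back, net)
        for acc in net.node_order:
            assert m1[acc] == pytest.approx(m2[acc], abs=1e-12)


class TestMoASubnetwork:
    def test_zero_delta_keeps_all_nonzero(self, chain_network):
        activity = {"A": -1.0, "B": 0.5, "C": 0.0, "D": 0.2}
        moa = extract_moa_subnetwork(chain_network, activity, nonnull_delta=0.0)
        assert set(moa.network.node_order) == {"A", "B", "C", "D"}

    def test_delta_above_one_empties_subnetwork(self, chain_network):
        activity = {"A": -1.0, "B": 0.5}
        moa = extract_moa_subnetwork(chain_network, activity, nonnull_delta=1.1)
        assert moa.network.n_nodes == 0

    def test_threshold_scan_oracle(self, rng):
        net = generate_network(40, 120, 0.3, seed=6)
        activity = {
            a: float(rng.uniform(-1, 1)) for a in net.node_order
        }
        moa = extract_moa_subnetwork(net, activity, nonnull_delta=0.3)
        expected = {a for a, v in activity.items() if abs(v) >= 0.3}
        assert set(moa.network.node_order) == expected
        # edges restricted to retained nodes
        for e in moa.network.edges:
            assert e.source.accession in expected
            assert e.target.accession in expected
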