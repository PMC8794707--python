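"""Proximity features, the relationship scorer and score banding."""

import networkx as nx
import numpy as np
import pytest

from netsynergy.errors import (
    DegenerateTrainingSetError,
    EmptySetError,
    InsufficientNullError,
    InvalidScoreError,
)
from netsynergy.fixtures import load_drug_score_table, load_target_score_table
from netsynergy.knowledge_base import InteractionEdge, ProteinNetwork, ProteinRef
from netsynergy.scoring import (
    calibrate_score_pvalues,
    categorize_score,
    compute_proximity_features,
    score_relationship,
    train_relationship_scorer,
)
from netsynergy.synthetic import generate_disease, generate_drug, generate_network

from conftest import make_network, random_triples


class TestCategorize:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (89, "+++"),
            (74, "++"),
            (56, "+"),
            (5, "-"),
            (78, "+++"),   # lower-inclusive HIGH boundary
            (71, "++"),    # published boundary cell: 71 is MEDIUM-HIGH
            (47, "+"),     # published boundary cell: 47 is MEDIUM
            (46.999, "-"),
            (0, "-"),
            (100, "+++"),
        ],
    )
    def test_bands(self, value, expected):
        assert categorize_score(value) == expected

    @pytest.mark.parametrize("value", [-0.1, 100.1, 150])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(InvalidScoreError):
            categorize_score(value)

    def test_reproduces_every_published_cell(self):
        """Banding must reproduce all printed score/category pairs of the
        packaged drug-level and target-level mRCC tables."""
        for table in (load_drug_score_table(), load_target_score_table()):
            for row in table.itertuples(index=False):
                assert categorize_score(row.score) == row.category


class TestProximityFeatures:
    def test_identical_sets_have_zero_distance_full_overlap(self, rng):
        net = make_network(random_triples(rng, 10, 25))
        members = net.node_order[:3]
        f = compute_proximity_features(net, members, members, n_null=50)
        assert f.mean_min_distance == 0
        assert f.overlap_fraction == 1

    def test_disjoint_components_use_sentinel(self):
        net = make_network([("A", "B", 1), ("C", "D", 1)])
        f = compute_proximity_features(net, ["A"], ["C"], n_null=50)
        assert f.mean_min_distance == net.n_nodes
        assert f.overlap_fraction == 0

    def test_mean_distance_matches_bfs_oracle(self, rng):
        net = make_network(random_triples(rng, 30, 70))
        targets = list(net.node_order[:5])
        effectors = list(net.node_order[10:14])
        f = compute_proximity_features(net, targets, effectors, n_null=50)
        g = net.to_undirected_graph()
        dists = []
        for t in sorted(targets):
            best = net.n_nodes
            for e in effectors:
                try:
                    best = min(best, nx.shortest_path_length(g, t, e))
                except nx.NetworkXNoPath:
                    pass
            dists.append(best)
        assert f.mean_min_distance == pytest.approx(np.mean(dists))

    def test_empty_set_rejected(self, chain_network):
        with pytest.raises(EmptySetError):
            compute_proximity_features(chain_network, [], ["A"])
        with pytest.raises(EmptySetError):
            compute_proximity_features(chain_network, ["ZZZ"], ["A"])


def _planted_study(seed, n_nodes=120, n_edges=420):
    """Network + disease + planted drug + random decoy sets for scorer tests."""
    net = generate_network(n_nodes, n_edges, 0.3, seed)
    disease, truth = generate_disease(net, [8, 6], overlap_frac=0.1, seed=seed)
    rng = np.random.default_rng(seed)
    motive = disease.motive_names[0]
    drug = generate_drug(net, truth, motive, 3, 0.0, seed)
    effectors = disease.motive(motive).accessions
    positives, negatives = [], []
    for m in disease.motive_names:
        regs = sorted(truth.planted_regulators[m])
        eff = disease.motive(m).accessions
        for k in range(8):
            take = [regs[i] for i in rng.choice(len(regs), 2, replace=False)]
            positives.append((take, eff))
            rand = [
                net.node_order[i]
                for i in rng.choice(net.n_nodes, 3, replace=False)
            ]
            negatives.append((rand, eff))
    return net, drug, effectors, positives, negatives


class TestScorer:
    def test_separable_training_reaches_high_resubstitution(self):
        net, drug, effectors, pos, neg = _planted_study(seed=2)
        scorer = train_relationship_scorer(pos, neg, net, seed=0)
        correct = 0
        for targets, eff in pos:
            correct += score_relationship(scorer, net, targets, eff).value >= 50
        for targets, eff in neg:
            correct += score_relationship(scorer, net, targets, eff).value < 50
        assert correct / (len(pos) + len(neg)) >= 0.9

    def test_same_seed_gives_identical_scores(self):
        net, drug, effectors, pos, neg = _planted_study(seed=3)
        s1 = train_relationship_scorer(pos, neg, net, seed=7)
        s2 = train_relationship_scorer(pos, neg, net, seed=7)
        probe = score_relationship(s1, net, drug.accessions, effectors)
        assert probe.value == score_relationship(
            s2, net, drug.accessions, effectors
        ).value

    def test_label_shuffle_breaks_separation(self):
        """With labels shuffled, held-out accuracy should hover at chance."""
        net, drug, effectors, pos, neg = _planted_study(seed=4)
        rng = np.random.default_rng(0)
        all_pairs = list(pos) + list(neg)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        accs = []
        for rep in range(10):
            perm = rng.permutation(len(labels))
            shuffled = labels[perm]
            half = len(all_pairs) // 2
            train_p = [all_pairs[i] for i in range(half) if shuffled[i] == 1]
            train_n = [all_pairs[i] for i in range(half) if shuffled[i] == 0]
            if min(len(train_p), len(train_n)) < 5:
                continue
            scorer = train_relationship_scorer(
                train_p, train_n, net, seed=rep
            )
            ok = 0
            for i in range(half, len(all_pairs)):
                t, e = all_pairs[i]
                v = score_relationship(scorer, net, t, e).value
                ok += (v >= 50) == bool(shuffled[i])
            accs.append(ok / (len(all_pairs) - half))
        assert 0.35 <= np.median(accs) <= 0.65

    def test_single_class_rejected(self):
        net, drug, effectors, pos, neg = _planted_study(seed=5)
        with pytest.raises(DegenerateTrainingSetError):
            train_relationship_scorer(pos, [], net, seed=0)
        with pytest.raises(DegenerateTrainingSetError):
            train_relationship_scorer(pos[:2], neg[:2], net, seed=0)

    def test_scores_in_codomain_and_unmapped_rejected(self):
        net, drug, effectors, pos, neg = _planted_study(seed=6)
        scorer = train_relationship_scorer(pos, neg, net, seed=0)
        score = score_relationship(scorer, net, drug.accessions, effectors)
        assert 0 <= score.value <= 100
        assert score.category in {"+++", "++", "+", "-"}
        with pytest.raises(EmptySetError):
            score_relationship(scorer, net, ["UNKNOWN"], effectors)

    def test_isomorphism_invariance(self):
        """Relabelling every node must not change the score."""
        net, drug, effectors, pos, neg = _planted_study(seed=8)
        mapping = {a: f"X_{a}" for a in net.node_order}

        def relabel_net(network):
            from netsynergy.knowledge_base import (
                InteractionEdge,
                ProteinNetwork,
                ProteinRef,
            )

            return ProteinNetwork(
                nodes=[ProteinRef(mapping[a]) for a in network.node_order],
                edges=[
                    InteractionEdge(
                        ProteinRef(mapping[e.source.accession]),
                        ProteinRef(mapping[e.target.accession]),
                        e.sign,
                    )
                    for e in network.edges
                ],
            )

        net2 = relabel_net(net)
        pos2 = [([mapping[a] for a in t], {mapping[a] for a in e})
                for t, e in pos]
        neg2 = [([mapping[a] for a in t], {mapping[a] for a in e})
                for t, e in neg]
        s1 = train_relationship_scorer(pos, neg, net, seed=1)
        s2 = train_relationship_scorer(pos2, neg2, net2, seed=1)
        v1 = score_relationship(s1, net, drug.accessions, effectors).value
        v2 = score_relationship(
            s2, net2, {mapping[a] for a in drug.accessions},
            {mapping[a] for a in effectors},
        ).value
        assert v1 == pytest.approx(v2, abs=1e-9)


class TestScorerPersistence:
    def test_save_load_scores_identically(self, tmp_path):
        from netsynergy.scoring import RelationshipScorer

        net, drug, effectors, pos, neg = _planted_study(seed=12)
        scorer = train_relationship_scorer(pos, neg, net, seed=0)
        calibrate_score_pvalues(scorer, net, effectors, n_null=100, seed=1,
                                target_size=3)
        path = tmp_path / "scorer.joblib"
        scorer.save(path)
        back = RelationshipScorer.load(path)
        s1 = score_relationship(scorer, net, drug.accessions, effectors)
        s2 = score_relationship(back, net, drug.accessions, effectors)
        assert s1.value == s2.value
        assert back.calibration.p_value(s1.value) == pytest.approx(
            scorer.calibration.p_value(s1.value)
        )


class TestCalibration:
    def test_empirical_p_properties(self):
        net, drug, effectors, pos, neg = _planted_study(seed=9)
        scorer = train_relationship_scorer(pos, neg, net, seed=0)
        cal = calibrate_score_pvalues(
            scorer, net, effectors, n_null=200, seed=1, target_size=3
        )
        median = float(np.median(cal.null_scores))
        assert 0.4 <= cal.p_value(median) <= 0.6
        top = float(cal.null_scores[-1])
        assert cal.p_value(top + 1e-9) <= 1 / cal.n_null + 1e-12
        grid = np.linspace(0, 100, 41)
        ps = [cal.p_value(s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_insufficient_null_rejected(self):
        net, drug, effectors, pos, neg = _planted_study(seed=10)
        scorer = train_relationship_scorer(pos, neg, net, seed=0)
        with pytest.raises(InsufficientNullError):
            calibrate_score_pvalues(scorer, net, effectors, n_null=50)
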