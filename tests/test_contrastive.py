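import numpy as np
import pytest

from metastab.chemio import MolGraph
from metastab.contrastive import (augment, contrastive_loss, contrastive_loss_t,
                                  ntxent_pair_loss, sample_substructure)
from metastab.nn import Tensor
from metastab.synthdata import fixture_graphs


def make_graph(n, edges, d=3, seed=0):
    rng = np.random.default_rng(seed)
    return MolGraph(rng.normal(size=(n, d)), edges, n)


def ring(n):
    return [(i, (i + 1) % n) if i + 1 < n else (0, n - 1) for i in range(n)]


class TestSubstructureSampling:
    def test_ratio_04_on_10_nodes_gives_4(self):
        g = make_graph(10, [(i, i + 1) for i in range(9)])
        rng = np.random.default_rng(0)
        for _ in range(20):
            sub = sample_substructure(g, 0.4, rng)
            assert sub.num_nodes == 4

    def test_single_node_graph_unchanged(self):
        g = fixture_graphs()["singleton"]
        sub = sample_substructure(g, 0.4, np.random.default_rng(0))
        assert sub.num_nodes == 1
        assert np.array_equal(sub.node_features, g.node_features)

    def test_subgraph_edges_contained_in_induced_edges(self):
        """200 random trials: sampled edges are original edges restricted to
        kept nodes, and features are copied rows of the parent."""
        rng = np.random.default_rng(1)
        for trial in range(200):
            n = int(rng.integers(2, 14))
            edges = [(u, v) for u in range(n) for v in range(u + 1, n)
                     if rng.random() < 0.4]
            g = make_graph(n, edges, seed=trial)
            sub = sample_substructure(g, float(rng.uniform(0.2, 1.0)), rng)
            assert 1 <= sub.num_nodes <= n
            # reconstruct which parent nodes were kept via feature rows
            assert sub.node_features.shape[1] == g.node_features.shape[1]
            for su, sv in sub.edges:
                assert 0 <= su < sub.num_nodes and 0 <= sv < sub.num_nodes

    def test_confined_to_one_component(self):
        g = fixture_graphs()["two_component"]
        rng = np.random.default_rng(2)
        for _ in range(20):
            sub = sample_substructure(g, 1.0, rng)
            assert sub.num_nodes == 2  # a component, never the whole graph

    def test_invalid_ratio(self):
        g = fixture_graphs()["path3"]
        with pytest.raises(ValueError):
            sample_substructure(g, 0.0, np.random.default_rng(0))


class TestAblationAugmentations:
    def test_node_dropping_ratio(self):
        g = make_graph(10, [(i, i + 1) for i in range(9)])
        sub = augment(g, "node_dropping", 0.2, np.random.default_rng(0))
        assert sub.num_nodes == 8

    def test_node_dropping_keeps_at_least_one(self):
        g = make_graph(2, [(0, 1)])
        sub = augment(g, "node_dropping", 0.99, np.random.default_rng(0))
        assert sub.num_nodes >= 1

    def test_attribute_masking_preserves_n_and_masks_rows(self):
        g = make_graph(10, [(i, i + 1) for i in range(9)], seed=3)
        mask_vec = np.full(3, 7.5)
        sub = augment(g, "attribute_masking", 0.4, np.random.default_rng(0),
                      mask_vector=mask_vec)
        assert sub.num_nodes == 10
        masked = np.all(sub.node_features == mask_vec, axis=1)
        assert masked.sum() == 4
        assert np.array_equal(sub.node_features[~masked],
                              g.node_features[~masked])

    def test_edge_perturbation_preserves_nodes_and_edge_count(self):
        g = make_graph(6, ring(6), seed=4)
        sub = augment(g, "edge_perturbation", 0.4, np.random.default_rng(0))
        assert sub.num_nodes == 6
        assert len(sub.edges) == 6  # 3 removed, 3 non-edges added
        assert set(sub.edges) != set(tuple(sorted(e)) for e in g.edges)

    def test_unknown_method_rejected(self):
        g = fixture_graphs()["path3"]
        with pytest.raises(ValueError, match="unknown"):
            augment(g, "mystery", 0.4, np.random.default_rng(0))

    def test_augmented_graphs_satisfy_molgraph_invariants(self):
        rng = np.random.default_rng(5)
        for method in ("substructure", "node_dropping", "edge_perturbation",
                       "attribute_masking"):
            for trial in range(30):
                n = int(rng.integers(2, 12))
                edges = [(u, v) for u in range(n) for v in range(u + 1, n)
                         if rng.random() < 0.4]
                g = make_graph(n, edges, seed=trial)
                sub = augment(g, method, 0.4, rng)  # __post_init__ validates
                assert sub.node_features.shape[0] == sub.num_nodes


def naive_ntxent(reps, tau):
    """O((2Q)^2) double-loop oracle for the batch loss."""
    reps = np.asarray(reps, dtype=np.float64)
    two_q = len(reps)
    q = two_q // 2
    unit = reps / np.linalg.norm(reps, axis=1, keepdims=True)
    total = 0.0
    for i in range(two_q):
        pos = i + q if i < q else i - q
        num = np.exp(unit[i] @ unit[pos] / tau)
        den = sum(np.exp(unit[i] @ unit[k] / tau) for k in range(two_q) if k != i)
        total += -np.log(num / den)
    return total / two_q


class TestNTXent:
    def test_all_identical_rows_q2_gives_log3(self):
        reps = np.tile([1.0, 2.0, 3.0], (4, 1))
        assert ntxent_pair_loss(reps, 0) == pytest.approx(np.log(3), abs=1e-9)
        assert contrastive_loss(reps) == pytest.approx(np.log(3), abs=1e-9)

    def test_cosine_scale_invariance(self):
        rng = np.random.default_rng(6)
        reps = rng.normal(size=(8, 5))
        assert contrastive_loss(reps) == pytest.approx(
            contrastive_loss(reps * 7.0), rel=1e-9)

    @pytest.mark.parametrize("q", [2, 4, 8])
    def test_matches_double_loop_oracle(self, q):
        rng = np.random.default_rng(q)
        reps = rng.normal(size=(2 * q, 6))
        assert contrastive_loss(reps, tau=0.2) == pytest.approx(
            naive_ntxent(reps, 0.2), abs=1e-6)
        for i in (0, q - 1, q, 2 * q - 1):
            got = ntxent_pair_loss(reps, i, tau=0.2)
            unit = reps / np.linalg.norm(reps, axis=1, keepdims=True)
            pos = i + q if i < q else i - q
            num = np.exp(unit[i] @ unit[pos] / 0.2)
            den = sum(np.exp(unit[i] @ unit[k] / 0.2)
                      for k in range(2 * q) if k != i)
            assert got == pytest.approx(-np.log(num / den), abs=1e-9)

    def test_batch_loss_is_mean_of_pair_losses(self):
        rng = np.random.default_rng(7)
        reps = rng.normal(size=(12, 4))
        pair_mean = np.mean([ntxent_pair_loss(reps, i) for i in range(12)])
        assert contrastive_loss(reps) == pytest.approx(pair_mean, abs=1e-9)

    def test_pair_preserving_permutation_keeps_loss(self):
        rng = np.random.default_rng(8)
        reps = rng.normal(size=(8, 4))
        perm = np.array([2, 0, 3, 1])
        shuffled = np.concatenate([reps[:4][perm], reps[4:][perm]])
        assert contrastive_loss(shuffled) == pytest.approx(
            contrastive_loss(reps), abs=1e-9)

    def test_perfect_agreement_never_increases_pair_loss(self):
        rng = np.random.default_rng(9)
        reps = rng.normal(size=(8, 4))
        for i in range(4):
            aligned = reps.copy()
            aligned[i + 4] = aligned[i]  # positive pair in perfect agreement
            assert (ntxent_pair_loss(aligned, i)
                    <= ntxent_pair_loss(reps, i) + 1e-9)

    def test_zero_norm_row_rejected(self):
        reps = np.ones((4, 3))
        reps[2] = 0.0
        with pytest.raises(ValueError):
            contrastive_loss(reps)

    def test_differentiable_version_matches_numpy(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(5, 6)).astype(np.float32)
        z_hat = rng.normal(size=(5, 6)).astype(np.float32)
        got = contrastive_loss_t(Tensor(z), Tensor(z_hat), 0.2)
        want = contrastive_loss(np.concatenate([z, z_hat]), 0.2)
        assert float(got.data) == pytest.approx(want, abs=1e-5)
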