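import numpy as np
import pytest

import metastab as ms
from metastab.chemio import parse_molecule
from metastab.interpret import (Explanation, TokenAlignmentError,
                                attention_explanation, bond_weights_from_atoms,
                                edge_shapley, group_frequency_report,
                                shapley_values)
from metastab.synthdata import SynthSpec, fixture_graphs, generate_dataset


@pytest.fixture(scope="module")
def trained(tiny_params):
    """Small model trained on clean planted-motif data (shared by the module)."""
    ds, truth = generate_dataset(SynthSpec(n=300, noise=0.0, seed=21))
    est = ms.StabilityClassifier(**tiny_params, epochs=10, seed=1)
    est.fit(ds.molecules, ds.labels)
    return est, ds, truth


class TestAttentionExplanation:
    def test_atom_weights_simplex(self, trained):
        est, ds, _ = trained
        for mol in ds.molecules[:10]:
            expl = attention_explanation(est, mol)
            assert expl.atom_weights.shape == (mol.num_atoms,)
            assert np.all(expl.atom_weights >= 0)
            assert expl.atom_weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_bond_weight_is_mean_of_endpoints(self, trained):
        est, ds, _ = trained
        for mol in ds.molecules[:10]:
            expl = attention_explanation(est, mol)
            for (u, v), w in expl.bond_weights.items():
                assert w == pytest.approx(
                    (expl.atom_weights[u] + expl.atom_weights[v]) / 2, abs=1e-9)

    def test_bond_rule_hand_example(self):
        w = bond_weights_from_atoms(np.array([0.6, 0.2, 0.2]), [(0, 1), (1, 2)])
        assert w[(0, 1)] == pytest.approx(0.4)
        assert w[(1, 2)] == pytest.approx(0.2)

    def test_alignment_failure_reported(self, trained):
        est, _, _ = trained
        # explicit H token merges into the carbon on sanitization: 2 atom
        # tokens but a single graph atom
        with pytest.raises(TokenAlignmentError):
            attention_explanation(est, "C[H]")


class TestShapley:
    def test_single_edge_is_exact_marginal(self, trained):
        est, _, _ = trained
        mol = parse_molecule("CC")
        expl = edge_shapley(est, mol, n_samples=5, rng=np.random.default_rng(0))
        _, s_vec = est.sequence_attention(mol)
        f_full = est.score_graph_variants([mol.graph], s_vec)[0]
        f_empty = est.score_graph_variants([mol.graph.with_edges([])], s_vec)[0]
        assert expl.edge_shapley[(0, 1)] == pytest.approx(f_full - f_empty,
                                                          abs=1e-6)
        assert expl.shapley_se[(0, 1)] == pytest.approx(0.0, abs=1e-7)

    def test_efficiency_axiom_exact_under_permutation_sampling(self):
        g = fixture_graphs()["benzene"]
        rng = np.random.default_rng(1)
        weights = {tuple(sorted(e)): rng.normal() for e in g.edges}

        def value_fn(subsets):
            # nonlinear coalition game so marginals genuinely vary
            return np.array([sum(weights[tuple(sorted(e))] for e in s) ** 2
                             + 0.3 * len(s) for s in subsets])

        phi, se = shapley_values(g, value_fn, n_samples=200,
                                 rng=np.random.default_rng(2))
        f_all = value_fn([list(g.edges)])[0]
        f_none = value_fn([[]])[0]
        assert sum(phi.values()) == pytest.approx(f_all - f_none, abs=1e-9)

    def test_symmetry_axiom_on_equivalent_edges(self):
        """All benzene-ring edges are automorphic; under a symmetric game
        their Shapley estimates agree within sampling error."""
        g = fixture_graphs()["benzene"]

        def value_fn(subsets):
            return np.array([np.sqrt(len(s) + 1.0) for s in subsets])

        phi, se = shapley_values(g, value_fn, n_samples=400,
                                 rng=np.random.default_rng(3))
        vals = list(phi.values())
        ses = list(se.values())
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                bound = 3 * np.hypot(ses[i], ses[j]) + 1e-9
                assert abs(vals[i] - vals[j]) <= bound

    def test_standard_error_shrinks_with_sample_size(self):
        g = fixture_graphs()["benzene"]
        rng = np.random.default_rng(4)
        weights = {tuple(sorted(e)): rng.uniform(0.5, 2.0) for e in g.edges}

        def value_fn(subsets):
            return np.array([np.log1p(sum(weights[tuple(sorted(e))] for e in s))
                             for s in subsets])

        _, se_small = shapley_values(g, value_fn, n_samples=100,
                                     rng=np.random.default_rng(5))
        _, se_big = shapley_values(g, value_fn, n_samples=1600,
                                   rng=np.random.default_rng(6))
        ratio = np.mean(list(se_small.values())) / np.mean(list(se_big.values()))
        # expected ratio sqrt(1600/100) = 4, allow sampling slack
        assert 2.5 < ratio < 6.0

    def test_deterministic_under_fixed_rng(self, trained):
        est, ds, _ = trained
        mol = ds.molecules[0]
        a = edge_shapley(est, mol, n_samples=50, rng=np.random.default_rng(9))
        b = edge_shapley(est, mol, n_samples=50, rng=np.random.default_rng(9))
        assert a.edge_shapley == b.edge_shapley

    def test_empty_edge_graph(self, trained):
        est, _, _ = trained
        mol = parse_molecule("C")
        expl = edge_shapley(est, mol, n_samples=5, rng=np.random.default_rng(0))
        assert expl.edge_shapley == {}


class TestFrequencyReport:
    def _expl(self, smiles, shapley, label):
        mol = parse_molecule(smiles)
        n = mol.num_atoms
        aw = np.full(n, 1.0 / n)
        return Explanation(molecule_id=smiles, smiles=smiles, atom_weights=aw,
                           bond_weights=bond_weights_from_atoms(aw, mol.graph.edges),
                           edge_shapley=shapley, predicted_label=label, score=float(label))

    def test_empty_input(self):
        assert group_frequency_report([]).empty

    def test_no_bond_over_threshold(self):
        mol = parse_molecule("CCCC")
        shap = {e: 0.05 for e in mol.graph.edges}
        report = group_frequency_report([self._expl("CCCC", shap, 1)])
        assert report.empty

    def test_planted_motif_ranks_first_for_stable_class(self):
        """Every predicted-stable molecule carries one high-value acetylene
        bond; the acetylene fragment must dominate the stable table."""
        expls = []
        for scaffold in ("CCC", "CCCC", "CCCCC"):
            smiles = scaffold + "C#C"
            mol = parse_molecule(smiles)
            edges = sorted(mol.graph.edges)
            shap = {e: 0.01 for e in edges}
            shap[edges[-1]] = 0.9  # the triple bond at the tail
            expls.append(self._expl(smiles, shap, 1))
        # one unstable molecule with a different hot fragment
        mol = parse_molecule("CCO")
        expls.append(self._expl("CCO", {e: 0.5 for e in mol.graph.edges}, 0))
        report = group_frequency_report(expls, threshold=0.2, top=10)
        stable = report[report.predicted_class == "stable"]
        assert len(stable) >= 1
        top_row = stable.iloc[0]
        assert "#" in top_row.substructure
        assert top_row["count"] == 3
        assert top_row.percentage == pytest.approx(100.0)

    def test_threshold_applied(self):
        mol = parse_molecule("CCCC")
        edges = sorted(mol.graph.edges)
        shap = {e: 0.0 for e in edges}
        shap[edges[0]] = 0.21
        report = group_frequency_report([self._expl("CCCC", shap, 1)],
                                        threshold=0.2)
        assert len(report) == 1
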