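import numpy as np
import pytest

import metastab as ms
from metastab.model_train import (ModelConfig, Prediction, StabilityClassifier,
                                  aggregate_reports, cluster_molecules,
                                  crossval, evaluate, evaluate_scores,
                                  leave_one_cluster_out, total_loss)
from metastab.synthdata import SynthSpec, generate_dataset


def scores_for_confusion(tp, fp, tn, fn):
    y = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    s = [0.9] * (tp + fp) + [0.1] * (tn + fn)
    return np.array(y), np.array(s)


class TestLossComposition:
    def test_lambda_zero_reduces_to_classification(self):
        logits = np.array([0.3, -1.2, 2.0])
        labels = np.array([1, 0, 1])
        L, L_C, L_CL = total_loss(logits, labels, contrastive=5.0, lam=0.0)
        assert L == L_C

    def test_weighted_sum_exact(self):
        # L_C = 2.0 is achieved by construction below only approximately, so
        # check the composition contract on the returned pieces instead
        logits = np.array([0.0, 0.0])
        labels = np.array([1, 0])
        L, L_C, L_CL = total_loss(logits, labels, contrastive=3.0, lam=0.1)
        assert L == L_C + 0.1 * L_CL
        assert L_CL == 3.0
        assert total_loss(np.array([0.0]), np.array([1]), 0.0, 0.1)[1] == \
            pytest.approx(np.log(2))

    def test_arithmetic_example(self):
        # with L_C pinned by zero logits: 2 * log(2); lambda = 0.1
        L, L_C, L_CL = total_loss(np.zeros(2), np.array([1, 0]), 3.0, 0.1)
        assert L == pytest.approx(2 * np.log(2) + 0.3)

    def test_cross_entropy_monotone_in_confident_logit(self):
        losses = [total_loss(np.array([l]), np.array([1]), 0.0, 0.0)[1]
                  for l in (1.0, 5.0, 10.0)]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-4


class TestEvaluate:
    def test_perfect_separation(self):
        rep = evaluate_scores([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.auc == 1.0 and rep.mcc == 1.0 and rep.accuracy == 1.0

    def test_balanced_random_closed_form(self):
        y, s = scores_for_confusion(tp=5, fp=5, tn=5, fn=5)
        rep = evaluate_scores(y, s)
        assert rep.mcc == pytest.approx(0.0)
        assert rep.accuracy == pytest.approx(0.5)

    def test_hand_confusion_matrix(self):
        y, s = scores_for_confusion(tp=8, fp=2, tn=6, fn=4)
        rep = evaluate_scores(y, s)
        assert rep.accuracy == pytest.approx(0.70)
        assert rep.f1 == pytest.approx(16 / 22, abs=1e-4)
        # MCC denominator: (TP+FP)(TP+FN)(TN+FP)(TN+FN) = 10*12*8*10
        assert rep.mcc == pytest.approx((8 * 6 - 2 * 4) / np.sqrt(10 * 12 * 8 * 10),
                                        abs=1e-4)

    def test_auc_matches_all_pairs_rank_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(4, 24))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse scores exercise ties
            pos, neg = s[y == 1], s[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert evaluate_scores(y, s).auc == pytest.approx(oracle, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_scores([1, 1, 1], [0.2, 0.5, 0.9])

    def test_evaluate_prediction_objects(self):
        preds = [Prediction("a", 0.9, 1), Prediction("b", 0.2, 0)]
        rep = evaluate(preds)
        assert rep.auc == 1.0
        with pytest.raises(ValueError):
            evaluate([Prediction("a", 0.9, None), Prediction("b", 0.2, 0)])


class TestEstimator:
    def test_default_predictor_widths_768_256_1(self):
        ds, _ = generate_dataset(SynthSpec(n=20, noise=0.0, seed=0))
        est = StabilityClassifier(epochs=0, embed_epochs=1)
        est.fit(ds.molecules, ds.labels)
        assert est.predictor_.dims == (768, 256, 1)
        assert est.gin_.d3 + est.d_s == 768

    def test_zero_predictor_weights_score_half_and_range(self, tiny_params):
        ds, _ = generate_dataset(SynthSpec(n=20, noise=0.0, seed=0))
        est = StabilityClassifier(**tiny_params, epochs=0)
        est.fit(ds.molecules, ds.labels)
        scores = est.predict_proba(ds.molecules)[:, 1]
        assert np.all((scores > 0) & (scores < 1))
        for _, mod in est.predictor_.layers:
            if mod is not None:
                mod.weight.data[:] = 0
                mod.bias.data[:] = 0
        assert np.allclose(est.predict_proba(ds.molecules)[:, 1], 0.5)

    def test_single_class_training_rejected(self, tiny_params):
        ds, _ = generate_dataset(SynthSpec(n=20, noise=0.0, seed=0))
        y = np.ones(len(ds), dtype=int)
        with pytest.raises(ValueError, match="both classes"):
            StabilityClassifier(**tiny_params, epochs=1).fit(ds.molecules, y)

    def test_loss_decreases_on_separable_data(self, tiny_params):
        """Optimization sanity on a noise-free planted-motif set."""
        ds, _ = generate_dataset(SynthSpec(n=500, noise=0.0, seed=11))
        for seed in range(3):
            est = StabilityClassifier(**tiny_params, epochs=30, seed=seed)
            est.fit(ds.molecules, ds.labels)
            assert est.history_[-1]["loss"] < est.history_[0]["loss"]

    def test_deterministic_under_seed(self, tiny_params):
        ds, _ = generate_dataset(SynthSpec(n=60, noise=0.1, seed=2))
        runs = []
        for _ in range(2):
            est = StabilityClassifier(**tiny_params, epochs=3, seed=9)
            est.fit(ds.molecules, ds.labels)
            runs.append((est.predict_proba(ds.molecules)[:, 1],
                         [h["loss"] for h in est.history_]))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    @pytest.mark.parametrize("override", [
        {"use_sequence": False},             # graph-only ablation
        {"contrastive_weight": 0.0},         # no contrastive learning
        {"aug_method": "node_dropping", "aug_ratio": 0.2},
        {"aug_method": "edge_perturbation"},
        {"aug_method": "attribute_masking"},
        {"projection_head": True},
    ])
    def test_ablation_variants_train_and_predict(self, tiny_params, override):
        ds, _ = generate_dataset(SynthSpec(n=40, noise=0.0, seed=3))
        est = StabilityClassifier(**{**tiny_params, **override}, epochs=1, seed=0)
        est.fit(ds.molecules, ds.labels)
        assert est.predict(ds.molecules[:5]).shape == (5,)

    def test_sklearn_clone_and_get_params(self, tiny_params):
        from sklearn.base import clone
        est = StabilityClassifier(**tiny_params, contrastive_weight=0.3)
        c = clone(est)
        assert c.get_params()["contrastive_weight"] == 0.3


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = ModelConfig(epochs=7, contrastive_weight=0.25)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = ModelConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_defaults_match_recommended_settings(self):
        cfg = ModelConfig()
        assert (cfg.d1, cfg.d2) == (100, 200)
        assert cfg.gin_layers == 2
        assert (cfg.epochs, cfg.learning_rate) == (200, 5e-4)
        assert (cfg.tau, cfg.aug_ratio, cfg.contrastive_weight) == (0.2, 0.4, 0.1)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(contrastive_weight=-1.0)
        with pytest.raises(ValueError):
            ModelConfig(aug_method="bogus")


class TestProtocols:
    def test_crossval_partitions_dataset(self, tiny_params):
        ds, _ = generate_dataset(SynthSpec(n=100, noise=0.0, seed=4))
        est = StabilityClassifier(**tiny_params, epochs=1)
        reports, agg = crossval(ds, estimator=est, folds=10, seed=0)
        assert len(reports) == 10
        assert sum(r.n for r in reports) == 100
        assert set(agg) == {"auc", "accuracy", "f1", "mcc"}
        assert 0 <= agg["auc"]["mean"] <= 1

    def test_crossval_fold_count_validation(self, tiny_params):
        ds, _ = generate_dataset(SynthSpec(n=20, noise=0.0, seed=4))
        est = StabilityClassifier(**tiny_params, epochs=1)
        with pytest.raises(ValueError, match="folds"):
            crossval(ds, estimator=est, folds=19)

    def test_cluster_separation_of_duplicated_groups(self):
        """Two structurally disjoint duplicated groups (within-group Tanimoto
        1, across-group ~0) are split into two clusters."""
        smiles = ["CCCCCCCC"] * 10 + ["c1ccc2ccccc2c1"] * 10
        labels = cluster_molecules(smiles, n_clusters=2, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_leave_one_cluster_out(self, tiny_params):
        smiles = (["CCCCCCCC", "CCCCCCC", "CCCCCC", "CCCCCCCCC"] * 5
                  + ["c1ccc2ccccc2c1", "Cc1ccc2ccccc2c1",
                     "CCc1ccc2ccccc2c1", "c1ccc2cc3ccccc3cc2c1"] * 5)
        y = np.array(([0, 1, 0, 1] * 5) + ([1, 0, 1, 0] * 5))
        est = StabilityClassifier(**tiny_params, epochs=1)
        reports, labels = leave_one_cluster_out(smiles, y, estimator=est,
                                                n_clusters=2, seed=0)
        assert len(reports) == 2
        assert all(r.n == 20 for r in reports.values())

    def test_degenerate_cluster_skipped_with_warning(self, tiny_params):
        smiles = (["CCCCCCCC"] * 8 + ["c1ccc2ccccc2c1"] * 8
                  + ["O=S(=O)(O)c1ccncc1"] * 8)
        # first structural group is single-class; the other two are mixed
        y = np.array([1] * 8 + [0, 1] * 4 + [0, 1] * 4)
        est = StabilityClassifier(**tiny_params, epochs=1)
        with pytest.warns(UserWarning, match="skipped"):
            reports, _ = leave_one_cluster_out(smiles, y, estimator=est,
                                               n_clusters=3, seed=0)
        assert 1 <= len(reports) <= 2

    def test_aggregate_reports_mean_sd(self):
        reps = [evaluate_scores([0, 1], [0.2, 0.8]),
                evaluate_scores([0, 1, 0, 1], [0.6, 0.4, 0.3, 0.9])]
        agg = aggregate_reports(reps)
        assert agg["auc"]["mean"] == pytest.approx((1.0 + 0.75) / 2)
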