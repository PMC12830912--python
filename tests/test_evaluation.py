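"""Metrics, fold aggregation, ablation harness, Shapley importance."""

import numpy as np
import pytest

from entpet import classifier as clf
from entpet import evaluation as ev
from entpet import features as feat


def _pair_counting_auc(scores, labels):
    """Brute-force oracle: P(random positive outscores random negative),
    ties counting one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_hand_example(self):
        auc = ev.roc_auc_one_vs_rest(np.array([0.9, 0.8, 0.4, 0.3]),
                                     np.array([1, 0, 1, 0]), class_c=1)
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        auc = ev.roc_auc_one_vs_rest(np.array([0.9, 0.8, 0.2, 0.1]),
                                     np.array([1, 1, 0, 0]), class_c=1)
        assert auc == 1.0

    def test_null_distribution(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        auc = ev.roc_auc_one_vs_rest(scores, labels, class_c=1)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(4, 30)
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            ours = ev.roc_auc_one_vs_rest(scores, labels, class_c=1)
            assert ours == pytest.approx(_pair_counting_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc_one_vs_rest(np.array([0.1, 0.2]), np.array([1, 1]), 1)


class TestF1:
    def test_all_correct(self):
        assert ev.f1_per_class([1, 0, 1], [1, 0, 1], 1) == 1.0

    def test_formula(self):
        # TP=1, FP=1, FN=1 -> 2/(2+1+1) = 0.5
        assert ev.f1_per_class([1, 1, 0], [1, 0, 1], 1) == 0.5

    def test_empty_convention(self):
        assert ev.f1_per_class([0, 0], [0, 0], 1) == 0.0


class TestAggregation:
    def _fold(self, i, auc):
        return ev.FoldMetrics(fold=i, auc={0: auc}, f1={0: auc},
                              roc_tpr={0: np.full(101, auc)})

    def test_mean_and_sample_std(self):
        agg = ev.aggregate_folds([self._fold(0, 0.8), self._fold(1, 0.9)])
        assert agg["auc_mean"][0] == pytest.approx(0.85)
        assert agg["auc_std"][0] == pytest.approx(0.0707, abs=1e-3)

    def test_identical_folds_zero_std(self):
        agg = ev.aggregate_folds([self._fold(i, 0.8) for i in range(5)])
        assert agg["auc_std"][0] == 0.0

    def test_mean_roc_of_identical_curves(self):
        curve = np.linspace(0, 1, 101) ** 0.5
        folds = [ev.FoldMetrics(fold=i, auc={0: 0.8}, f1={0: 0.5},
                                roc_tpr={0: curve}) for i in range(3)]
        agg = ev.aggregate_folds(folds)
        assert np.allclose(agg["mean_roc"][0], curve)

    def test_requires_two_folds(self):
        with pytest.raises(ValueError):
            ev.aggregate_folds([self._fold(0, 0.8)])


@pytest.fixture(scope="module")
def trained_subset(small_dataset):
    """One cheap paired CV run on the synthetic dataset (two subsets)."""
    X, y, _ = small_dataset
    folds = clf.make_folds(y, k=3, rng_seed=5)
    tspec = clf.TrainSpec(max_epochs=4, seed=5)
    spec = clf.ModelSpec(encoder_widths=(64, 32), fusion_widths=(16,))
    out = {}
    for subset in (("E", "dphi"), ("dphi",)):
        fm, agg, models = ev.cross_validate_subset(
            X, y, subset, folds, spec, tspec, return_models=True)
        out[subset] = (fm, agg, models)
    return X, y, folds, out


class TestAblation:
    def test_report_shape_and_paired_folds(self, small_dataset):
        X, y, _ = small_dataset
        sub = np.arange(600)
        spec = clf.ModelSpec(encoder_widths=(16, 8), fusion_widths=(8,))
        tspec = clf.TrainSpec(max_epochs=2, seed=0)
        rep = ev.run_ablation(X[sub], y[sub],
                              subsets=[("E",), ("dphi",), ("E", "dphi")],
                              model_spec=spec, train_spec=tspec,
                              k=3, fold_seed=1)
        assert len(rep.subsets) == 3
        for s in rep.subsets:
            assert rep.auc_mean[s].shape == (5,)
            assert rep.f1_mean[s].shape == (5,)
        frame = rep.to_frame()
        assert len(frame) == 15
        # paired design: rerunning with the same fold seed gives the same hash
        rep2 = ev.run_ablation(X[sub], y[sub], subsets=[("E",)],
                               model_spec=spec, train_spec=tspec,
                               k=3, fold_seed=1)
        assert rep.fold_hash == rep2.fold_hash

    def test_energy_plus_dphi_dominates_dphi_alone(self, trained_subset):
        """Random-coincidence rejection with E+dphi is at least as good as
        with dphi alone (paired folds)."""
        _, _, _, out = trained_subset
        auc_both = out[("E", "dphi")][1]["auc_mean"][4]
        auc_dphi = out[("dphi",)][1]["auc_mean"][4]
        assert auc_both >= auc_dphi


class TestShapley:
    def _groups(self, d=6):
        return {"a": [0, 1], "b": [2, 3], "c": [4, 5]}

    def _model_on_group(self, groups, active, rng_seed=0):
        """Train a tiny model whose signal lives in one group only."""
        rng = np.random.default_rng(rng_seed)
        X = rng.normal(size=(600, 4, 6)).astype(np.float32)
        y = rng.integers(0, 5, 600)
        for i, lab in enumerate(y):
            if lab < 4:
                X[i, lab, groups[active]] += 4.0
        spec = clf.ModelSpec(encoder_widths=(32, 16), fusion_widths=(16,))
        model = clf.build_model(spec, 6, rng_seed=1)
        model, _ = clf.train_fold(model, X[:500], y[:500], X[500:], y[500:],
                                  clf.TrainSpec(max_epochs=15, seed=1))
        return model, X

    def test_trained_group_dominates(self):
        groups = self._groups()
        model, X = self._model_on_group(groups, "b")
        base = X.reshape(-1, 6).mean(axis=0)
        att = ev.shapley_group_importance(model, X[:64], groups, base,
                                          n_permutations=30, rng_seed=2)
        imp = np.abs(att).mean(axis=0)
        assert imp[1] > imp[0] and imp[1] > imp[2]

    def test_duplicated_groups_equal_importance(self):
        """Shapley symmetry axiom: interchangeable players (identical
        columns entering the model through identical weights) receive equal
        attribution up to Monte-Carlo error."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 4, 4)).astype(np.float32)
        y = rng.integers(0, 5, 500)
        for i, lab in enumerate(y):
            if lab < 4:
                X[i, lab, 0] += 3.0
        X[:, :, 1] = X[:, :, 0]                # exact duplicate column
        spec = clf.ModelSpec(encoder_widths=(16, 8), fusion_widths=(8,))
        model = clf.build_model(spec, 4, rng_seed=4)
        model, _ = clf.train_fold(model, X[:400], y[:400], X[400:], y[400:],
                                  clf.TrainSpec(max_epochs=10, seed=4))
        # make the game symmetric in the two players: tie the first-layer
        # weight rows of the duplicated columns
        w = model.params["enc0_W"]
        w[[0, 1]] = w[[0, 1]].mean(axis=0)
        groups = {"g1": [0], "g2": [1], "rest": [2, 3]}
        base = X.reshape(-1, 4).mean(axis=0)
        att = ev.shapley_group_importance(model, X[:64], groups, base,
                                          n_permutations=400, rng_seed=5)
        imp = np.abs(att).mean(axis=0)
        assert imp[0] == pytest.approx(imp[1], rel=0.15)

    def test_efficiency_axiom(self):
        groups = self._groups()
        model, X = self._model_on_group(groups, "a", rng_seed=6)
        base = X.reshape(-1, 6).mean(axis=0)
        Z = X[:32]
        att = ev.shapley_group_importance(model, Z, groups, base,
                                          n_permutations=100, rng_seed=7)
        pred_class = clf.predict(model, Z).argmax(axis=1)
        full = clf.predict(model, Z)[np.arange(32), pred_class]
        B = np.broadcast_to(base, Z.shape).copy().astype(np.float32)
        none = clf.predict(model, B)[np.arange(32), pred_class]
        assert np.allclose(att.sum(axis=1), full - none, atol=1e-5)

    def test_reproducible_under_seed(self):
        groups = self._groups()
        model, X = self._model_on_group(groups, "c", rng_seed=8)
        base = X.reshape(-1, 6).mean(axis=0)
        a = ev.shapley_group_importance(model, X[:16], groups, base,
                                        n_permutations=20, rng_seed=9)
        b = ev.shapley_group_importance(model, X[:16], groups, base,
                                        n_permutations=20, rng_seed=9)
        assert np.array_equal(a, b)

    def test_few_permutations_warn(self):
        groups = {"a": [0, 1, 2, 3, 4, 5]}
        model, X = self._model_on_group(self._groups(), "a", rng_seed=10)
        base = X.reshape(-1, 6).mean(axis=0)
        with pytest.warns(UserWarning, match="permutations"):
            ev.shapley_group_importance(model, X[:4], groups, base,
                                        n_permutations=5, rng_seed=11)

    def test_importance_report_over_folds(self, trained_subset):
        X, y, folds, out = trained_subset
        _, _, models = out[("E", "dphi")]
        rep = ev.importance_report(models, X, y, ("E", "dphi"), folds,
                                   n_permutations=15, rng_seed=12,
                                   n_samples=64)
        assert rep.per_fold.shape == (3, 2)
        assert np.all(rep.mean >= 0.0)
        assert rep.groups == ["E", "dphi"]
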