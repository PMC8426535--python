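"""Training-machinery tests: folds, alternation scheme, ensembling,
threshold tuning, and the hyperparameter-search harness."""

import numpy as np
import pytest

from subloc.encoding import EncodedProtein
from subloc.hierarchy import load_hierarchy
from subloc.network import Model, ModelConfig, ScoreMatrix
from subloc.synthetic_data import SimConfig, ClassSpec, nls_motif, pts1_motif, \
    signal_peptide_motif, simulate_proteome, toy_hierarchy
from subloc.training import (
    EnsembleModel,
    ThresholdSet,
    bayes_search,
    ensemble_predict,
    make_folds,
    prepare_samples,
    train_submodel,
    tune_thresholds,
)


class _Stub:
    def __init__(self, cluster_id=None):
        self.cluster_id = cluster_id


class TestFolds:
    def test_even_random_folds(self):
        plan = make_folds([_Stub() for _ in range(16)], k=8, seed=0)
        sizes = np.bincount(plan.assignment, minlength=8)
        assert list(sizes) == [2] * 8

    def test_cluster_mode_never_splits_clusters(self):
        records = (
            [_Stub("c1")] * 5 + [_Stub("c2")] * 5 + [_Stub("c3")] * 6
        )
        plan = make_folds(records, k=2, mode="cluster", seed=0)
        ids = np.array([r.cluster_id for r in records])
        for cid in ("c1", "c2", "c3"):
            assert len(set(plan.assignment[ids == cid])) == 1

    def test_same_seed_same_plan(self):
        records = [_Stub() for _ in range(23)]
        a = make_folds(records, k=5, seed=42)
        b = make_folds(records, k=5, seed=42)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds([_Stub(), _Stub()], k=3)

    def test_cluster_mode_requires_ids(self):
        with pytest.raises(ValueError, match="cluster_id"):
            make_folds([_Stub("c1"), _Stub(None)], k=2, mode="cluster")


def _mixed_tiny_samples(seed=0):
    sim = SimConfig(
        classes=[
            ClassSpec("sig", "mitochondrion", "mitochondrial matrix",
                      signal_peptide_motif()),
            ClassSpec("bg", "cytoplasm", "cytosol", None),
        ],
        n_per_class=10, length_range=(50, 80), lv1_only_fraction=0.4,
        seed=seed,
    )
    records, _ = simulate_proteome(sim)
    h = toy_hierarchy(sim)
    cfg = ModelConfig(n_organelles=h.n_organelles, encode_length=60,
                      hidden_total=8, heads=2, attn_inner=6, seed=seed,
                      dropout_lstm=0.0, dropout_dense=0.0, batch_size=8)
    return prepare_samples(records, h, encode_length=60), cfg


class TestTrainSubmodel:
    def test_alternation_order_lv1_then_lv2(self):
        samples, cfg = _mixed_tiny_samples()
        model = train_submodel(samples, cfg, cycles=2)
        assert [phase for phase, _, _ in model.history] == [
            "lv1", "lv2", "lv1", "lv2"
        ]

    def test_zero_cycles_returns_untrained_model(self):
        samples, cfg = _mixed_tiny_samples()
        model = train_submodel(samples, cfg, cycles=0)
        fresh = Model(cfg)
        np.testing.assert_array_equal(
            model.params["Ws1"].value, fresh.params["Ws1"].value
        )
        assert model.history == []

    def test_requires_lv2_samples(self):
        samples, cfg = _mixed_tiny_samples()
        lv1_only = [s for s in samples if not s.lv2]
        with pytest.raises(ValueError, match="lv2"):
            train_submodel(lv1_only, cfg, cycles=1)

    def test_loss_decreases_on_average(self):
        samples, cfg = _mixed_tiny_samples(seed=3)
        cfg.lr = 3e-3
        model = train_submodel(samples, cfg, cycles=6)
        lv2_losses = [v for phase, _, v in model.history if phase == "lv2"]
        assert np.mean(lv2_losses[-2:]) < np.mean(lv2_losses[:2])


class TestEnsemble:
    def _x(self, rng, cfg):
        feats = rng.normal(size=(cfg.encode_length, 25))
        mask = np.ones(cfg.encode_length, dtype=np.uint8)
        return EncodedProtein(feats, mask,
                              np.arange(1, cfg.encode_length + 1),
                              cfg.encode_length)

    def test_mean_of_two_submodels(self, rng, default_hierarchy):
        cfg = ModelConfig(n_organelles=10, encode_length=20, hidden_total=8,
                          heads=2, attn_inner=6)
        models = [Model(ModelConfig(**{**cfg.__dict__, "seed": s}))
                  for s in (0, 1)]
        ens = EnsembleModel(models=models, hierarchy=default_hierarchy)
        x = self._x(rng, cfg)
        combined = ensemble_predict(ens, x)
        parts = [m.predict(x.features[None], x.mask[None])[0][0] for m in models]
        np.testing.assert_allclose(
            combined.sub_scores,
            (parts[0].sub_scores + parts[1].sub_scores) / 2,
        )
        np.testing.assert_allclose(
            combined.org_scores, combined.sub_scores.max(axis=0)
        )

    def test_single_model_ensemble_is_identity(self, rng, default_hierarchy):
        cfg = ModelConfig(n_organelles=10, encode_length=20, hidden_total=8,
                          heads=2, attn_inner=6)
        model = Model(cfg)
        ens = EnsembleModel(models=[model], hierarchy=default_hierarchy)
        x = self._x(rng, cfg)
        np.testing.assert_allclose(
            ensemble_predict(ens, x).sub_scores,
            model.predict(x.features[None], x.mask[None])[0][0].sub_scores,
        )

    def test_mean_vs_loop_oracle(self, rng, default_hierarchy):
        mats = rng.random((8, 8, 10))
        mean = np.zeros((8, 10))
        for m in mats:
            mean += m
        mean /= 8
        np.testing.assert_allclose(np.mean(mats, axis=0), mean)

    def test_empty_ensemble_rejected(self, rng, default_hierarchy):
        ens = EnsembleModel(models=[], hierarchy=default_hierarchy)
        with pytest.raises(ValueError, match="no sub-models"):
            ensemble_predict(ens, (np.zeros((5, 25)), np.ones(5)))


class TestThresholds:
    def _scores(self, h, cell, pos, neg):
        n = len(pos) + len(neg)
        scores = np.zeros((n, 8, h.n_organelles))
        targets = np.zeros((n, 8, h.n_organelles))
        r, c = cell
        for i, v in enumerate(pos):
            scores[i, r, c] = v
            targets[i, r, c] = 1
        for j, v in enumerate(neg):
            scores[len(pos) + j, r, c] = v
        return scores, targets

    def test_grid_candidate_with_perfect_mcc_wins(self, default_hierarchy):
        cell = default_hierarchy.name_to_cell["cytosol"]
        scores, targets = self._scores(default_hierarchy, cell, [0.45], [0.30])
        ts = tune_thresholds(scores, targets, default_hierarchy,
                             grid=[0.3, 0.4, 0.5])
        assert ts.get(cell) == pytest.approx(0.4)

    def test_tie_breaks_toward_smaller_threshold(self, default_hierarchy):
        cell = default_hierarchy.name_to_cell["cytosol"]
        scores, targets = self._scores(
            default_hierarchy, cell, [0.45, 0.48], [0.25, 0.28]
        )
        ts = tune_thresholds(scores, targets, default_hierarchy,
                             grid=[0.3, 0.4])
        assert ts.get(cell) == pytest.approx(0.3)

    def test_all_negative_cell_keeps_default(self, default_hierarchy):
        cell = default_hierarchy.name_to_cell["cytosol"]
        scores, targets = self._scores(default_hierarchy, cell, [], [0.4, 0.2])
        ts = tune_thresholds(scores, targets, default_hierarchy)
        assert ts.get(cell) == 0.5

    def test_never_above_half(self, default_hierarchy, rng):
        n = 50
        scores = rng.random((n, 8, 10))
        targets = (rng.random((n, 8, 10)) < 0.3).astype(float)
        ts = tune_thresholds(scores, targets, default_hierarchy)
        assert all(v <= 0.5 for v in ts.thresholds.values())

    def test_empty_grid_rejected(self, default_hierarchy):
        with pytest.raises(ValueError, match="empty"):
            tune_thresholds(np.zeros((2, 8, 10)), np.zeros((2, 8, 10)),
                            default_hierarchy, grid=[])

    def test_out_of_range_grid_rejected(self, default_hierarchy):
        with pytest.raises(ValueError, match="0.5"):
            tune_thresholds(np.zeros((2, 8, 10)), np.zeros((2, 8, 10)),
                            default_hierarchy, grid=[0.6])


class TestBayesSearch:
    def test_quadratic_toy_finds_optimum(self):
        best, trials = bayes_search(
            lambda c: -(c["x"] - 0.3) ** 2, {"x": (0.0, 1.0)},
            n_trials=15, seed=0,
        )
        assert best["x"] == pytest.approx(0.3, abs=0.1)
        assert len(trials) == 15

    def test_single_trial_returns_sampled_point(self):
        best, trials = bayes_search(
            lambda c: c["x"], {"x": (0.0, 1.0)}, n_trials=1, seed=5
        )
        assert len(trials) == 1 and best == trials[0]["config"]

    def test_same_seed_same_trajectory(self):
        space = {"x": (0.0, 1.0), "kind": ["a", "b"]}

        def obj(c):
            return c["x"] * (1.0 if c["kind"] == "a" else 0.5)

        _, ta = bayes_search(obj, space, n_trials=8, seed=9)
        _, tb = bayes_search(obj, space, n_trials=8, seed=9)
        assert [t["config"] for t in ta] == [t["config"] for t in tb]

    def test_objective_failure_marks_trial_and_continues(self):
        calls = {"n": 0}

        def obj(c):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return c["x"]

        best, trials = bayes_search(obj, {"x": (0.0, 1.0)}, n_trials=6, seed=1)
        assert sum(t["value"] is None for t in trials) == 1
        assert len(trials) == 6
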