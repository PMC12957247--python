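"""MAE, repeated grouped cross-validation, window sweep, and TPE search."""

import numpy as np
import pytest

from eegsev.evaluation import (CVPlan, CVResult, SEARCH_SPACES, cv_folds,
                               features_from_recordings, mae, run_cv,
                               tpe_minimize, window_sweep, _sample_prior)


class _MeanPredictor:
    """Predicts the training-label mean; the weakest honest baseline."""

    def fit(self, X, y, groups=None):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class TestMAE:
    def test_identical_vectors_give_zero(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_worked_example(self):
        assert mae([1, 2, 3], [2, 2, 2]) == pytest.approx(2 / 3)

    def test_matches_explicit_loop(self, rng):
        y = rng.normal(size=50)
        p = rng.normal(size=50)
        expected = sum(abs(a - b) for a, b in zip(p, y)) / 50
        assert mae(y, p) == pytest.approx(expected, abs=1e-12)

    def test_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([1, 2], [1])
        with pytest.raises(ValueError):
            mae([], [])


class TestFolds:
    def test_subject_mode_never_splits_a_subject(self):
        groups = np.repeat([f"s{i}" for i in range(10)], 4)
        plan = CVPlan(seed=3)
        for folds in cv_folds(40, groups, plan):
            for tr_idx, te_idx in folds:
                assert set(groups[tr_idx]).isdisjoint(set(groups[te_idx]))

    def test_each_sample_tested_once_per_repeat(self):
        groups = np.repeat(np.arange(10), 4)
        plan = CVPlan(n_repeats=3, seed=0)
        repeats = cv_folds(40, groups, plan)
        assert len(repeats) == 3
        for folds in repeats:
            assert len(folds) == 5
            tested = np.concatenate([te for _, te in folds])
            assert sorted(tested) == list(range(40))

    def test_ten_subjects_two_per_test_fold(self):
        groups = np.repeat(np.arange(10), 3)
        folds = cv_folds(30, groups, CVPlan(seed=1))[0]
        for _, te_idx in folds:
            assert len(set(groups[te_idx])) == 2

    def test_too_few_subjects_rejected(self):
        groups = np.repeat(np.arange(3), 5)
        with pytest.raises(ValueError):
            cv_folds(15, groups, CVPlan())

    def test_epoch_mode_partitions_samples(self):
        plan = CVPlan(grouping="epoch", seed=2)
        folds = cv_folds(23, None, plan)[0]
        tested = np.concatenate([te for _, te in folds])
        assert sorted(tested) == list(range(23))


class TestRunCV:
    def test_fifteen_fold_evaluations(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.uniform(0, 56, 40)
        groups = np.repeat(np.arange(10), 4)
        res = run_cv(X, y, _MeanPredictor, CVPlan(seed=0), groups=groups)
        assert len(res.fold_maes) == 15

    def test_constant_labels_mean_predictor_zero_error(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.full(30, 12.0)
        res = run_cv(X, y, _MeanPredictor, CVPlan(grouping="epoch", seed=0))
        assert res.mean == 0.0

    def test_mean_and_sd_summaries(self):
        res = CVResult.from_folds([1.0, 2.0, 3.0])
        assert res.mean == pytest.approx(2.0)
        assert res.sd == pytest.approx(np.std([1.0, 2.0, 3.0]))

    def test_mean_invariant_to_fold_order(self, rng):
        maes = rng.uniform(0, 5, 15)
        a = CVResult.from_folds(maes)
        b = CVResult.from_folds(maes[::-1])
        assert a.mean == b.mean and a.sd == b.sd

    def test_epoch_mode_leaks_subject_identity(self, tiny_cohort):
        """Epoch-level folds place windows of one subject on both sides of
        the train/test boundary, deflating the error estimate relative to
        honest subject-grouped folds."""
        from eegsev.baselines import BaselineSpec, build
        recordings, _ = tiny_cohort
        X, y, groups = features_from_recordings(
            recordings, window_s=10.0, average_epochs=False)
        factory = lambda: build(BaselineSpec(
            "lightgbm", {"min_data_in_leaf": 5, "learning_rate": 0.1}))
        m_epoch = run_cv(X, y, factory,
                         CVPlan(n_repeats=1, grouping="epoch", seed=4))
        m_subject = run_cv(X, y, factory,
                           CVPlan(n_repeats=1, grouping="subject", seed=4),
                           groups=groups)
        assert m_epoch.mean <= m_subject.mean


class TestWindowSweep:
    def test_bookkeeping_tags_and_counts(self, tiny_cohort):
        recordings, _ = tiny_cohort
        res = window_sweep(recordings, [2.0, 10.0], _MeanPredictor,
                           CVPlan(n_repeats=1, seed=0))
        assert set(res) == {2.0, 10.0}
        assert res[2.0].window_s == 2.0 and res[10.0].window_s == 10.0

    def test_empty_window_list(self, tiny_cohort):
        recordings, _ = tiny_cohort
        assert window_sweep(recordings, [], _MeanPredictor, CVPlan()) == {}

    def test_longer_windows_give_cleaner_pli_features(self):
        # 10-s epochs estimate PLI from 5x more samples than 2-s epochs, so
        # with each epoch as a regression sample the coupling-severity
        # relation is recovered more accurately at the longer window
        from eegsev.baselines import BaselineSpec, build
        from eegsev.synthetic import CohortSpec, generate_cohort
        recordings = generate_cohort(
            CohortSpec(n_subjects=16, duration_s=120.0, seed=11))
        factory = lambda: build(BaselineSpec(
            "lightgbm", {"min_data_in_leaf": 5, "learning_rate": 0.1}))
        res = window_sweep(recordings, [2.0, 10.0], factory,
                           CVPlan(n_repeats=2, seed=1),
                           average_epochs=False)
        assert res[10.0].mean <= res[2.0].mean


class TestTPE:
    def test_single_eval_budget(self):
        space = {"x": ("uniform", 0.0, 1.0)}
        best, trials = tpe_minimize(lambda p: p["x"], space, max_evals=1,
                                    seed=0)
        assert len(trials) == 1
        assert best == trials[0].params

    def test_all_samples_respect_bounds(self):
        space = SEARCH_SPACES["conv_gmlp"]
        seen = []

        def obj(p):
            seen.append(dict(p))
            return (np.log(p["learning_rate"]) + 7) ** 2 + p["num_layers"]

        tpe_minimize(obj, space, max_evals=30, seed=5)
        assert len(seen) == 30
        for p in seen:
            assert p["d_channel"] in (32, 64, 128, 256)
            assert p["num_layers"] in (1, 2, 4, 6, 8)
            assert p["d_ffn"] in (128, 256, 384, 512, 640, 768)
            assert p["batch_size"] in (64, 96, 128, 160)
            assert 5e-5 <= p["learning_rate"] <= 1e-3

    def test_gbdt_spaces_match_published_bounds(self):
        lgb = SEARCH_SPACES["lightgbm"]
        assert lgb["num_leaves"] == ("uniformint", 16, 96)
        assert lgb["min_data_in_leaf"] == ("uniformint", 2, 60)
        assert lgb["feature_fraction"] == ("uniform", 0.75, 1.0)
        assert lgb["learning_rate"] == ("loguniform", 5e-3, 0.1)
        xgb = SEARCH_SPACES["xgboost"]
        assert xgb["depth"] == ("uniformint", 3, 10)
        assert xgb["min_child_weight"] == ("uniformint", 1, 5)

    def test_invalid_space_rejected(self):
        with pytest.raises(ValueError):
            tpe_minimize(lambda p: 0.0, {"x": ("uniform", 2.0, 1.0)})
        with pytest.raises(ValueError):
            tpe_minimize(lambda p: 0.0, {"x": ("loguniform", 0.0, 1.0)})

    def test_beats_random_search_on_quadratic(self):
        """Head-to-head at equal 30-trial budget over 20 seeded problems."""
        space = {"x": ("uniform", -5.0, 5.0), "y": ("uniform", -5.0, 5.0)}
        wins = 0
        for seed in range(20):
            r = np.random.default_rng([seed, 77])
            a, b = r.uniform(-3, 3), r.uniform(-3, 3)

            def obj(p):
                return (p["x"] - a) ** 2 + (p["y"] - b) ** 2

            _, trials = tpe_minimize(obj, space, max_evals=30, seed=seed)
            best_tpe = min(t.loss for t in trials)
            rng2 = np.random.default_rng(seed + 1000)
            best_rand = min(
                obj({n: _sample_prior(s, rng2) for n, s in space.items()})
                for _ in range(30))
            wins += best_tpe <= best_rand
        assert wins >= 12  # >= 60% of 20
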