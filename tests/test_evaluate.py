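"""Frameworks, metrics and classifiers."""

import numpy as np
import pandas as pd
import pytest

import oracles
from emgconfounds import (
    ClassifierSpec,
    FeatureMatrix,
    PredictionRecord,
    SplitPlan,
    UndefinedActiveErrorRate,
    aer,
    dbi,
    fit_predict,
    make_splits,
    run_experiment,
    ter,
    tune_hyperparameters,
)


def _record(p, l, nm=1):
    return PredictionRecord(p=np.asarray(p), l=np.asarray(l), no_motion_class=nm)


def _fm(x, labels, subjects=None, conditions=None, trials=None):
    n = len(labels)
    return FeatureMatrix(
        values=np.asarray(x, dtype=float),
        feature_names=[f"f{i}" for i in range(np.asarray(x).shape[1])],
        subject_id=np.asarray(subjects if subjects is not None else np.zeros(n, int)),
        motion_label=np.asarray(labels),
        condition_value=np.asarray(conditions if conditions is not None else np.zeros(n, int), dtype=object),
        trial_index=np.asarray(trials if trials is not None else np.arange(n) % 2),
    )


class TestMakeSplits:
    def test_intra_counts(self):
        plans = make_splits("intra", [0, 1, 2], [0, 1, 2, 3], 0)
        assert len(plans) == 12
        assert all(p.train_conditions == p.test_conditions for p in plans)

    def test_inter_ordered_pairs(self):
        plans = make_splits("inter", list(range(5)), [0, 1], 0)
        assert len(plans) == 5 * 4 * 2
        assert all(set(p.train_conditions).isdisjoint(p.test_conditions) for p in plans)

    def test_single_vs_all(self):
        plans = make_splits("single_vs_all", [0, 1, 2], [0, 1], 0)
        assert len(plans) == 6
        assert all(len(p.train_conditions) == 1 and len(p.test_conditions) == 3 for p in plans)

    def test_multi_vs_all_combinations(self):
        plans = make_splits("multi_vs_all", list(range(5)), [0, 1], 0, n_train=2)
        assert len(plans) == 10 * 2

    def test_multi_vs_all_subsampled_cap(self):
        plans = make_splits(
            "multi_vs_all", list(range(10)), [0, 1], 0, n_train=5, max_train_sets=7, seed=3
        )
        assert len({p.train_conditions for p in plans}) == 7

    def test_requires_n_train(self):
        with pytest.raises(ValueError):
            make_splits("multi_vs_all", [0, 1], [0, 1], 0)

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            make_splits("intra", [0], [0], 0)

    def test_splitplan_invariants_enforced(self):
        with pytest.raises(ValueError):
            SplitPlan("intra", (0,), (1,), 0, 0)
        with pytest.raises(ValueError):
            SplitPlan("inter", (0,), (0, 1), 0, 0)


class TestTer:
    def test_perfect(self):
        assert ter(_record([1, 2, 3], [1, 2, 3])) == 0.0

    def test_one_of_four(self):
        assert ter(_record([1, 2, 3, 3], [1, 2, 3, 1])) == pytest.approx(25.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ter(_record([], []))

    def test_matches_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(1, 100)
            k = rng.integers(2, 10)
            p = rng.integers(0, k, n)
            l = rng.integers(0, k, n)
            assert ter(_record(p, l)) == oracles.ter(list(p), list(l))


class TestAer:
    def test_hand_example(self):
        # numerator 2, denominator 3
        assert aer(_record([2, 2, 1, 3], [2, 3, 3, 1], nm=1)) == pytest.approx(200 / 3)

    def test_all_no_motion_is_undefined(self):
        with pytest.raises(UndefinedActiveErrorRate):
            aer(_record([1, 1, 1], [1, 2, 3], nm=1))

    def test_perfect_predictions(self):
        assert aer(_record([2, 3, 1], [2, 3, 1], nm=1)) == 0.0

    def test_matches_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(1, 100)
            k = rng.integers(2, 10)
            p = rng.integers(0, k, n)
            l = rng.integers(0, k, n)
            want = oracles.aer(list(p), list(l), 0)
            if want is None:
                with pytest.raises(UndefinedActiveErrorRate):
                    aer(_record(p, l, nm=0))
            else:
                assert aer(_record(p, l, nm=0)) == pytest.approx(want, abs=1e-12)

    def test_printed_denominator_variant(self):
        rec = _record([2, 2, 1, 3], [2, 3, 3, 1], nm=2)
        # intended: predictions != 2 -> denominator 2; printed: != 1 -> 3
        assert aer(rec) == pytest.approx(100.0)
        assert aer(rec, printed_denominator=True) == pytest.approx(200 / 3)


class TestDbi:
    def test_singleton_clusters_zero(self):
        x = np.array([[0.0], [10.0]])
        assert dbi(x, [0, 1]) == 0.0

    def test_hand_computed_anchor(self):
        x = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert dbi(x, [0, 0, 1, 1]) == pytest.approx(0.02)

    def test_monotone_in_dispersion(self, rng):
        means = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        labels = np.repeat([0, 1, 2], 50)
        noise = rng.normal(size=(150, 2))
        wide = means[labels] + 1.0 * noise
        narrow = means[labels] + 0.3 * noise
        assert dbi(narrow, labels) < dbi(wide, labels)

    def test_decreases_when_separation_doubles(self, rng):
        labels = np.repeat([0, 1], 40)
        noise = rng.normal(size=(80, 3))
        base = np.array([[0, 0, 0], [2, 0, 0]])
        near = base[labels] + 0.5 * noise
        far = (2 * base)[labels] + 0.5 * noise
        assert dbi(far, labels) < dbi(near, labels)

    def test_coincident_means_infinite_with_warning(self):
        x = np.array([[0.0], [0.0], [0.0], [0.0]])
        with pytest.warns(RuntimeWarning):
            assert dbi(x, [0, 0, 1, 1]) == np.inf

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            k = rng.integers(2, 10)
            d = rng.integers(1, 8)
            n = rng.integers(k, 100)
            labels = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
            x = rng.normal(size=(n, d))
            got = dbi(x, labels)
            want = oracles.dbi(x.tolist(), labels.tolist())
            assert got == pytest.approx(want, rel=1e-9)


class TestFitPredict:
    def test_separated_gaussians_lda_perfect(self, rng, lda_spec):
        mu = np.array([[0.0, 0.0], [10.0, 10.0]])
        xtr = np.vstack([rng.normal(mu[i], 1.0, size=(500, 2)) for i in range(2)])
        ytr = np.repeat(["a", "b"], 500)
        xte = np.vstack([rng.normal(mu[i], 1.0, size=(500, 2)) for i in range(2)])
        rec = fit_predict(lda_spec, _fm(xtr, ytr), _fm(xte, ytr))
        assert ter(rec) == 0.0

    def test_knn_self_test_perfect(self, rng):
        x = rng.normal(size=(60, 3))
        y = np.repeat(["a", "b", "c"], 20)
        spec = ClassifierSpec("knn", k=1)
        rec = fit_predict(spec, _fm(x, y), _fm(x, y))
        assert ter(rec) == 0.0

    def test_uninformative_features_near_chance(self, rng):
        x = np.ones((400, 2)) + rng.normal(scale=1e-9, size=(400, 2))
        y = np.tile(["a", "b"], 200)
        rec = fit_predict(ClassifierSpec("lda"), _fm(x, y), _fm(x, y))
        acc = 100.0 - ter(rec)
        # binomial 99% CI around 50% for n = 400
        assert 43.0 < acc < 57.0

    def test_single_class_training_rejected(self, rng, lda_spec):
        x = rng.normal(size=(10, 2))
        y = np.repeat(["a"], 10)
        with pytest.raises(ValueError):
            fit_predict(lda_spec, _fm(x, y), _fm(x, y))

    def test_dimension_mismatch_rejected(self, rng, lda_spec):
        x = rng.normal(size=(10, 2))
        y = np.tile(["a", "b"], 5)
        with pytest.raises(ValueError):
            fit_predict(lda_spec, _fm(x, y), _fm(rng.normal(size=(10, 3)), y))

    def test_rf_deterministic_given_seed(self, rng):
        x = rng.normal(size=(80, 4))
        y = np.tile(["a", "b"], 40)
        spec = ClassifierSpec("rf", n_trees=20, seed=5)
        r1 = fit_predict(spec, _fm(x, y), _fm(x, y))
        r2 = fit_predict(spec, _fm(x, y), _fm(x, y))
        np.testing.assert_array_equal(r1.p, r2.p)


class TestRunExperiment:
    def test_split_row_count_and_consistency(self, tiny_td, lda_spec):
        res = run_experiment(tiny_td, "intra", lda_spec)
        # 2 subjects x 3 conditions x 3 trials
        assert len(res.rows) == 18
        np.testing.assert_allclose(res.rows["accuracy"] + res.rows["ter"], 100.0)
        s = res.summary()
        acc = res.rows["accuracy"]
        assert s["mean"] == pytest.approx(acc.mean(), abs=1e-12)
        assert s["sd"] == pytest.approx(acc.std(ddof=1), abs=1e-12)
        assert s["min"] == acc.min() and s["max"] == acc.max()

    def test_groupings_exposed(self, tiny_td, lda_spec):
        res = run_experiment(tiny_td, "intra", lda_spec)
        for level in ("subject_id", "train_conditions", "held_out_trial"):
            g = res.by_group(level)
            assert {"mean", "sd"} <= set(g.columns)

    def test_subject_average(self, tiny_td, lda_spec):
        res = run_experiment(tiny_td, "intra", lda_spec)
        sa = res.subject_average()
        assert set(sa.index) == {0, 1}
        assert res.mean_accuracy() == pytest.approx(sa.mean())


class TestTuning:
    def test_single_point_grid_returned(self, tiny_td):
        spec = ClassifierSpec("knn", hyperparameter_grid={"k": [3]})
        tuned = tune_hyperparameters(spec, tiny_td)
        assert tuned.k == 3
        assert tuned.tuning_subjects == (0, 1)

    def test_reuse_of_tuning_subject_blocked(self, tiny_td):
        spec = ClassifierSpec("lda", tuning_subjects=(0,))
        with pytest.raises(ValueError):
            run_experiment(tiny_td, "intra", spec)

    def test_grid_selects_best_candidate(self, tiny_td):
        grid = [1, 5, 15]
        spec = ClassifierSpec("knn", hyperparameter_grid={"k": grid})
        sub0 = tiny_td.subset(tiny_td.subject_id == 0)
        tuned = tune_hyperparameters(spec, sub0)
        # exhaustive check: the returned k maximises intra tuning accuracy
        accs = {
            k: run_experiment(sub0, "intra", ClassifierSpec("knn", k=k)).mean_accuracy()
            for k in grid
        }
        assert accs[tuned.k] == max(accs.values())
        assert tuned.tuning_subjects == (0,)
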