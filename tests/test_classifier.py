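import numpy as np
import pytest

from ecochg.classifier import (
    CostConfig,
    ModelBundle,
    TrainingSet,
    assemble_training_set,
    cost_search,
    crossval_split,
    feature_importance,
    predict,
    run_cross_validation,
    train,
)
from ecochg.features import fit_minmax


def separable_set(rng, n=200, d=8):
    """Balanced, linearly separable toy set: drops live at high feature 0."""
    X = rng.uniform(0, 1, (n, d))
    y = X[:, 0] > 0.5
    return TrainingSet(X, y, np.array([f"P{i % 10}" for i in range(n)], dtype=object))


class TestTrainPredict:
    def test_separable_set_fits_perfectly(self, rng):
        ts = separable_set(rng)
        model = train(ts, cost=1.0, seed=0)
        np.testing.assert_array_equal(predict(model, ts.X), ts.y)

    def test_single_class_rejected(self, rng):
        ts = separable_set(rng)
        with pytest.raises(ValueError):
            train(TrainingSet(ts.X, np.zeros(ts.y.size, bool), ts.patient_ids), 1.0)

    def test_duplicate_rows_get_identical_labels(self, rng):
        ts = separable_set(rng)
        model = train(ts, cost=5.0, seed=0)
        row = ts.X[:1]
        dup = np.vstack([row, row, row])
        assert len(set(predict(model, dup).tolist())) == 1

    def test_dimension_mismatch_rejected(self, rng):
        ts = separable_set(rng)
        model = train(ts, cost=1.0, seed=0)
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 5)))

    def test_fixed_seed_deterministic(self, rng):
        ts = separable_set(rng)
        m1 = train(ts, cost=7.0, seed=3)
        m2 = train(ts, cost=7.0, seed=3)
        probe = rng.uniform(0, 1, (50, 8))
        np.testing.assert_array_equal(predict(m1, probe), predict(m2, probe))

    def test_cost_below_one_rejected(self):
        with pytest.raises(ValueError):
            CostConfig(0.5)

    def test_initial_cost_is_class_ratio(self):
        y = np.zeros(92, bool)
        y[:4] = True
        assert CostConfig.from_class_ratio(y).drop_miss_cost == pytest.approx(22.0)

    def test_raising_cost_does_not_reduce_training_sensitivity(self, rng):
        # overlapping classes so the weighted loss actually matters
        X = rng.normal(size=(400, 4))
        y = (X[:, 0] + rng.normal(scale=1.5, size=400)) > 1.0
        ts = TrainingSet(X, y, np.array(["P"] * 400, dtype=object))
        sens = []
        for cost in (1, 10, 40):
            model = train(ts, cost=cost, seed=0)
            pred = predict(model, X)
            sens.append((pred & y).sum() / y.sum())
        assert sens[-1] >= sens[0]

    def test_knn_honours_the_same_contract(self, rng):
        ts = separable_set(rng)
        model = train(ts, cost=1.0, spec={"kind": "knn", "n_neighbors": 1}, seed=0)
        np.testing.assert_array_equal(predict(model, ts.X), ts.y)


class TestCrossvalSplit:
    def test_each_fold_gets_one_drop_patient(self):
        patients = [f"P{i}" for i in range(10)]
        droppers = patients[:5]
        folds = crossval_split(patients, droppers, k=5, seed=1)
        assert sorted(p for f in folds for p in f) == sorted(patients)
        for f in folds:
            assert sum(p in droppers for p in f) == 1

    def test_too_few_drop_patients_rejected(self):
        with pytest.raises(ValueError):
            crossval_split([f"P{i}" for i in range(10)], ["P0", "P1", "P2", "P3"], k=5)

    def test_same_seed_same_folds(self):
        patients = [f"P{i}" for i in range(23)]
        droppers = patients[:7]
        assert crossval_split(patients, droppers, seed=5) == crossval_split(
            patients, droppers, seed=5
        )

    def test_fold_sizes_balanced(self):
        patients = [f"P{i}" for i in range(23)]
        folds = crossval_split(patients, patients[:7], seed=2)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1


class TestFeatureImportance:
    def test_fractions_sum_to_one(self, rng):
        ts = separable_set(rng)
        models = [train(ts, cost=1.0, seed=s) for s in range(3)]
        w = feature_importance(models)
        assert w.shape == (8,)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_informative_feature_outweighs_noise(self, rng):
        ts = separable_set(rng)  # only feature 0 carries the label
        model = train(ts, cost=1.0, seed=0)
        w = feature_importance([model])
        assert w[0] > w[1:].max()


class TestCohortCrossValidation:
    def test_cv_runs_and_counts_partition_points(self, tiny_series):
        droppers = [s.patient_id for s in tiny_series if s.annotation.has_drop]
        folds = crossval_split([s.patient_id for s in tiny_series], droppers, k=2, seed=0)
        cv = run_cross_validation(tiny_series, folds, cost=10, seed=0)
        total_eligible = sum(int(s.eligible.sum()) for s in tiny_series)
        assert cv.pooled_counts.total == total_eligible
        m = cv.mean_metrics
        assert 0.0 <= m.accuracy <= 1.0

    def test_cv_deterministic(self, tiny_series):
        droppers = [s.patient_id for s in tiny_series if s.annotation.has_drop]
        folds = crossval_split([s.patient_id for s in tiny_series], droppers, k=2, seed=0)
        m1 = run_cross_validation(tiny_series, folds, cost=10, seed=0).mean_metrics
        m2 = run_cross_validation(tiny_series, folds, cost=10, seed=0).mean_metrics
        assert m1 == m2

    def test_single_point_grid_returns_that_cost(self, tiny_series):
        droppers = [s.patient_id for s in tiny_series if s.annotation.has_drop]
        folds = crossval_split([s.patient_id for s in tiny_series], droppers, k=2, seed=0)
        res = cost_search(tiny_series, folds, grid=[17], seed=0)
        assert res.best_cost == 17.0
        assert list(res.curves["cost"]) == [17.0]

    def test_empty_grid_rejected(self, tiny_series):
        with pytest.raises(ValueError):
            cost_search(tiny_series, [["P000"]], grid=[])


class TestModelBundle:
    def test_save_load_round_trip(self, rng, tmp_path):
        ts = separable_set(rng)
        model = train(ts, cost=3.0, seed=0)
        bundle = ModelBundle(model, fit_minmax(ts.X))
        path = tmp_path / "model.pkl"
        bundle.save(path)
        back = ModelBundle.load(path)
        probe = rng.uniform(0, 1, (20, 8))
        np.testing.assert_array_equal(predict(back.model, probe), predict(model, probe))

    def test_assemble_restricts_to_eligible_points(self, tiny_series):
        ts = assemble_training_set(tiny_series)
        assert ts.X.shape[0] == sum(int(s.eligible.sum()) for s in tiny_series)
        assert np.isfinite(ts.X).all()
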