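"""Tests of grouped splitting, the R^2/RMSE formulas, the four regressors,
permutation importance and voxel prediction."""

import numpy as np
import pandas as pd
import pytest

from voxfpar.errors import ConfigurationError, InsufficientDataError
from voxfpar.indices import INDEX_NAMES
from voxfpar.models import (ALGORITHMS, FitResult, ModelSpec, evaluate,
                            grouped_cv_folds, permutation_importance,
                            predict_voxels, split_data, train_model,
                            validate_model)


def synthetic_training_table(n_trees=60, seed=0, target="linear",
                             noise=0.0):
    """Tree-level table with 14 correlated VI columns and a known target.

    The predictors are generated from a 2-D latent (as real band-derived
    indices would be); the target is a stated function of the NDVI column.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tree in range(1, n_trees + 1):
        for stratum in range(3):
            a = rng.uniform(0, 1)
            b = rng.uniform(0, 1)
            feats = {}
            for pos, name in enumerate(INDEX_NAMES):
                w = np.sin(pos + 1.0)
                feats[name] = w * a + (1 - w) * b + 0.01 * rng.normal()
            feats["tree_id"] = tree
            rows.append(feats)
    table = pd.DataFrame(rows)
    if target == "linear":
        y = 0.2 + 0.6 * table["NDVI"]
    else:
        y = rng.uniform(0, 1, len(table))
    table["fpar_label"] = y + noise * rng.normal(size=len(table))
    return table


class TestEvaluate:
    def test_perfect_fit(self):
        r2, rmse = evaluate([0.2, 0.8], [0.2, 0.8])
        assert r2 == pytest.approx(1.0) and rmse == 0.0

    def test_worked_example(self):
        r2, rmse = evaluate([0.0, 2.0], [1.0, 1.0])
        assert rmse == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_zero_r2(self, rng):
        y = rng.uniform(0, 1, 50)
        r2, _ = evaluate(y, np.full(50, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_r2_undefined(self):
        r2, rmse = evaluate([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])
        assert np.isnan(r2)
        assert rmse == pytest.approx(np.sqrt(0.02 / 3), abs=1e-15)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            y = rng.normal(size=30)
            yhat = rng.normal(size=30)
            r2, rmse = evaluate(y, yhat)
            sse = sum((a - b) ** 2 for a, b in zip(y, yhat))
            sst = sum((a - np.mean(y)) ** 2 for a in y)
            assert r2 == pytest.approx(1 - sse / sst, abs=1e-12)
            assert rmse == pytest.approx(np.sqrt(sse / 30), abs=1e-12)


class TestSplitData:
    def test_proportions(self):
        table = synthetic_training_table(n_trees=100, seed=1)
        cal, val = split_data(table, 0.8, seed=2)
        assert cal["tree_id"].nunique() == 80
        assert val["tree_id"].nunique() == 20

    def test_deterministic(self):
        table = synthetic_training_table(n_trees=30, seed=1)
        a1, b1 = split_data(table, seed=5)
        a2, b2 = split_data(table, seed=5)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_no_tree_overlap(self):
        table = synthetic_training_table(n_trees=37, seed=3)
        for seed in range(5):
            cal, val = split_data(table, seed=seed)
            assert not set(cal["tree_id"]) & set(val["tree_id"])

    def test_too_few_units(self):
        table = synthetic_training_table(n_trees=4, seed=1)
        with pytest.raises(InsufficientDataError):
            split_data(table)


class TestGroupedCv:
    def test_folds_partition_groups(self):
        groups = np.repeat(np.arange(20), 3)
        folds = list(grouped_cv_folds(groups, n_splits=10, n_repeats=5,
                                      seed=1))
        assert len(folds) == 50
        for train, test in folds:
            assert not set(groups[train]) & set(groups[test])
        # every group held out exactly once per repeat
        for rep in range(5):
            held = np.concatenate(
                [groups[test] for _, test in folds[rep * 10:(rep + 1) * 10]])
            assert sorted(set(held)) == list(range(20))

    def test_too_few_groups(self):
        with pytest.raises(InsufficientDataError):
            list(grouped_cv_folds(np.arange(5), n_splits=10))


class TestTrainModel:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_learnable_identity(self, algorithm):
        """A noiseless target linear in one VI is learned by every model."""
        table = synthetic_training_table(n_trees=100, seed=4)
        cal, val = split_data(table, seed=4)
        fit = train_model(cal, ModelSpec(algorithm=algorithm, seed=4),
                          n_splits=5, n_repeats=1)
        r2, _ = validate_model(fit, val)
        assert r2 >= 0.99

    def test_permuted_labels_negative_control(self):
        for seed in range(10):
            table = synthetic_training_table(n_trees=40, seed=seed)
            rng = np.random.default_rng(seed)
            table["fpar_label"] = rng.permutation(
                table["fpar_label"].to_numpy())
            cal, val = split_data(table, seed=seed)
            fit = train_model(cal, ModelSpec(algorithm="RF", seed=seed),
                              n_splits=5, n_repeats=1)
            r2, _ = validate_model(fit, val)
            assert r2 <= 0.2

    def test_grid_of_size_one_matches_no_search(self):
        table = synthetic_training_table(n_trees=30, seed=6, noise=0.02)
        cal, _ = split_data(table, seed=6)
        spec = ModelSpec(algorithm="RF", grid={"max_features": [6]}, seed=6)
        a = train_model(cal, spec, n_splits=5, n_repeats=1, grid_search=True)
        b = train_model(cal, ModelSpec(algorithm="RF", seed=6), n_splits=5,
                        n_repeats=1, grid_search=False)
        assert a.cv_rmse_mean == pytest.approx(b.cv_rmse_mean, abs=1e-12)
        assert np.allclose(
            a.model.predict(cal[INDEX_NAMES].to_numpy()),
            b.model.predict(cal[INDEX_NAMES].to_numpy()))

    def test_missing_rows_dropped_with_warning(self):
        table = synthetic_training_table(n_trees=30, seed=7)
        table.loc[:4, "NDVI"] = np.nan
        with pytest.warns(UserWarning, match="dropping 5"):
            fit = train_model(table, ModelSpec(seed=7), n_splits=5,
                              n_repeats=1)
        assert fit.dropped_rows == 5

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(algorithm="MLP")

    def test_cv_folds_respect_tree_grouping(self):
        table = synthetic_training_table(n_trees=25, seed=8)
        fit = train_model(table, ModelSpec(seed=8), n_splits=5, n_repeats=2)
        assert len(fit.cv_results) == 10
        assert np.isfinite(fit.cv_results["rmse"]).all()


class TestPermutationImportance:
    def test_null_predictor_near_zero_planted_signal_first(self):
        """Importance ~0 for a null column; a planted driver ranks first."""
        rng = np.random.default_rng(9)
        n = 300
        table = pd.DataFrame(
            {name: rng.uniform(0, 1, n) for name in INDEX_NAMES})
        table["tree_id"] = np.arange(n) // 3
        table["fpar_label"] = (0.5 * table["RECI"]
                               + 0.02 * rng.normal(size=n))
        cal, val = split_data(table, seed=9)
        fit = train_model(cal, ModelSpec(algorithm="RF", seed=9), n_splits=5,
                          n_repeats=1)
        imp = permutation_importance(fit, val, n_repeats=10, seed=9)
        assert imp["predictor"].iloc[0] == "RECI"
        null_scores = imp[imp["predictor"] != "RECI"]["importance"]
        top = imp["importance"].iloc[0]
        assert (null_scores.abs() < 0.2 * top).all()

    def test_duplicated_column_splits_importance(self):
        rng = np.random.default_rng(10)
        n = 300
        base = {name: rng.uniform(0, 1, n) for name in INDEX_NAMES}
        table = pd.DataFrame(base)
        table["tree_id"] = np.arange(n) // 3
        table["fpar_label"] = 0.5 * table["RECI"] + 0.02 * rng.normal(size=n)
        # duplicate the informative column into an otherwise-null one
        table["NDRE"] = table["RECI"]
        cal, val = split_data(table, seed=10)
        fit = train_model(cal, ModelSpec(algorithm="RF", seed=10), n_splits=5,
                          n_repeats=1)
        imp = permutation_importance(fit, val, n_repeats=10,
                                     seed=10).set_index("predictor")
        pair = imp.loc[["RECI", "NDRE"], "importance"]
        rest = imp.drop(["RECI", "NDRE"])["importance"]
        # both twins matter and each is diluted relative to a lone signal
        assert (pair > rest.max()).all()


class TestPredictVoxels:
    def _fit(self):
        table = synthetic_training_table(n_trees=30, seed=11)
        return train_model(table, ModelSpec(seed=11), n_splits=5,
                           n_repeats=1), table

    def test_clipping_flagged(self):
        fit, table = self._fit()

        class Saturating:
            def predict(self, X):
                return np.full(len(X), 1.3)

        sat = FitResult(**{**fit.__dict__, "model": Saturating()})
        out = predict_voxels(sat, table.head(5))
        assert (out["fpar_pred"] == 1.0).all()
        assert out["pred_clipped"].all()

    def test_missing_predictors_missing_prediction(self):
        fit, table = self._fit()
        table = table.head(10).copy()
        table.loc[3, "NDVI"] = np.nan
        out = predict_voxels(fit, table)
        assert np.isnan(out.loc[3, "fpar_pred"])
        assert out.loc[3, "pred_missing"]
        assert out["fpar_pred"].drop(3).notna().all()

    def test_constant_inputs_constant_predictions(self):
        fit, table = self._fit()
        rep = pd.concat([table.head(1)] * 4, ignore_index=True)
        out = predict_voxels(fit, rep)
        assert out["fpar_pred"].nunique() == 1
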