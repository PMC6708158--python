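import numpy as np
import pandas as pd
import pytest

import epiclock as ec
from epiclock.clocks import power_lambda_grid
from epiclock.io import TransformSpec

from conftest import beta_matrix


class TestTransforms:
    def test_power_lambda_one_is_identity(self):
        mat = beta_matrix(5, 8, seed=0)
        out = ec.apply_transform(mat, TransformSpec("power", 1.0))
        np.testing.assert_allclose(out.to_numpy(), mat.beta.to_numpy())

    def test_mvalue_at_half_is_zero(self):
        spec = TransformSpec("mvalue")
        assert spec.apply(np.array([0.5]))[0] == pytest.approx(0.0, abs=1e-15)

    def test_power_grid_has_39_values(self):
        grid = power_lambda_grid()
        assert len(grid) == 39
        assert grid[0] == pytest.approx(0.1)
        assert grid[-1] == pytest.approx(2.0)
        np.testing.assert_allclose(np.diff(grid), 0.05)

    def test_arcsine_and_log_formulas(self):
        b = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(
            TransformSpec("arcsine").apply(b), np.arcsin(np.sqrt(b))
        )
        eps = 1e-3
        np.testing.assert_allclose(
            TransformSpec("log", eps=eps).apply(b),
            np.log(np.clip(b, eps, 1 - eps)),
        )

    def test_mvalue_clipping_keeps_values_finite(self):
        out = TransformSpec("mvalue").apply(np.array([0.0, 1.0]))
        assert np.isfinite(out).all()

    @pytest.mark.parametrize(
        "kwargs", [dict(kind="bogus"), dict(kind="power", lam=5.0),
                   dict(kind="log", eps=0.7)]
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TransformSpec(**kwargs)


class TestTrainingDesign:
    def test_fourteen_cohorts_five_replicates_gives_65(self):
        cohorts = [f"c{i}" for i in range(14)]
        design = ec.make_training_design(cohorts, n_replicates=5, seed=0)
        assert len(design) == 65
        sizes = [e.size for e in design]
        assert sorted(set(sizes)) == list(range(1, 14))

    def test_train_and_test_always_disjoint_and_exhaustive(self):
        cohorts = [f"c{i}" for i in range(14)]
        design = ec.make_training_design(cohorts, n_replicates=5, seed=2)
        for entry in design:
            assert not set(entry.train_cohorts) & set(entry.test_cohorts)
            assert sorted(entry.train_cohorts + entry.test_cohorts) == sorted(cohorts)
            assert len(entry.train_cohorts) == entry.size

    def test_two_cohorts_one_replicate(self):
        design = ec.make_training_design(["A", "B"], n_replicates=1, seed=0)
        assert len(design) == 1
        entry = design.entries[0]
        assert {entry.train_cohorts[0], entry.test_cohorts[0]} == {"A", "B"}

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 cohorts"):
            ec.make_training_design(["A"], n_replicates=1)
        with pytest.raises(ValueError, match="n_replicates"):
            ec.make_training_design(["A", "B"], n_replicates=0)


class TestBLUP:
    def test_equals_closed_form_ridge(self):
        """Dual-system BLUP effects equal the primal ridge solution with
        penalty m*se2/su2 on a 30 x 100 instance."""
        rng = np.random.default_rng(3)
        mat = beta_matrix(30, 100, seed=3)
        y = rng.uniform(20, 80, 30)
        ratio = 2.5
        pred = ec.train_blup(mat, y, variance_ratio=ratio)
        z = ((mat.beta - mat.beta.mean()) / mat.beta.std(ddof=1)).to_numpy()
        lam = 100 / ratio
        ridge = np.linalg.solve(z.T @ z + lam * np.eye(100), z.T @ (y - y.mean()))
        assert np.abs(pred.weights.to_numpy() - ridge).max() < 1e-8

    def test_sample_at_training_mean_predicts_mean_age(self):
        mat = beta_matrix(25, 40, seed=4)
        y = np.random.default_rng(4).uniform(30, 70, 25)
        pred = ec.train_blup(mat, y, variance_ratio=1.0)
        probe_means = mat.beta.mean()
        test = ec.MethylationMatrix(
            pd.DataFrame([probe_means], index=["mean_sample"])
        )
        assert pred.predict(test).iloc[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_zero_variance_ratio_collapses_to_mean_age(self):
        mat = beta_matrix(20, 30, seed=5)
        y = np.random.default_rng(5).uniform(30, 70, 20)
        pred = ec.train_blup(mat, y, variance_ratio=0.0)
        assert (pred.weights == 0).all()
        assert pred.intercept == pytest.approx(y.mean())

    def test_noiseless_linear_world_near_interpolates(self):
        """When age is an exact linear function of 10 probes and n >> 10,
        the REML-tuned BLUP clock fits it almost perfectly in-sample."""
        rng = np.random.default_rng(6)
        n, m = 300, 50
        b = rng.beta(2, 2, size=(n, m))
        mat = ec.MethylationMatrix(
            pd.DataFrame(b, index=[f"s{i}" for i in range(n)],
                         columns=[f"p{j}" for j in range(m)])
        )
        y = 40 + b[:, :10] @ rng.normal(0, 15, 10)
        pred = ec.train_blup(mat, y)
        rmse = ec.score(pred.predict(mat), y).rmse
        assert rmse < 0.1


class TestElasticNet:
    def test_kkt_conditions_hold_at_solution(self):
        """Coordinate-descent solution satisfies the subgradient optimality
        conditions of the elastic-net objective on a 50 x 200 instance."""
        rng = np.random.default_rng(7)
        mat = beta_matrix(50, 200, seed=7)
        y = (mat.beta.to_numpy()[:, :5] @ np.array([30, -20, 25, 15, -10])
             + rng.normal(0, 1, 50) + 40)
        lam, alpha = 0.5, 0.5
        pred = ec.train_enet(mat, y, alpha=alpha, lambda_penalty=lam,
                             tol=1e-10, max_iter=100000)
        z = ((mat.beta - mat.beta.mean()) / mat.beta.std(ddof=1)).to_numpy()
        b = pred.weights.to_numpy()
        resid = y - pred.intercept - z @ b
        grad = -(z.T @ resid) / 50 + lam * (1 - alpha) * b
        active = b != 0
        assert np.abs(grad[active] + lam * alpha * np.sign(b[active])).max() < 1e-6
        assert np.abs(grad[~active]).max() <= lam * alpha + 1e-6

    def test_pure_ridge_matches_closed_form(self):
        rng = np.random.default_rng(8)
        mat = beta_matrix(40, 60, seed=8)
        y = rng.uniform(20, 80, 40)
        lam = 0.3
        pred = ec.train_enet(mat, y, alpha=0.0, lambda_penalty=lam,
                             tol=1e-12, max_iter=200000)
        z = ((mat.beta - mat.beta.mean()) / mat.beta.std(ddof=1)).to_numpy()
        ridge = np.linalg.solve(
            z.T @ z / 40 + lam * np.eye(60), z.T @ (y - y.mean()) / 40
        )
        assert np.abs(pred.weights.to_numpy() - ridge).max() < 1e-6

    def test_infinite_penalty_gives_zero_clock(self):
        mat = beta_matrix(30, 50, seed=9)
        y = np.random.default_rng(9).uniform(20, 80, 30)
        pred = ec.train_enet(mat, y, alpha=0.5, lambda_penalty=1e10)
        assert (pred.weights == 0).all()
        assert pred.intercept == pytest.approx(y.mean())

    def test_selection_monotone_in_penalty(self):
        mat = beta_matrix(60, 120, seed=10)
        rng = np.random.default_rng(10)
        y = mat.beta.to_numpy()[:, :8] @ rng.normal(0, 20, 8) + rng.normal(0, 2, 60)
        counts = [
            ec.train_enet(mat, y, alpha=0.5, lambda_penalty=lam).n_selected
            for lam in (0.01, 0.1, 0.5, 2.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_arguments_rejected(self):
        mat = beta_matrix(12, 10, seed=11)
        y = np.arange(12.0)
        with pytest.raises(ValueError, match="alpha"):
            ec.train_enet(mat, y, alpha=1.5)
        with pytest.raises(ValueError, match="folds"):
            ec.train_enet(mat, y, cv=20)


class TestPredictorProperties:
    def test_no_test_set_leakage(self, small_world):
        """Perturbing test-cohort samples leaves the trained clock unchanged."""
        _, matrix, pheno, _ = small_world
        ages = pheno.set_index("sample_id")["age"]
        train = matrix.subset_cohorts(["C1"])
        p1 = ec.train_enet(train, ages.loc[train.sample_ids], seed=0, cv=5)
        # shuffle the test cohort rows in the full matrix; retrain
        beta2 = matrix.beta.copy()
        c2_rows = matrix.cohort[matrix.cohort == "C2"].index
        rng = np.random.default_rng(0)
        beta2.loc[c2_rows] = beta2.loc[rng.permutation(c2_rows)].to_numpy()
        matrix2 = ec.MethylationMatrix(beta2, matrix.cohort)
        train2 = matrix2.subset_cohorts(["C1"])
        p2 = ec.train_enet(train2, ages.loc[train2.sample_ids], seed=0, cv=5)
        pd.testing.assert_series_equal(p1.weights, p2.weights)
        assert p1.intercept == p2.intercept

    def test_prediction_is_linear_in_beta(self, small_world):
        _, matrix, pheno, _ = small_world
        ages = pheno.set_index("sample_id")["age"]
        train = matrix.subset_cohorts(["C1"])
        pred = ec.train_blup(train, ages.loc[train.sample_ids], variance_ratio=1.0)
        a = matrix.beta.iloc[[0]].to_numpy()
        b = matrix.beta.iloc[[1]].to_numpy()
        def predict_one(row):
            m = ec.MethylationMatrix(
                pd.DataFrame(row, index=["x"], columns=matrix.probe_ids)
            )
            return pred.predict(m).iloc[0]
        assert predict_one((a + b) / 2) == pytest.approx(
            (predict_one(a) + predict_one(b)) / 2, abs=1e-9
        )


class TestPruning:
    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(12)
        x = rng.beta(2, 2, size=(30, 1))
        mat = pd.DataFrame(np.hstack([x, x]), columns=["a", "b"])
        assert ec.prune_probes(mat, r2_threshold=0.9, window=10) == ["a"]

    def test_threshold_one_keeps_everything(self):
        mat = beta_matrix(20, 15, seed=13)
        kept = ec.prune_probes(mat, r2_threshold=1.0, window=15)
        assert kept == mat.probe_ids

    def test_block_structure_keeps_one_per_block(self):
        """Ten blocks of ten identical-signal probes reduce to ten probes."""
        rng = np.random.default_rng(14)
        n, blocks, per_block = 60, 10, 10
        signals = rng.normal(size=(n, blocks))
        cols = {}
        for b in range(blocks):
            for j in range(per_block):
                cols[f"b{b}_{j}"] = signals[:, b]
        x = pd.DataFrame(cols)
        x = (x - x.min().min()) / (x.max().max() - x.min().min())
        kept = ec.prune_probes(x, r2_threshold=0.2, window=200)
        assert len(kept) == blocks

    def test_invalid_arguments_rejected(self):
        mat = beta_matrix(10, 5, seed=15)
        with pytest.raises(ValueError, match="r2_threshold"):
            ec.prune_probes(mat, r2_threshold=0.0)
        with pytest.raises(ValueError, match="window"):
            ec.prune_probes(mat, window=0)
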