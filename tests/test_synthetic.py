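import numpy as np
import pandas as pd
import pytest

import epiclock as ec
from epiclock.synthetic import ConfigError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(n_samples=(), age_ranges=()), "cohort"),
            (dict(n_causal=50, n_probes=20), "n_causal"),
            (dict(age_ranges=((80.0, 20.0),), n_samples=(10,)), "min < max"),
            (dict(target_rho2=1.5), "target_rho2"),
            (dict(horizon=-1.0), "horizon"),
            (dict(n_samples=(10, 10)), "length"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        with pytest.raises(ConfigError, match=match):
            ec.SimulationConfig(**kwargs)


class TestGeneratorContracts:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_betas_bounded_and_proportions_sum_to_one(self, seed):
        cfg = ec.SimulationConfig(
            n_samples=(30, 40), age_ranges=((20, 60), (40, 90)),
            n_probes=80, n_causal=10, seed=seed,
        )
        matrix, pheno, truth = ec.simulate_world(cfg)
        vals = matrix.beta.to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()
        np.testing.assert_allclose(
            truth.cell_proportions.sum(axis=1).to_numpy(), 1.0, atol=1e-12
        )
        assert (truth.cell_proportions.to_numpy() >= 0).all()
        # ages within the configured cohort ranges
        ph = pheno.set_index("sample_id")
        for name, (lo, hi) in zip(cfg.cohorts, cfg.age_ranges):
            ages = ph.loc[ph["cohort"] == name, "age"]
            assert ages.between(lo, hi).all()
        assert (ph["surv_time"] > 0).all()
        assert ph["event"].isin([0, 1]).all()

    def test_determinism_bit_identical(self, tmp_path):
        cfg = ec.SimulationConfig(
            n_samples=(25,), age_ranges=((20, 80),), n_probes=60, n_causal=5, seed=9
        )
        out = []
        for run in range(2):
            matrix, pheno, _ = ec.simulate_world(cfg)
            mp = tmp_path / f"m{run}.tsv"
            pp = tmp_path / f"p{run}.tsv"
            ec.write_matrix(matrix, mp)
            ec.write_phenotypes(pheno, pp)
            out.append((mp.read_bytes(), pp.read_bytes()))
        assert out[0] == out[1]

    def test_heterogeneity_set_size_and_disjointness(self):
        cfg = ec.SimulationConfig(
            n_samples=(40,), age_ranges=((20, 80),), n_probes=200, n_causal=50,
            heterogeneity_fraction=0.25, seed=3,
        )
        _, _, truth = ec.simulate_world(cfg)
        assert len(truth.heterogeneity_probes) == round(0.25 * 200)
        assert not set(truth.heterogeneity_probes) & set(truth.causal_probes)

    def test_ground_truth_sidecar_round_trip(self, tmp_path, small_world):
        _, _, _, truth = small_world
        ec.synthetic.write_ground_truth(truth, tmp_path / "truth")
        back = ec.synthetic.read_ground_truth(tmp_path / "truth")
        assert back.causal_probes == truth.causal_probes
        assert back.heterogeneity_probes == truth.heterogeneity_probes
        assert back.realized_rho2 == pytest.approx(truth.realized_rho2, abs=1e-12)
        pd.testing.assert_frame_equal(back.cell_proportions, truth.cell_proportions)


class TestVarianceTargeting:
    def test_realized_fraction_matches_oracle(self):
        """The stored variance fraction equals an independent regression of
        age on the causal linear score, and hits the configured target."""
        fractions = []
        for seed in range(20):
            cfg = ec.SimulationConfig(
                n_samples=(400,), age_ranges=((20, 90),), n_probes=1000,
                n_causal=200, target_rho2=0.5, confounding_strength=0.0,
                batch_sd=0.0, seed=300 + seed,
            )
            matrix, pheno, truth = ec.simulate_world(cfg)
            oracle = ec.realized_variance_fraction(matrix, pheno, truth)
            assert oracle == pytest.approx(truth.realized_rho2, abs=1e-9)
            fractions.append(oracle)
        assert abs(np.mean(fractions) - 0.5) < 0.05

    def test_zero_signal_world(self):
        cfg = ec.SimulationConfig(
            n_samples=(100,), age_ranges=((20, 80),), n_probes=100,
            n_causal=0, target_rho2=0.0, confounding_strength=0.0, seed=4,
        )
        _, _, truth = ec.simulate_world(cfg)
        assert truth.realized_rho2 == 0.0
        assert len(truth.causal_probes) == 0


class TestConfounding:
    def test_stronger_coupling_raises_age_cell_correlation(self):
        """Average within-cohort |corr(age, proportion)| grows with the
        confounding strength."""
        def mean_abs_corr(strength, seeds=(0, 1, 2)):
            vals = []
            for s in seeds:
                cfg = ec.SimulationConfig(
                    n_samples=(150, 150), age_ranges=((20, 70), (40, 95)),
                    n_probes=30, n_causal=5, confounding_strength=strength,
                    seed=50 + s,
                )
                _, pheno, truth = ec.simulate_world(cfg)
                ph = pheno.set_index("sample_id")
                for cohort in cfg.cohorts:
                    mask = (ph["cohort"] == cohort).to_numpy()
                    age = ph.loc[mask, "age"].to_numpy()
                    props = truth.cell_proportions.iloc[mask]
                    for col in props.columns:
                        vals.append(abs(np.corrcoef(age, props[col])[0, 1]))
            return float(np.mean(vals))

        low, mid, high = (mean_abs_corr(s) for s in (0.0, 0.8, 2.0))
        assert low < mid < high


class TestMortality:
    def test_null_world_covers_unity(self):
        """With no age or cell effect on the hazard, Cox CIs cover HR = 1."""
        cfg = ec.SimulationConfig(
            n_samples=(800,), age_ranges=((20, 90),), n_probes=20, n_causal=0,
            target_rho2=0.0, mortality_cell_effect=0.0, age_hazard=0.0, seed=17,
        )
        _, pheno, truth = ec.simulate_world(cfg)
        z_cell = truth.cell_proportions.iloc[:, 0].to_numpy()
        z_cell = (z_cell - z_cell.mean()) / z_cell.std()
        X = np.column_stack([z_cell, pheno["age"].to_numpy()])
        beta, cov, _, _ = ec.survival.cox_newton(
            X, pheno["surv_time"].to_numpy(), pheno["event"].to_numpy()
        )
        se = np.sqrt(np.diag(cov))
        assert (np.abs(beta) < 1.96 * se).all()

    def test_cell_effect_recovered_within_2se(self):
        """Planted log-hazard per SD of the first cell type is recovered by
        an established partial-likelihood fit."""
        lifelines = pytest.importorskip("lifelines")
        b = np.log(2.0)
        cfg = ec.SimulationConfig(
            n_samples=(2000,), age_ranges=((20, 90),), n_probes=20, n_causal=0,
            target_rho2=0.0, mortality_cell_effect=b, mortality_cell_index=0,
            confounding_strength=0.0, age_hazard=0.05, seed=23,
        )
        _, pheno, truth = ec.simulate_world(cfg)
        p0 = truth.cell_proportions.iloc[:, 0].to_numpy()
        df = pd.DataFrame(
            {
                "z_cell": (p0 - p0.mean()) / p0.std(),
                "age": pheno["age"].to_numpy(),
                "T": pheno["surv_time"].to_numpy(),
                "E": pheno["event"].to_numpy(),
            }
        )
        fit = lifelines.CoxPHFitter().fit(df, "T", "E")
        est = fit.params_["z_cell"]
        se = fit.standard_errors_["z_cell"]
        assert abs(est - b) < 2 * se

    def test_all_censored_world_fails_downstream_cox(self):
        cfg = ec.SimulationConfig(
            n_samples=(50,), age_ranges=((20, 80),), n_probes=10, n_causal=0,
            target_rho2=0.0, baseline_hazard=1e-9, horizon=0.5,
            dropout_fraction=0.0, seed=2,
        )
        _, pheno, _ = ec.simulate_world(cfg)
        assert pheno["event"].sum() == 0
        with pytest.raises(ec.survival.CoxError, match="no events"):
            ec.survival.cox_newton(
                pheno[["age"]].to_numpy(),
                pheno["surv_time"].to_numpy(),
                pheno["event"].to_numpy(),
            )

    def test_weibull_times_positive_and_censoring_respected(self):
        cfg = ec.SimulationConfig(
            n_samples=(200,), age_ranges=((20, 90),), n_probes=10, n_causal=0,
            target_rho2=0.0, survival_dist="weibull", weibull_shape=1.5,
            horizon=10.0, seed=6,
        )
        _, pheno, _ = ec.simulate_world(cfg)
        assert (pheno["surv_time"] > 0).all()
        assert (pheno["surv_time"] <= 10.0).all()
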