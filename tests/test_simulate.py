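"""Synthetic-data generator: determinism, design shape, moment recovery."""

import numpy as np
import pandas as pd
import pytest

from antvar import SimulationConfig, generate_dataset, generate_study
from antvar.config import ConfigError
from antvar.simulate import (
    generate_nest_displacement,
    generate_productivity,
    simulate_individual_production,
)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SimulationConfig().validate()

    @pytest.mark.parametrize("kwargs, match", [
        (dict(n_workers_per_colony=0), "n_workers_per_colony"),
        (dict(sigma2_id_mu=-0.1), "sigma2_id_mu"),
        (dict(colony_size_range=(0, 100)), "colony_size_range"),
        (dict(beta=(0.0,) * 5), "beta"),
        (dict(nb_size=-1.0), "nb_size"),
        (dict(sigma2_id_mu=0.01, sigma2_id_sigma=0.01, cov_mu_sigma=0.5),
         "cov_mu_sigma"),
    ])
    def test_invalid_configs_name_the_invariant(self, kwargs, match):
        with pytest.raises(ConfigError, match=match):
            SimulationConfig(**kwargs)

    def test_non_psd_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 0.95, -0.95],
                        [0.95, 1.0, 0.95],
                        [-0.95, 0.95, 1.0]])
        cfg = SimulationConfig()
        cfg.level_correlation_matrices["colony"] = bad
        with pytest.raises(ConfigError, match="positive semidefinite"):
            cfg.validate()

    def test_yaml_roundtrip(self, tmp_path, study_config):
        path = tmp_path / "cfg.yaml"
        study_config.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.beta == study_config.beta
        np.testing.assert_allclose(
            back.level_correlation_matrices["colony"],
            study_config.level_correlation_matrices["colony"])


def test_study_design_shape(study):
    """23 colonies x 12 workers x 3 repeats = 828 rows per trait."""
    per_trait = study.trials.groupby("assay").size()
    assert (per_trait == 828).all()
    assert study.trials["individual_id"].nunique() == 276
    assert len(study.colonies) == 23
    assert study.colonies["habitat"].value_counts()["seminatural"] == 12
    sizes = study.colonies["colony_size"]
    assert sizes.between(219, 5964).all()
    assert study.colonies["myrmica_nests"].between(0, 9).all()
    assert study.colonies["allo_nests"].between(0, 3).all()


def test_identical_config_and_seed_give_identical_tables(study_config, study):
    again = generate_study(SimulationConfig(seed=study_config.seed))
    assert study.trials.to_csv(index=False) == again.trials.to_csv(index=False)
    assert study.colonies.to_csv(index=False) == again.colonies.to_csv(index=False)
    assert study.truth.to_csv(index=False) == again.truth.to_csv(index=False)


def test_different_seed_changes_data(study):
    other = generate_study(SimulationConfig(seed=8))
    assert not np.allclose(other.trials["raw_value"], study.trials["raw_value"])


def test_degenerate_config_gives_unit_noise():
    """All variances and coefficients zero: latent values are N(0, 1)."""
    cfg = SimulationConfig(seed=3, n_colonies_per_habitat=(25, 25),
                           n_workers_per_colony=10, n_repeats_per_assay=3,
                           beta=(0.0,) * 7, gamma=(0.0,) * 6,
                           sigma2_id_mu=0.0, sigma2_colony=0.0,
                           sigma2_id_sigma=0.0, cov_mu_sigma=0.0)
    trials, _, _ = generate_dataset(cfg)
    lat = trials.loc[trials["assay"] == "activity", "latent_value"]
    assert abs(lat.mean()) < 3.0 / np.sqrt(len(lat))
    assert lat.std() == pytest.approx(1.0, abs=0.05)


def test_among_individual_variance_recovered_from_trial_means():
    """sigma2_id_mu = 1 with tiny residual: variance of individual means ~ 1."""
    cfg = SimulationConfig(seed=5, n_colonies_per_habitat=(25, 25),
                           n_workers_per_colony=10, n_repeats_per_assay=50,
                           beta=(0.0,) * 7, gamma=(-2.0, 0, 0, 0, 0, 0),
                           sigma2_id_mu=1.0, sigma2_colony=0.0,
                           sigma2_id_sigma=0.0, cov_mu_sigma=0.0)
    trials, _, _ = generate_dataset(cfg)
    means = (trials[trials["assay"] == "exploration"]
             .groupby("individual_id")["latent_value"].mean())
    n = len(means)
    se = np.sqrt(2.0 / (n - 1))   # SE of a variance estimate at sigma2=1
    assert means.var() == pytest.approx(1.0, abs=3 * se)


def test_truth_moments_match_configured_values(study_config):
    """Realized random-effect moments within 3 SE at >= 500 individuals."""
    cfg = SimulationConfig(seed=9, n_colonies_per_habitat=(25, 25),
                           n_workers_per_colony=12)
    _, _, truth = generate_dataset(cfg)
    ind = truth[(truth.level == "individual") & (truth.trait == "activity")]
    n = len(ind)
    assert n == 600
    se_var = np.sqrt(2.0 / (n - 1)) * cfg.sigma2_id_mu
    assert ind.effect_mu.var() == pytest.approx(cfg.sigma2_id_mu, abs=3 * se_var)
    se_var_s = np.sqrt(2.0 / (n - 1)) * cfg.sigma2_id_sigma
    assert ind.effect_sigma.var() == pytest.approx(cfg.sigma2_id_sigma,
                                                   abs=3 * se_var_s)
    r_true = cfg.cov_mu_sigma / np.sqrt(cfg.sigma2_id_mu * cfg.sigma2_id_sigma)
    r_emp = np.corrcoef(ind.effect_mu, ind.effect_sigma)[0, 1]
    assert r_emp == pytest.approx(r_true, abs=3.0 / np.sqrt(n))


def test_level_correlations_of_stored_truth_match_config():
    cfg = SimulationConfig(seed=21, n_colonies_per_habitat=(30, 30),
                           n_workers_per_colony=10)
    _, _, truth = generate_dataset(cfg)
    ind = truth[truth.level == "individual"].pivot(
        index="unit_id", columns="trait", values="effect_mu")
    want = cfg.level_correlation_matrices["individual"]
    order = ("activity", "meandering", "exploration", "aggression")
    got = ind[list(order)].corr().to_numpy()
    n = len(ind)
    assert np.abs(got - want).max() < 3.0 / np.sqrt(n) + 0.02


class TestNestDisplacement:
    def test_three_positive_times_per_colony(self, study):
        times = study.colonies[["displacement_1", "displacement_2",
                                "displacement_3"]]
        assert times.shape == (23, 3)
        assert (times > 0).all().all()

    def test_colony_size_slope_recovered_at_200_colonies(self):
        """Generating slope -0.49 on standardized log colony size."""
        cfg = SimulationConfig(seed=13, n_colonies_per_habitat=(100, 100))
        trials, colonies, _ = generate_dataset(cfg)
        colonies, _ = generate_nest_displacement(cfg, colonies)
        lat = np.concatenate([colonies[f"displacement_latent_{r}"] for r in (1, 2, 3)])
        x = np.log(colonies["colony_size"].to_numpy(float))
        xz = np.tile((x - x.mean()) / x.std(), 3)
        slope = np.polyfit(xz, lat, 1)[0]
        assert slope == pytest.approx(-0.49, abs=0.15)

    def test_zero_colony_variance_gives_near_zero_icc(self):
        cfg = SimulationConfig(seed=14, n_colonies_per_habitat=(50, 50),
                               disp_beta=(0.0,) * 7, disp_gamma=(0.0,) * 6,
                               disp_sigma2_colony_mu=0.0,
                               disp_sigma2_colony_sigma=0.0, disp_cov=0.0)
        trials, colonies, _ = generate_dataset(cfg)
        colonies, _ = generate_nest_displacement(cfg, colonies)
        lat = colonies[[f"displacement_latent_{r}" for r in (1, 2, 3)]].to_numpy()
        grand = lat.var()
        among = lat.mean(axis=1).var()
        # among-colony variance of means ~ within/3 under the null
        assert among / grand < 0.5 / 3 + 0.1

    def test_missing_colonies_rejected(self, study_config):
        with pytest.raises(ValueError, match="colony table"):
            generate_nest_displacement(study_config, pd.DataFrame())


class TestProductivity:
    def test_intercept_only_link_sets_the_mean(self):
        cfg = SimulationConfig(
            seed=15, n_colonies_per_habitat=(60, 60),
            productivity_link={"intercept": float(np.log(100.0))})
        ds = generate_study(cfg)
        mean = ds.colonies["total_production"].mean()
        assert mean == pytest.approx(100.0, rel=0.15)

    def test_counts_are_nonnegative_integers(self, study):
        for c in ("total_production", "new_workers", "new_gynes", "new_males"):
            v = study.colonies[c]
            assert (v >= 0).all()
            assert (v == v.astype(int)).all()

    def test_large_nb_size_approaches_poisson_dispersion(self):
        base = dict(seed=16, n_colonies_per_habitat=(150, 150),
                    productivity_link={"intercept": float(np.log(50.0))})
        near_poisson = generate_study(SimulationConfig(nb_size=2e5, **base))
        y = near_poisson.colonies["total_production"].to_numpy(float)
        ratio = y.var() / y.mean()
        # Poisson oracle: variance/mean -> 1; chi-square spread at n=300
        assert ratio == pytest.approx(1.0, abs=0.25)
        overdispersed = generate_study(SimulationConfig(nb_size=2.0, **base))
        y2 = overdispersed.colonies["total_production"].to_numpy(float)
        assert y2.var() / y2.mean() > 5.0

    def test_single_worker_colony_rejected(self):
        cfg = SimulationConfig(seed=17, n_workers_per_colony=1)
        trials, colonies, _ = generate_dataset(cfg)
        with pytest.raises(Exception, match="minimum group size"):
            generate_productivity(cfg, trials, colonies)


def test_individual_production_simulator_recovers_design():
    frame, names = simulate_individual_production(
        n_individuals=50, coefficients={"activity": 0.2}, seed=3)
    assert len(frame) == 150
    assert frame["individual_id"].nunique() == 50
    assert (frame["count"] >= 0).all()
    assert set(names).issubset(frame.columns)
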