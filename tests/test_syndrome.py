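"""Multivariate model: correlation decomposition and pMCMC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antvar import (
    MultiTraitModel,
    decompose_correlations,
    fixed_effect_pmcmc,
)

FAST = dict(chains=2, iterations=1500, burn_in=500, thin=2)


def two_trait_data(seed, n_col=20, n_ind_per=8, n_rep=4, r_ind=0.9,
                   r_res=0.0, s_ind=0.6, s_col=0.3, s_res=0.7,
                   habitat_effect=0.0):
    rng = np.random.default_rng(seed)
    n_ind = n_col * n_ind_per
    cols = np.repeat(np.arange(n_col), n_ind_per)
    si = s_ind * np.array([[1.0, r_ind], [r_ind, 1.0]])
    sr = s_res * np.array([[1.0, r_res], [r_res, 1.0]])
    u = rng.multivariate_normal([0, 0], si, size=n_ind)
    c = rng.normal(0, np.sqrt(s_col), size=(n_col, 2))
    rows = np.repeat(np.arange(n_ind), n_rep)
    hab = (cols[rows] < n_col // 2).astype(float)
    y = (u[rows] + c[cols[rows]]
         + rng.multivariate_normal([0, 0], sr, size=len(rows))
         + habitat_effect * hab[:, None])
    return y, hab, cols[rows], rows


class TestDecomposeCorrelations:
    def test_diagonal_draws_give_identity(self):
        draws = np.stack([np.diag([1.0, 2.0, 3.0])] * 50)
        lc = decompose_correlations(draws, ("a", "b", "c"), "colony")
        np.testing.assert_allclose(lc.matrix, np.eye(3), atol=1e-12)

    def test_single_draw_is_a_point_mass(self):
        draws = np.array([[[1.0, 0.5], [0.5, 1.0]]])
        lc = decompose_correlations(draws, ("a", "b"), "individual")
        pair = lc.pair("a", "b")
        assert pair["r"] == pytest.approx(0.5)
        assert pair["cri"] == (pytest.approx(0.5), pytest.approx(0.5))
        assert pair["supported"]

    def test_wishart_draws_recover_scale_correlation(self, rng):
        """Monte Carlo oracle: posterior mean within 3 MC SE of truth."""
        true = np.array([[1.0, 0.6], [0.6, 1.0]])
        df = 200
        draws = stats.wishart.rvs(df, true / df, size=4000, random_state=rng)
        lc = decompose_correlations(draws, ("a", "b"), "colony")
        corr = draws[:, 0, 1] / np.sqrt(draws[:, 0, 0] * draws[:, 1, 1])
        mc_se = corr.std() / np.sqrt(len(corr))
        assert lc.pair("a", "b")["r"] == pytest.approx(corr.mean(), abs=1e-12)
        assert abs(lc.pair("a", "b")["r"] - 0.6) < 3 * (mc_se + 1.0 / np.sqrt(df))

    def test_zero_variance_draws_dropped_with_count(self):
        good = np.stack([np.eye(2)] * 10)
        bad = np.zeros((3, 2, 2))
        lc = decompose_correlations(np.concatenate([good, bad]), ("a", "b"),
                                    "residual")
        assert lc.n_dropped == 3

    def test_all_degenerate_draws_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            decompose_correlations(np.zeros((4, 2, 2)), ("a", "b"), "colony")


class TestPmcmc:
    def test_symmetric_draws_give_p_near_one(self, rng):
        x = np.concatenate([rng.standard_normal(5000),
                            -rng.standard_normal(5000)])
        _, _, p = fixed_effect_pmcmc(x)
        assert p > 0.9

    def test_one_sided_extreme_is_bounded_not_zero(self):
        _, _, p = fixed_effect_pmcmc(np.abs(np.random.default_rng(0)
                                            .standard_normal(500)) + 0.01)
        assert 0 < p <= 2.0 / 500 * 2

    def test_unit_normal_matches_gaussian_tail(self, rng):
        x = rng.normal(1.0, 1.0, size=10_000)
        eff, cri, p = fixed_effect_pmcmc(x)
        assert p == pytest.approx(2 * stats.norm.cdf(-1.0), abs=0.03)
        assert eff == pytest.approx(1.0, abs=0.05)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fixed_effect_pmcmc(np.array([]))


class TestMultiTraitModel:
    def test_fewer_than_two_traits_rejected(self):
        with pytest.raises(ValueError, match="2 traits"):
            MultiTraitModel(np.zeros((10, 1)), np.zeros(10), np.zeros(10))

    def test_unbalanced_trait_availability_points_to_filter(self, study):
        broken = study.trials.drop(index=study.trials.index[:1])
        from antvar.data import transform_and_standardize
        with pytest.raises(ValueError, match="filter_complete_cases"):
            MultiTraitModel.from_trials(transform_and_standardize(broken))

    def test_seeded_determinism(self):
        y, hab, col, ind = two_trait_data(1)
        m = MultiTraitModel(y, hab, col, ind, traits=("a", "b"))
        r1 = m.fit(seed=9, **FAST)
        r2 = m.fit(seed=9, **FAST)
        for key in r1.samples:
            np.testing.assert_array_equal(r1.samples[key], r2.samples[key])

    def test_among_individual_syndrome_recovered(self):
        """r_ind = 0.9, r_res = 0: level CrIs contain their truths."""
        y, hab, col, ind = two_trait_data(2, n_col=30, n_ind_per=7, n_rep=5)
        res = MultiTraitModel(y, hab, col, ind, traits=("a", "b")).fit(
            chains=2, iterations=2000, burn_in=700, thin=2, seed=11)
        pi = res.level_correlations("individual").pair("a", "b")
        pr = res.level_correlations("residual").pair("a", "b")
        assert pi["cri"][0] <= 0.9 <= pi["cri"][1]
        assert pr["cri"][0] <= 0.0 <= pr["cri"][1]
        assert pi["supported"] and not pr["supported"]

    def test_duplicated_trait_correlates_at_every_level(self):
        y, hab, col, ind = two_trait_data(3, n_col=15, n_ind_per=6, n_rep=4)
        dup = np.column_stack([y[:, 0], y[:, 0]])
        res = MultiTraitModel(dup, hab, col, ind, traits=("a", "a2")).fit(
            seed=12, **FAST)
        for level in res.levels:
            assert res.level_correlations(level).pair("a", "a2")["r"] > 0.8

    def test_trait_permutation_permutes_output(self):
        y, hab, col, ind = two_trait_data(4)
        r_ab = MultiTraitModel(y, hab, col, ind, traits=("a", "b")).fit(
            seed=13, **FAST)
        r_ba = MultiTraitModel(y[:, ::-1], hab, col, ind, traits=("b", "a")).fit(
            seed=13, **FAST)
        for level in r_ab.levels:
            m1 = r_ab.level_correlations(level).matrix
            m2 = r_ba.level_correlations(level).matrix
            assert m1[0, 1] == pytest.approx(m2[1, 0], abs=0.12)

    def test_moment_oracle_agreement_for_among_individual_correlation(self):
        """Method-of-moments on individual mean deviations vs the sampler."""
        y, hab, col, ind = two_trait_data(5, n_col=25, n_ind_per=10, n_rep=6,
                                          s_col=0.05)
        res = MultiTraitModel(y, hab, col, ind, traits=("a", "b")).fit(
            chains=2, iterations=2000, burn_in=700, thin=2, seed=14)
        # method-of-moments oracle: among-individual covariance =
        # cov(individual means) - within-individual covariance / n_rep
        n_rep = 6
        d = pd.DataFrame({"ind": ind, "a": y[:, 0], "b": y[:, 1]})
        means = d.groupby("ind")[["a", "b"]].mean()
        resid = d[["a", "b"]].to_numpy() - means.loc[d["ind"]].to_numpy()
        n_ind_total = len(means)
        s_w = resid.T @ resid / (len(d) - n_ind_total)
        s_b = np.cov(means.T) - s_w / n_rep
        oracle = s_b[0, 1] / np.sqrt(s_b[0, 0] * s_b[1, 1])
        fitted = res.level_correlations("individual").pair("a", "b")["r"]
        assert fitted == pytest.approx(oracle, abs=0.1)

    def test_habitat_effect_recovery_and_pmcmc(self):
        y, hab, col, ind = two_trait_data(6, n_col=40, habitat_effect=0.5)
        res = MultiTraitModel(y, hab, col, ind, traits=("a", "b")).fit(
            seed=15, **FAST)
        eff, cri, p = res.habitat_effect()
        assert eff == pytest.approx(0.5, abs=0.25)
        assert p < 0.05

    def test_per_draw_correlations_are_psd_with_unit_diagonal(self):
        y, hab, col, ind = two_trait_data(7)
        res = MultiTraitModel(y, hab, col, ind, traits=("a", "b")).fit(
            seed=16, **FAST)
        for level in res.levels:
            draws = res.cov_draws(level)
            assert (np.linalg.eigvalsh(draws).min(axis=1) > -1e-10).all()
            corr = draws[:, 0, 1] / np.sqrt(draws[:, 0, 0] * draws[:, 1, 1])
            assert (np.abs(corr) <= 1.0 + 1e-12).all()


class TestFiveTraitForm:
    def test_displacement_joins_at_colony_level(self, trials_z, study):
        model = MultiTraitModel.from_trials_and_displacement(trials_z,
                                                             study.colonies)
        assert model.traits[-1] == "displacement"
        assert model.ind is None
        res = model.fit(seed=17, chains=2, iterations=800, burn_in=300, thin=2)
        lc = res.level_correlations("colony")
        assert lc.interpretable
        assert not res.level_correlations("residual").interpretable
        assert np.isfinite(lc.matrix).all()
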