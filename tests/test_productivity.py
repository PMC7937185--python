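"""Production regressions: NB-GLM/GLMM behaviour and model selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from antvar import (
    ColonyProductionModel,
    IndividualProductionModel,
    NegativeBinomialMixedModel,
    SimulationConfig,
    generate_study,
    select_by_information_criterion,
)
from antvar.productivity import (
    DegenerateFitError,
    ModelSkipped,
    aicc,
    individual_design,
)
from antvar.simulate import simulate_individual_production


@pytest.fixture(scope="module")
def exploration_study():
    """200 colonies; only mean exploration drives total production (+0.73)."""
    link = {"intercept": 6.39, "mean_exploration": 0.73}
    cfg = SimulationConfig(seed=71, n_colonies_per_habitat=(100, 100),
                           productivity_link=link)
    return generate_study(cfg)


class TestColonyModel:
    def test_exploration_effect_recovered(self, exploration_study):
        fit = ColonyProductionModel(exploration_study.colonies,
                                    exploration_study.trials, "total").fit()
        assert fit.family == "negative_binomial"
        row = fit.coefficients.loc["mean_exploration"]
        assert row["ci_low"] <= 0.73 <= row["ci_high"]
        assert row["supported"]

    def test_stepwise_selection_retains_the_true_term(self, exploration_study):
        fit = ColonyProductionModel(exploration_study.colonies,
                                    exploration_study.trials, "total").fit(
                                        selection="stepwise")
        assert "mean_exploration" in fit.coefficients.index
        path = fit.selection_path
        best = path.iloc[0]
        assert (path["criterion"] >= best["criterion"]).all()

    def test_poisson_kept_when_no_overdispersion(self):
        link = {"intercept": np.log(40.0)}
        cfg = SimulationConfig(seed=72, n_colonies_per_habitat=(60, 60),
                               nb_size=1e6, productivity_link=link)
        ds = generate_study(cfg)
        fit = ColonyProductionModel(ds.colonies, ds.trials, "total").fit()
        assert fit.family == "poisson"
        assert fit.pearson_dispersion < 1.5

    def test_poisson_limit_matches_poisson_glm_oracle(self):
        link = {"intercept": np.log(60.0), "mean_activity": 0.3}
        cfg = SimulationConfig(seed=73, n_colonies_per_habitat=(80, 80),
                               nb_size=1e6, productivity_link=link)
        ds = generate_study(cfg)
        model = ColonyProductionModel(ds.colonies, ds.trials, "total")
        fit = model.fit()
        exog, _ = model._exog(model.terms)
        oracle = sm.GLM(model.y, exog, family=sm.families.Poisson()).fit()
        est = fit.coefficients["estimate"].to_numpy()
        se = fit.coefficients["se"].to_numpy()
        assert np.all(np.abs(est - np.asarray(oracle.params)) <= 3 * se + 1e-6)

    def test_males_model_skipped_when_unsupported(self, exploration_study):
        colonies = exploration_study.colonies.copy()
        colonies["pupae_male"] = 0
        colonies["winged_males"] = 0
        colonies.loc[colonies.index[:2], "pupae_male"] = 3
        from antvar.data import derive_production
        colonies = derive_production(
            colonies.drop(columns=["total_production", "new_workers",
                                   "new_gynes", "new_males"]))
        with pytest.raises(ModelSkipped, match="males"):
            ColonyProductionModel(colonies, exploration_study.trials, "males")

    def test_too_few_colonies_rejected(self, study):
        with pytest.raises(ValueError, match="colonies"):
            ColonyProductionModel(study.colonies.iloc[:5], study.trials)

    def test_constant_response_rejected(self, study):
        colonies = study.colonies.copy()
        for c in ("n_larvae", "pupae_worker", "pupae_male", "pupae_gyne",
                  "winged_gynes", "winged_males"):
            colonies[c] = 10
        from antvar.data import derive_production
        colonies = derive_production(
            colonies.drop(columns=["total_production", "new_workers",
                                   "new_gynes", "new_males"]))
        with pytest.raises(DegenerateFitError):
            ColonyProductionModel(colonies, study.trials, "total")


class TestNbGlmm:
    def test_row_level_coefficient_recovered(self):
        frame, names = simulate_individual_production(
            n_individuals=300, coefficients={"activity": 0.18}, seed=81)
        exog = sm.add_constant(frame[["activity"]].to_numpy(), prepend=True)
        res = NegativeBinomialMixedModel(frame["count"], exog,
                                         frame["individual_id"],
                                         names=["intercept", "activity"]).fit()
        coef = res.coefficients()
        assert coef.loc["activity", "ci_low"] <= 0.18 <= coef.loc["activity", "ci_high"]
        assert res.sigma == pytest.approx(0.3, abs=0.1)

    def test_constant_response_rejected(self):
        with pytest.raises(DegenerateFitError):
            NegativeBinomialMixedModel(np.full(30, 7.0), np.ones((30, 1)),
                                       np.repeat(np.arange(10), 3))

    def test_null_fixed_effects_rarely_supported(self):
        """Strong individual effect, zero fixed effects: flags mostly off."""
        false_hits = 0
        n_terms = 0
        for rep in range(10):
            frame, names = simulate_individual_production(
                n_individuals=120, coefficients={}, sigma_individual=0.5,
                seed=900 + rep)
            exog = sm.add_constant(frame[names].to_numpy(), prepend=True)
            res = NegativeBinomialMixedModel(frame["count"], exog,
                                             frame["individual_id"],
                                             names=["intercept"] + names).fit()
            flags = res.coefficients().loc[names, "supported"]
            false_hits += int(flags.sum())
            n_terms += len(names)
        assert false_hits / n_terms <= 0.10


class TestIndividualModel:
    def test_design_duplicates_colony_response(self, trials_z, study):
        d = individual_design(trials_z, study.colonies, "total", "all")
        per_colony = d.groupby("colony_id")["total_production"].nunique()
        assert (per_colony == 1).all()
        assert d["habitat"].isin(["seminatural", "invaded"]).all()

    def test_habitat_subset_row_counts(self, trials_z, study):
        d_semi = individual_design(trials_z, study.colonies, "total",
                                   "seminatural")
        d_inv = individual_design(trials_z, study.colonies, "total", "invaded")
        assert set(d_semi["habitat"]) == {"seminatural"}
        assert len(d_semi) + len(d_inv) == len(
            individual_design(trials_z, study.colonies, "total", "all"))

    def test_fit_runs_and_reports_family(self, trials_z, study):
        fit = IndividualProductionModel(trials_z, study.colonies, "total",
                                        "seminatural").fit()
        assert fit.family in ("negative_binomial", "gaussian")
        assert {"estimate", "ci_low", "ci_high", "supported"}.issubset(
            fit.coefficients.columns)

    def test_gaussian_family_can_be_forced(self, trials_z, study):
        model = IndividualProductionModel(trials_z, study.colonies, "total",
                                          "invaded")
        fit = model.fit(family="gaussian")
        assert fit.family == "gaussian"
        assert fit.sigma_individual is not None


class TestSelection:
    @staticmethod
    def _quadratic_fit_fn(truth_terms):
        def fit_fn(terms):
            # lower criterion the closer to the truth set; +2 per extra term
            missing = len(set(truth_terms) - set(terms))
            extra = len(set(terms) - set(truth_terms))
            aic = 100.0 + 25.0 * missing + 2.5 * extra
            return aic, len(terms) + 1
        return fit_fn

    def test_all_subsets_visits_exactly_four_models_for_two_terms(self):
        fit_fn = self._quadratic_fit_fn(["a"])
        best, path = select_by_information_criterion(fit_fn, ["a", "b"],
                                                     strategy="all_subsets",
                                                     n_obs=100)
        assert len(path) == 4
        assert best == ["a"]

    def test_smaller_model_wins_when_larger_has_higher_criterion(self):
        fit_fn = self._quadratic_fit_fn([])
        best, _ = select_by_information_criterion(fit_fn, ["a", "b", "c"],
                                                  strategy="stepwise",
                                                  n_obs=100)
        assert best == []

    def test_selection_invariant_to_term_ordering(self):
        fit_fn = self._quadratic_fit_fn(["b", "c"])
        b1, _ = select_by_information_criterion(fit_fn, ["a", "b", "c"],
                                                strategy="all_subsets", n_obs=50)
        b2, _ = select_by_information_criterion(fit_fn, ["c", "a", "b"],
                                                strategy="all_subsets", n_obs=50)
        assert set(b1) == set(b2) == {"b", "c"}

    def test_combinatorial_guard(self):
        with pytest.raises(ValueError, match="force"):
            select_by_information_criterion(lambda t: (0.0, 1),
                                            [f"t{i}" for i in range(25)],
                                            strategy="all_subsets", n_obs=10)

    def test_aicc_formula_matches_independent_computation(self):
        aic, k, n = 123.4, 5, 40
        assert aicc(aic, k, n) == pytest.approx(aic + 2 * 5 * 6 / (40 - 5 - 1))
        assert aicc(aic, 39, 40) == np.inf

    def test_intercept_only_truth_selects_no_terms_mostly(self):
        """Null all-subsets selection keeps the empty model most of the time."""
        keeps_null = 0
        for rep in range(10):
            link = {"intercept": 6.0}
            cfg = SimulationConfig(seed=600 + rep,
                                   n_colonies_per_habitat=(50, 50),
                                   productivity_link=link)
            ds = generate_study(cfg)
            model = ColonyProductionModel(ds.colonies, ds.trials, "total")
            best, _ = select_by_information_criterion(
                model._aic_for_terms, model.terms, strategy="stepwise",
                n_obs=len(model.y))
            keeps_null += len(best) <= 2
        assert keeps_null >= 8
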