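"""Fitness-consequence regressions: production counts on behaviour.

Colony level: a negative-binomial GLM (log link, ML including the
dispersion parameter) of a brood-production count on habitat plus the
per-colony mean and SD of each standardized behavioural trait —
overdispersion is assessed by fitting Poisson first and switching to NB
when the Pearson dispersion statistic exceeds 1.5.

Individual level: the colony's production count is attached to each of
the colony's trial rows (one row per individual and trial series, traits
as fixed effects) and modelled as a negative-binomial GLMM with a random
intercept per individual, fitted by Laplace-approximation ML (no NB
mixed model exists in statsmodels, so the marginal likelihood is
implemented here: per-group posterior modes by Newton steps, Gaussian
curvature correction, outer quasi-Newton optimisation of fixed effects,
dispersion and random-effect SD).  Where the NB fit fails to converge a
Gaussian LMM is the documented fallback.

Automated model selection: bidirectional stepwise AIC over fixed-effect
terms, or exhaustive all-subsets ranking by AICc (random effects always
retained), with ties broken toward fewer parameters.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

from .data import INDIVIDUAL_TRAITS, colony_trait_summaries, transform_and_standardize

RESPONSE_COLUMNS = {
    "total": "total_production",
    "workers": "new_workers",
    "gynes": "new_gynes",
    "males": "new_males",
}


class ModelSkipped(RuntimeError):
    """The data cannot support this model (reported, not fatal)."""


class DegenerateFitError(RuntimeError):
    pass


@dataclass
class ProductivityFit:
    """Coefficient table and metadata of one production regression."""

    response: str
    scope: str                       # colony | individual
    habitat_subset: str
    family: str                      # negative_binomial | poisson | gaussian
    coefficients: pd.DataFrame      # estimate, se, ci_low, ci_high, p, supported
    dispersion: float | None = None  # NB size parameter (1/alpha)
    sigma_individual: float | None = None
    llf: float | None = None
    aic: float | None = None
    selection_path: pd.DataFrame | None = None
    pearson_dispersion: float | None = None
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"{self.scope}-level {self.family} model of {self.response} "
                 f"({self.habitat_subset} habitats)"]
        for term, row in self.coefficients.iterrows():
            star = " *" if row["supported"] else ""
            lines.append(f"  {term:22s} {row['estimate']:8.3f} "
                         f"({row['ci_low']:.3f} to {row['ci_high']:.3f}){star}")
        if self.dispersion is not None:
            lines.append(f"  NB size = {self.dispersion:.2f}")
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


def _coef_frame(params, se, names, level=0.95):
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = params - z * se
    hi = params + z * se
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2 * stats.norm.sf(np.abs(params / se))
    return pd.DataFrame({
        "estimate": params, "se": se, "ci_low": lo, "ci_high": hi,
        "p": pvals, "supported": (lo > 0) | (hi < 0),
    }, index=names)


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# colony-level NB-GLM


def _check_males_support(counts: np.ndarray, response: str, min_nonzero: int = 5):
    if response == "males" and int(np.sum(counts > 0)) < min_nonzero:
        raise ModelSkipped(
            f"only {int(np.sum(counts > 0))} colonies produced males "
            f"(< {min_nonzero}); male-production model skipped"
        )


def colony_design(colonies: pd.DataFrame, trials: pd.DataFrame,
                  traits=INDIVIDUAL_TRAITS) -> pd.DataFrame:
    """Per-colony design: habitat + standardized trait means and SDs.

    Trait summaries are computed from the transformed, standardized trial
    values; nest-displacement summaries come from the colony table's
    three log-transformed repeat times.  Each summary column is itself
    z-scored across colonies (all variables standardized before
    analysis).
    """
    tz = trials if "z_value" in trials.columns else transform_and_standardize(trials)
    summ = colony_trait_summaries(tz, "z_value").set_index("colony_id")
    disp = np.log1p(colonies[["displacement_1", "displacement_2",
                              "displacement_3"]].to_numpy(float))
    dz = (disp - disp.mean()) / disp.std()
    summ["mean_displacement"] = pd.Series(dz.mean(axis=1),
                                          index=colonies["colony_id"]).reindex(summ.index)
    summ["sd_displacement"] = pd.Series(dz.std(axis=1, ddof=1),
                                        index=colonies["colony_id"]).reindex(summ.index)
    for c in summ.columns:
        x = summ[c].to_numpy(float)
        summ[c] = (x - x.mean()) / x.std()
    summ["habitat"] = (colonies.set_index("colony_id")["habitat"]
                       .reindex(summ.index) == "invaded").astype(float)
    return summ.reset_index()


class ColonyProductionModel:
    """NB-GLM of a colony production count on behavioural summaries."""

    def __init__(self, colonies, trials, response="total",
                 traits=INDIVIDUAL_TRAITS, min_colonies=12):
        if len(colonies) < min_colonies:
            raise ValueError(f"need >= {min_colonies} colonies")
        design = colony_design(colonies, trials, traits)
        merged = design.merge(
            colonies[["colony_id"] + list(RESPONSE_COLUMNS.values())],
            on="colony_id")
        self.response = response
        self.y = merged[RESPONSE_COLUMNS[response]].to_numpy(float)
        _check_males_support(self.y, response)
        self.terms = (["habitat"]
                      + [f"mean_{t}" for t in list(traits) + ["displacement"]]
                      + [f"sd_{t}" for t in list(traits) + ["displacement"]])
        self.design = merged
        if self.y.std() == 0:
            raise DegenerateFitError("response is constant across colonies")

    def _exog(self, terms):
        x = self.design[list(terms)].to_numpy(float)
        return sm.add_constant(x, prepend=True), ["intercept"] + list(terms)

    def _fit_terms(self, terms):
        """Poisson first; NB when Pearson dispersion > 1.5."""
        exog, names = self._exog(terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.GLM(self.y, exog, family=sm.families.Poisson()).fit()
            pearson = float(pois.pearson_chi2 / pois.df_resid) if pois.df_resid > 0 else np.inf
            if pearson > 1.5:
                nb = sm.NegativeBinomial(self.y, exog).fit(disp=False, maxiter=200,
                                                           method="bfgs")
                if not np.all(np.isfinite(nb.bse)):
                    nb = sm.NegativeBinomial(self.y, exog).fit(disp=False, maxiter=500,
                                                               method="nm")
                return nb, names, "negative_binomial", pearson
        return pois, names, "poisson", pearson

    def fit(self, selection: str | None = None) -> ProductivityFit:
        """Fit the full model, optionally with stepwise/all-subsets selection."""
        path = None
        terms = list(self.terms)
        if selection:
            terms, path = select_by_information_criterion(
                self._aic_for_terms, self.terms, strategy=selection,
                n_obs=len(self.y))
        res, names, family, pearson = self._fit_terms(terms)
        params = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        if family == "negative_binomial":
            # last parameter of statsmodels NegativeBinomial is alpha
            disp = 1.0 / float(params[-1]) if params[-1] > 0 else np.inf
            coef = _coef_frame(params[:-1], se[:-1], names)
        else:
            disp = None
            coef = _coef_frame(params, se, names)
        if not np.all(np.isfinite(se)):
            raise RuntimeError(f"model did not converge; trace:\n{res.summary()}")
        return ProductivityFit(self.response, "colony", "all", family, coef,
                               dispersion=disp, llf=float(res.llf),
                               aic=float(res.aic), selection_path=path,
                               pearson_dispersion=pearson)

    def _aic_for_terms(self, terms):
        res, _, _, _ = self._fit_terms(terms)
        k = len(terms) + 1 + (1 if hasattr(res, "lnalpha") or
                              isinstance(res.model, sm.NegativeBinomial) else 0)
        return float(res.aic), k


# ---------------------------------------------------------------------------
# model selection


def select_by_information_criterion(fit_fn, candidate_terms, strategy="stepwise",
                                    n_obs=None, forced=(), max_terms=20,
                                    force=False):
    """Search fixed-effect subsets by information criterion.

    ``fit_fn(terms) -> (aic, k)`` fits one candidate.  ``stepwise`` does
    bidirectional AIC steps from the full model; ``all_subsets``
    enumerates every subset ranked by AICc.  Ties break toward fewer
    parameters.  Returns ``(best_terms, path)``.
    """
    candidate_terms = list(candidate_terms)
    if strategy == "all_subsets" and len(candidate_terms) > max_terms and not force:
        raise ValueError(
            f"{len(candidate_terms)} candidate terms would need "
            f"2^{len(candidate_terms)} fits; pass force=True to insist"
        )
    records = []

    def crit(terms):
        aic, k = fit_fn(list(terms))
        value = aicc(aic, k, n_obs) if strategy == "all_subsets" else aic
        records.append(dict(terms=tuple(terms), criterion=value, k=k))
        return value, k

    if strategy == "all_subsets":
        free = [t for t in candidate_terms if t not in forced]
        best = None
        for r in range(len(free) + 1):
            for combo in itertools.combinations(free, r):
                terms = list(forced) + list(combo)
                value, k = crit(terms)
                key = (value, k)
                if best is None or key < best[0]:
                    best = (key, terms)
        best_terms = best[1]
    elif strategy == "stepwise":
        current = list(candidate_terms)
        cur_val, cur_k = crit(current)
        improved = True
        while improved:
            improved = False
            moves = []
            for t in current:
                if t in forced:
                    continue
                moves.append([x for x in current if x != t])
            for t in candidate_terms:
                if t not in current:
                    moves.append(current + [t])
            best_move = None
            for terms in moves:
                value, k = crit(terms)
                if best_move is None or (value, k) < best_move[0]:
                    best_move = ((value, k), terms)
            if best_move and best_move[0] < (cur_val, cur_k):
                (cur_val, cur_k), current = best_move
                improved = True
        best_terms = current
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    path = pd.DataFrame(records).sort_values("criterion").reset_index(drop=True)
    return best_terms, path


# ---------------------------------------------------------------------------
# individual-level NB-GLMM (Laplace ML)


def _nb_eta_derivs(y, eta, alpha):
    mu = np.exp(eta)
    denom = 1.0 + alpha * mu
    grad = y - (alpha * y + 1.0) * mu / denom
    hess = (alpha * y + 1.0) * mu / denom**2
    return grad, hess


def _nb_loglik(y, eta, alpha):
    mu = np.exp(eta)
    inv_a = 1.0 / alpha
    return (special.gammaln(y + inv_a) - special.gammaln(inv_a)
            - special.gammaln(y + 1.0)
            + y * (np.log(alpha) + eta) - (y + inv_a) * np.log1p(alpha * mu))


class NegativeBinomialMixedModel:
    """NB2 GLMM with one random intercept, Laplace-approximation ML."""

    def __init__(self, y, exog, groups, names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        self.labels, self.g = np.unique(groups, return_inverse=True)
        self.n_g = len(self.labels)
        self.names = list(names) if names else [f"x{i}" for i in range(self.X.shape[1])]
        if self.y.std() == 0:
            raise DegenerateFitError("response is constant; nothing to model")
        if self.n_g < 2:
            raise ValueError("need >= 2 groups for a random intercept")

    def _inner_modes(self, beta, alpha, sigma2, b0):
        eta_fix = self.X @ beta
        b = b0.copy()
        for _ in range(50):
            grad, hess = _nb_eta_derivs(self.y, eta_fix + b[self.g], alpha)
            gsum = np.bincount(self.g, grad, minlength=self.n_g) - b / sigma2
            hsum = np.bincount(self.g, hess, minlength=self.n_g) + 1.0 / sigma2
            step = gsum / hsum
            step = np.clip(step, -2.0, 2.0)
            b = b + step
            if np.max(np.abs(gsum)) < 1e-8:
                break
        return b, hsum

    def _nll(self, theta, b_cache):
        beta = theta[:-2]
        alpha = np.exp(theta[-2])
        sigma2 = np.exp(2.0 * theta[-1])
        b, hsum = self._inner_modes(beta, alpha, sigma2, b_cache["b"])
        b_cache["b"] = b
        ll_obs = np.sum(_nb_loglik(self.y, self.X @ beta + b[self.g], alpha))
        ll = (ll_obs - 0.5 * np.sum(b**2) / sigma2
              - 0.5 * self.n_g * np.log(sigma2) - 0.5 * np.sum(np.log(hsum)))
        if not np.isfinite(ll):
            return 1e10
        return -ll

    def fit(self, maxiter=200) -> "NBMMResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start_glm = sm.GLM(self.y, self.X, family=sm.families.Poisson()).fit()
        theta0 = np.concatenate([np.asarray(start_glm.params), [0.0, np.log(0.3)]])
        cache = {"b": np.zeros(self.n_g)}
        res = optimize.minimize(self._nll, theta0, args=(cache,), method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-6})
        if not np.isfinite(res.fun):
            raise RuntimeError(f"NB-GLMM did not converge: {res.message}")
        from statsmodels.tools.numdiff import approx_hess2
        # freeze the inner-mode warm start so finite differences see a
        # smooth function (warm-start hysteresis corrupts the Hessian)
        self._nll(res.x, cache)
        b_opt = cache["b"].copy()
        hess = approx_hess2(res.x, lambda t: self._nll(t, {"b": b_opt.copy()}))
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            se_all = np.sqrt(np.where(diag > 0, diag, np.nan))
        except np.linalg.LinAlgError:
            se_all = np.full_like(res.x, np.nan)
        return NBMMResults(self, res.x, se_all, -res.fun, res)

    def fit_map(self):  # pragma: no cover - convenience alias
        return self.fit()


class NBMMResults:
    def __init__(self, model, theta, se, llf, optres):
        self.model = model
        k = len(model.names)
        self.params = theta[:k]
        self.bse = se[:k]
        self.alpha = float(np.exp(theta[-2]))
        self.sigma = float(np.exp(theta[-1]))
        self.llf = float(llf)
        self.nparams = len(theta)
        self.aic = 2.0 * self.nparams - 2.0 * self.llf
        self.converged = bool(optres.success or optres.status in (0, 2))
        self.singular_re = self.sigma < 1e-4

    def coefficients(self, level=0.95) -> pd.DataFrame:
        return _coef_frame(self.params, self.bse, self.model.names, level)


def individual_design(trials: pd.DataFrame, colonies: pd.DataFrame,
                      response="total", habitat_subset="all",
                      traits=INDIVIDUAL_TRAITS) -> pd.DataFrame:
    """One row per (individual, trial series) with the colony's production.

    The colony-level count is duplicated across the colony's rows; the
    traits are the standardized trial values of that series.
    """
    tz = trials if "z_value" in trials.columns else transform_and_standardize(trials)
    wide = tz.pivot_table(index=["colony_id", "habitat", "individual_id",
                                 "repeat_index"],
                          columns="assay", values="z_value").reset_index()
    wide = wide.dropna(subset=list(traits))
    merged = wide.merge(colonies[["colony_id", RESPONSE_COLUMNS[response]]],
                        on="colony_id")
    if habitat_subset != "all":
        merged = merged[merged["habitat"] == habitat_subset]
    return merged.reset_index(drop=True)


class IndividualProductionModel:
    """Individual-level production regression with an individual random
    intercept (NB-GLMM, Gaussian LMM fallback)."""

    def __init__(self, trials, colonies, response="total", habitat_subset="all",
                 traits=INDIVIDUAL_TRAITS):
        self.design = individual_design(trials, colonies, response,
                                        habitat_subset, traits)
        if self.design["individual_id"].nunique() < 2:
            raise ValueError("need >= 2 individuals")
        self.response = response
        self.habitat_subset = habitat_subset
        self.traits = list(traits)
        self.y = self.design[RESPONSE_COLUMNS[response]].to_numpy(float)
        _check_males_support(self.y, response)

    def _fit_nb(self, terms):
        exog = sm.add_constant(self.design[list(terms)].to_numpy(float),
                               prepend=True)
        model = NegativeBinomialMixedModel(self.y, exog,
                                           self.design["individual_id"],
                                           names=["intercept"] + list(terms))
        return model.fit()

    def _fit_gaussian(self, terms):
        d = self.design.assign(_y=self.y)
        fe = "_y ~ " + " + ".join(terms) if terms else "_y ~ 1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM.from_formula(fe, groups="individual_id", data=d
                                          ).fit(reml=False, method="lbfgs")
        return res

    def fit(self, family="auto", selection: str | None = None) -> ProductivityFit:
        terms = list(self.traits)
        path = None
        if selection:
            terms, path = select_by_information_criterion(
                self._aic_for_terms, self.traits, strategy=selection,
                n_obs=len(self.y))
        notes = []
        if family in ("auto", "negative_binomial"):
            try:
                res = self._fit_nb(terms)
                if res.converged and np.all(np.isfinite(res.bse)):
                    coef = res.coefficients()
                    if res.singular_re:
                        notes.append("individual random-effect variance is "
                                     "effectively zero (singular fit)")
                    return ProductivityFit(self.response, "individual",
                                           self.habitat_subset,
                                           "negative_binomial", coef,
                                           dispersion=1.0 / res.alpha,
                                           sigma_individual=res.sigma,
                                           llf=res.llf, aic=res.aic,
                                           selection_path=path, notes=notes)
                notes.append("NB-GLMM failed to converge; Gaussian LMM fallback")
            except (RuntimeError, np.linalg.LinAlgError) as err:
                if family == "negative_binomial":
                    raise
                notes.append(f"NB-GLMM failed ({err}); Gaussian LMM fallback")
        res = self._fit_gaussian(terms)
        params = np.asarray(res.fe_params, dtype=float)
        se = np.asarray(res.bse_fe, dtype=float)
        names = ["intercept"] + list(terms)
        coef = _coef_frame(params, se, names)
        sigma_ind = float(np.sqrt(max(float(res.cov_re.iloc[0, 0]), 0.0)))
        return ProductivityFit(self.response, "individual", self.habitat_subset,
                               "gaussian", coef, sigma_individual=sigma_ind,
                               llf=float(res.llf), aic=float(res.aic),
                               selection_path=path, notes=notes)

    def _aic_for_terms(self, terms):
        try:
            res = self._fit_nb(terms)
            return float(res.aic), res.nparams
        except (RuntimeError, np.linalg.LinAlgError):
            res = self._fit_gaussian(terms)
            return float(res.aic), len(terms) + 3


def fit_colony_production_model(colonies, trials, response="total",
                                selection=None) -> ProductivityFit:
    return ColonyProductionModel(colonies, trials, response).fit(selection)


def fit_individual_production_model(trials, colonies, response="total",
                                    habitat_subset="all", family="auto",
                                    selection=None) -> ProductivityFit:
    return IndividualProductionModel(trials, colonies, response,
                                     habitat_subset).fit(family, selection)
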