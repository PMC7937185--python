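"""Double-hierarchical Gaussian mixed model (DHGLM) fitted by MCMC.

The model pairs two submodels.  For trial *i* on individual *j* in colony
*k*:

mean:        y_i = x_i' beta + u_j + v_k + eps_i
dispersion:  log SD(eps_i) = w_i' gamma + s_j

with v_k ~ N(0, sigma2_colony) and the individual intercepts jointly

    (u_j, s_j) ~ MVN(0, Omega),
    Omega = [[sigma2_id_mu, cov], [cov, sigma2_id_sigma]].

u_j is the individual's behavioural type (deviation of its mean), s_j its
residual intraindividual variability (rIIV) on the log-SD scale, and the
correlation cov / sqrt(sigma2_id_mu * sigma2_id_sigma) measures whether
behavioural type predicts predictability.

Fixed effects: the mean submodel takes worker size, colony size (log
scale), conspecific and allospecific nest densities, habitat (0 =
seminatural, 1 = invaded) and the within-assay repeat number; the
dispersion submodel takes the same covariates minus the repeat term.  A
colony-level variant (for nest displacement, three repeats per colony)
replaces the individual intercepts with colony intercepts on both
submodels and drops the separate colony term; its "residual" is then the
within-colony variation.

Sampling is Metropolis-within-Gibbs: beta, v and u have closed-form
Gaussian full conditionals; s, gamma, the Omega parameters (SDs plus
correlation) and the colony SD use adaptive random-walk Metropolis steps
tuned during burn-in.  Priors: Normal(0, 10^2) on beta and gamma,
half-Normal(0, 1) on every random-effect SD, Uniform(-1, 1) on the Omega
correlation — diffuse relative to signal on standardised data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    Standardizer,
    log_transform,
    transform_and_standardize,
    validate_trials,
)

_PRIOR_BETA_VAR = 100.0
_VAR_FLOOR = 1e-10


class DiagnosticsError(RuntimeError):
    """Posterior summaries requested before convergence diagnostics pass."""


MEAN_TERMS = ("intercept", "worker_size", "colony_size", "myrmica_nests",
              "allo_nests", "habitat", "repeat_index")
DISP_TERMS = MEAN_TERMS[:-1]


def _check_standardized(name: str, x: np.ndarray) -> None:
    if abs(float(np.mean(x))) > 0.01 or abs(float(np.std(x)) - 1.0) > 0.01:
        raise ValueError(
            f"covariate {name!r} is not standardized (mean 0, SD 1 required)"
        )


def build_design(trials: pd.DataFrame, colonies: pd.DataFrame,
                 trait: str) -> pd.DataFrame:
    """Assemble the standardized trial-level design for one trait.

    Joins colony covariates onto the trait's trials, log-transforms and
    z-scores the response, z-scores the continuous covariates (colony size
    on the log scale) over the analysis rows, and codes habitat 0/1.
    """
    sub = trials[trials["assay"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no trials for trait {trait!r}")
    if "z_value" not in sub.columns:
        sub = transform_and_standardize(sub)
    cols = colonies.set_index("colony_id")
    sub["colony_size_raw"] = cols["colony_size"].reindex(sub["colony_id"]).to_numpy()
    sub["myrmica_raw"] = cols["myrmica_nests"].reindex(sub["colony_id"]).to_numpy()
    sub["allo_raw"] = cols["allo_nests"].reindex(sub["colony_id"]).to_numpy()
    if "worker_size" not in sub.columns:
        sub["worker_size"] = cols["mean_worker_size"].reindex(sub["colony_id"]).to_numpy()
    std = Standardizer()
    out = pd.DataFrame({
        "colony_id": sub["colony_id"].to_numpy(),
        "individual_id": sub["individual_id"].to_numpy(),
        "repeat_raw": sub["repeat_index"].to_numpy(),
        "y": sub["z_value"].to_numpy(),
        "worker_size": std.fit_apply("worker_size", sub["worker_size"]),
        "colony_size": std.fit_apply("colony_size", np.log(sub["colony_size_raw"])),
        "myrmica_nests": std.fit_apply("myrmica_nests", sub["myrmica_raw"]),
        "allo_nests": std.fit_apply("allo_nests", sub["allo_raw"]),
        "habitat": (sub["habitat"] == "invaded").to_numpy(float),
        "repeat_index": std.fit_apply("repeat_index", sub["repeat_index"]),
    })
    return out.sort_values(["colony_id", "individual_id", "repeat_raw"],
                           kind="mergesort").reset_index(drop=True)


@dataclass
class McmcSettings:
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def validate(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains required")
        return self


class DHGLM:
    """Double-hierarchical Gaussian model for one behavioural trait.

    Parameters
    ----------
    y : standardized response, one entry per trial.
    exog_mean, exog_disp : design matrices (including intercept column)
        for the mean and log-residual-SD submodels; continuous columns
        must be standardized.
    groups : labels of the unit carrying the paired location/dispersion
        intercepts (individuals, or colonies in the colony-level variant).
    colony : optional labels for the extra colony intercept in the mean
        submodel (omit for the colony-level variant).
    """

    def __init__(self, y, exog_mean, exog_disp, groups, colony=None,
                 mean_names=None, disp_names=None):
        self.y = np.asarray(y, dtype=float)
        self.Xm = np.asarray(exog_mean, dtype=float)
        self.Xd = np.asarray(exog_disp, dtype=float)
        n = len(self.y)
        if self.Xm.shape[0] != n or self.Xd.shape[0] != n:
            raise ValueError("design row mismatch")
        for mat, names in ((self.Xm, mean_names), (self.Xd, disp_names)):
            for p in range(mat.shape[1]):
                col = mat[:, p]
                uniq = np.unique(col)
                if len(uniq) <= 2:   # intercept / binary factor
                    continue
                _check_standardized(names[p] if names else f"column {p}", col)
        if np.linalg.matrix_rank(self.Xm) < self.Xm.shape[1]:
            raise ValueError("singular mean design")
        self.group_labels, self.g = np.unique(groups, return_inverse=True)
        counts = np.bincount(self.g)
        if counts.min() < 2:
            raise ValueError("every group needs >= 2 repeats for the dispersion submodel")
        if colony is not None:
            self.colony_labels, self.c = np.unique(colony, return_inverse=True)
        else:
            self.colony_labels, self.c = None, None
        self.mean_names = list(mean_names) if mean_names else [
            f"beta{p}" for p in range(self.Xm.shape[1])]
        self.disp_names = list(disp_names) if disp_names else [
            f"gamma{p}" for p in range(self.Xd.shape[1])]

    # ------------------------------------------------------------------
    @classmethod
    def from_tables(cls, trials, colonies, trait,
                    grouping="individual_within_colony"):
        """Build the model from the interchange tables for one trait."""
        validate_trials(trials)
        d = build_design(trials, colonies, trait)
        Xm = np.column_stack([np.ones(len(d))] + [d[t].to_numpy() for t in MEAN_TERMS[1:]])
        Xd = Xm[:, :-1]
        if grouping == "individual_within_colony":
            return cls(d["y"], Xm, Xd, d["individual_id"], colony=d["colony_id"],
                       mean_names=MEAN_TERMS, disp_names=DISP_TERMS)
        if grouping == "colony_only":
            return cls(d["y"], Xm, Xd, d["colony_id"], colony=None,
                       mean_names=MEAN_TERMS, disp_names=DISP_TERMS)
        raise ValueError(f"unknown grouping {grouping!r}")

    @classmethod
    def from_displacement(cls, colonies):
        """Colony-level variant for the three nest-displacement repeats."""
        rows = []
        for r in (1, 2, 3):
            rows.append(pd.DataFrame({
                "colony_id": colonies["colony_id"],
                "habitat": colonies["habitat"],
                "repeat_index": r,
                "time": colonies[f"displacement_{r}"],
                "worker_size_raw": colonies["mean_worker_size"],
                "colony_size_raw": colonies["colony_size"],
                "myrmica_raw": colonies["myrmica_nests"],
                "allo_raw": colonies["allo_nests"],
            }))
        d = pd.concat(rows, ignore_index=True).sort_values(
            ["colony_id", "repeat_index"], kind="mergesort").reset_index(drop=True)
        std = Standardizer()
        y = std.fit_apply("displacement", log_transform(d["time"], "displacement"))
        cov = {
            "worker_size": std.fit_apply("worker_size", d["worker_size_raw"]),
            "colony_size": std.fit_apply("colony_size", np.log(d["colony_size_raw"])),
            "myrmica_nests": std.fit_apply("myrmica_nests", d["myrmica_raw"]),
            "allo_nests": std.fit_apply("allo_nests", d["allo_raw"]),
            "habitat": (d["habitat"] == "invaded").to_numpy(float),
            "repeat_index": std.fit_apply("repeat_index", d["repeat_index"]),
        }
        Xm = np.column_stack([np.ones(len(d))] + [cov[t] for t in MEAN_TERMS[1:]])
        return cls(y, Xm, Xm[:, :-1], d["colony_id"], colony=None,
                   mean_names=MEAN_TERMS, disp_names=DISP_TERMS)

    # ------------------------------------------------------------------
    def fit(self, chains=4, iterations=10_000, burn_in=5_000, thin=5, seed=0,
            progress=False) -> "DHGLMResults":
        settings = McmcSettings(chains, iterations, burn_in, thin, seed).validate()
        stores = []
        root = np.random.SeedSequence(int(seed) % 2**31)
        for chain, ss in enumerate(root.spawn(settings.chains)):
            rng = np.random.default_rng(ss)
            stores.append(self._run_chain(settings, rng))
        samples = {k: np.stack([s[k] for s in stores]) for k in stores[0]}
        return DHGLMResults(self, samples, settings)

    # ------------------------------------------------------------------
    def _run_chain(self, settings: McmcSettings, rng) -> dict:
        y, Xm, Xd = self.y, self.Xm, self.Xd
        g, c = self.g, self.c
        n = len(y)
        pm, pd_ = Xm.shape[1], Xd.shape[1]
        n_g = len(self.group_labels)
        n_c = len(self.colony_labels) if c is not None else 0
        counts_g = np.bincount(g).astype(float)

        # initial values from least squares
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid0 = y - Xm @ beta
        gamma = np.zeros(pd_)
        gamma[0] = np.log(max(resid0.std() * 0.8, 1e-3))
        u = np.zeros(n_g)
        s = np.zeros(n_g)
        v = np.zeros(n_c) if c is not None else None
        sd_u, sd_s, rho = max(resid0.std() * 0.5, 0.05), 0.3, 0.0
        sd_c = max(resid0.std() * 0.3, 0.05) if c is not None else 0.0

        # adaptive step sizes
        step_s = np.full(n_g, 0.4)
        step_gamma = np.full(pd_, 0.1)
        step_omega = np.array([0.2, 0.2, 0.2])   # log sd_u, log sd_s, rho
        step_sdc = 0.2
        acc_s = np.zeros(n_g)
        acc_gamma = np.zeros(pd_)
        acc_omega = np.zeros(3)
        acc_sdc = 0.0
        adapt_every = 50

        keep = (settings.iterations - settings.burn_in) // settings.thin
        out = {k: np.empty(keep) for k in
               [f"beta_{t}" for t in self.mean_names] +
               [f"gamma_{t}" for t in self.disp_names] +
               ["sigma2_id_mu", "sigma2_id_sigma", "cov_mu_sigma",
                "r_int_riiv", "sigma2_colony"]}
        kept = 0

        eta_d = Xd @ gamma            # dispersion linear predictor (no s)
        eye_m = np.eye(pm) / _PRIOR_BETA_VAR

        for it in range(settings.iterations):
            log_sd_row = eta_d + s[g]
            tau = np.exp(-2.0 * log_sd_row)

            # --- beta (Gaussian full conditional) -----------------------
            r = y - u[g] - (v[c] if c is not None else 0.0)
            Xt = Xm * tau[:, None]
            A = Xm.T @ Xt + eye_m
            b = Xt.T @ r
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, b))
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(pm))
            fixed = Xm @ beta

            # --- colony intercepts -------------------------------------
            if c is not None:
                e = y - fixed - u[g]
                prec = np.bincount(c, tau, minlength=n_c) + 1.0 / max(sd_c**2, _VAR_FLOOR)
                m_v = np.bincount(c, tau * e, minlength=n_c) / prec
                v = m_v + rng.standard_normal(n_c) / np.sqrt(prec)

            # --- individual mean intercepts u ---------------------------
            e = y - fixed - (v[c] if c is not None else 0.0)
            var_u_cond = max(sd_u**2 * (1 - rho**2), _VAR_FLOOR)
            mu_u_cond = rho * sd_u / max(sd_s, 1e-8) * s
            prec = np.bincount(g, tau, minlength=n_g) + 1.0 / var_u_cond
            m_u = (np.bincount(g, tau * e, minlength=n_g) + mu_u_cond / var_u_cond) / prec
            u = m_u + rng.standard_normal(n_g) / np.sqrt(prec)

            # --- individual dispersion intercepts s (vectorised MH) -----
            e2 = (e - u[g]) ** 2
            base = np.exp(-2.0 * eta_d)
            A_g = np.bincount(g, e2 * base, minlength=n_g)
            var_s_cond = max(sd_s**2 * (1 - rho**2), _VAR_FLOOR)
            mu_s_cond = rho * sd_s / max(sd_u, 1e-8) * u
            prop = s + step_s * rng.standard_normal(n_g)

            def s_logpost(sv):
                return (-counts_g * sv - 0.5 * np.exp(-2.0 * sv) * A_g
                        - 0.5 * (sv - mu_s_cond) ** 2 / var_s_cond)

            logr = s_logpost(prop) - s_logpost(s)
            accept = np.log(rng.uniform(size=n_g)) < logr
            s = np.where(accept, prop, s)
            acc_s += accept

            # --- gamma (componentwise MH) -------------------------------
            e2_all = e2  # residual squares unchanged within this block
            for p in range(pd_):
                gp = gamma[p] + step_gamma[p] * rng.standard_normal()
                eta_new = eta_d + Xd[:, p] * (gp - gamma[p])
                ll_new = (-np.sum(eta_new)
                          - 0.5 * np.sum(e2_all * np.exp(-2.0 * (eta_new + s[g])))
                          - 0.5 * gp**2 / _PRIOR_BETA_VAR)
                ll_old = (-np.sum(eta_d)
                          - 0.5 * np.sum(e2_all * np.exp(-2.0 * (eta_d + s[g])))
                          - 0.5 * gamma[p] ** 2 / _PRIOR_BETA_VAR)
                if np.log(rng.uniform()) < ll_new - ll_old:
                    gamma[p] = gp
                    eta_d = eta_new
                    acc_gamma[p] += 1

            # --- Omega: (log sd_u, log sd_s, rho) via MH ----------------
            def omega_logpost(lsu, lss, rh):
                if abs(rh) >= 1.0:
                    return -np.inf
                su, ssd = np.exp(lsu), np.exp(lss)
                det = su**2 * ssd**2 * (1 - rh**2)
                if det <= 0:
                    return -np.inf
                q = (u**2 / su**2 - 2 * rh * u * s / (su * ssd) + s**2 / ssd**2) / (1 - rh**2)
                ll = -0.5 * n_g * np.log(det) - 0.5 * np.sum(q)
                # half-Normal(0,1) prior on the SDs + log-scale Jacobian
                ll += -0.5 * su**2 + lsu - 0.5 * ssd**2 + lss
                return ll

            state = np.array([np.log(max(sd_u, 1e-8)), np.log(max(sd_s, 1e-8)), rho])
            for p in range(3):
                cand = state.copy()
                cand[p] += step_omega[p] * rng.standard_normal()
                if np.log(rng.uniform()) < (omega_logpost(*cand) - omega_logpost(*state)):
                    state = cand
                    acc_omega[p] += 1
            sd_u, sd_s, rho = np.exp(state[0]), np.exp(state[1]), state[2]

            # --- colony SD ---------------------------------------------
            if c is not None:
                def sdc_logpost(lsc):
                    sc = np.exp(lsc)
                    return (-n_c * lsc - 0.5 * np.sum(v**2) / sc**2
                            - 0.5 * sc**2 + lsc)
                lsc = np.log(max(sd_c, 1e-8))
                cand = lsc + step_sdc * rng.standard_normal()
                if np.log(rng.uniform()) < sdc_logpost(cand) - sdc_logpost(lsc):
                    lsc = cand
                    acc_sdc += 1
                sd_c = np.exp(lsc)

            # --- adaptation during burn-in ------------------------------
            if it < settings.burn_in and (it + 1) % adapt_every == 0:
                target = 0.44
                step_s *= np.exp(np.clip(acc_s / adapt_every - target, -0.5, 0.5))
                step_gamma *= np.exp(np.clip(acc_gamma / adapt_every - target, -0.5, 0.5))
                step_omega *= np.exp(np.clip(acc_omega / adapt_every - target, -0.5, 0.5))
                step_sdc *= np.exp(np.clip(acc_sdc / adapt_every - target, -0.5, 0.5))
                acc_s[:] = 0; acc_gamma[:] = 0; acc_omega[:] = 0; acc_sdc = 0.0

            # --- store --------------------------------------------------
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                if kept < keep:
                    for p, t in enumerate(self.mean_names):
                        out[f"beta_{t}"][kept] = beta[p]
                    for p, t in enumerate(self.disp_names):
                        out[f"gamma_{t}"][kept] = gamma[p]
                    out["sigma2_id_mu"][kept] = sd_u**2
                    out["sigma2_id_sigma"][kept] = sd_s**2
                    out["cov_mu_sigma"][kept] = rho * sd_u * sd_s
                    out["r_int_riiv"][kept] = rho
                    out["sigma2_colony"][kept] = sd_c**2 if c is not None else np.nan
                    kept += 1
        return out


# ---------------------------------------------------------------------------


def _split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat over an array of shape (chains, draws)."""
    m, n = draws.shape
    half = n // 2
    if half < 2:
        return np.nan
    splits = np.concatenate([draws[:, :half], draws[:, half:2 * half]], axis=0)
    w = splits.var(axis=1, ddof=1).mean()
    b = half * splits.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf   # stuck chains that disagree
    return float(np.sqrt((half - 1) / half + b / (w * half)))


def _ess(draws: np.ndarray) -> float:
    """Effective sample size via initial-monotone autocorrelation sums."""
    m, n = draws.shape
    if n < 4:
        return float(m * n)
    acsu = np.zeros(n)
    for row in draws:
        x = row - row.mean()
        f = np.fft.rfft(x, 2 * n)
        acf = np.fft.irfft(f * np.conj(f))[:n]
        if acf[0] <= 0:
            return float(m * n)
        acsu_row = acf / acf[0]
        acsu_row = acsu_row[: n]
        acsu = acsu + acsu_row
    acsu /= m
    # Geyer initial positive sequence
    rho_sum = 0.0
    t = 1
    while t + 1 < n:
        pair = acsu[t] + acsu[t + 1]
        if pair < 0:
            break
        rho_sum += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * rho_sum)
    return float(min(ess, m * n))


class DHGLMResults:
    """Posterior draws and summaries of a fitted DHGLM."""

    def __init__(self, model: DHGLM, samples: dict, settings: McmcSettings):
        self.model = model
        self.samples = samples          # name -> (chains, draws)
        self.settings = settings
        bad = np.array([(samples[k] < 0).any() for k in
                        ("sigma2_id_mu", "sigma2_id_sigma")])
        assert not bad.any(), "negative variance draw (sampler bug)"

    # -- accessors matching the model's vocabulary ----------------------
    def draws(self, name: str) -> np.ndarray:
        """Pooled posterior draws for one parameter (all chains)."""
        return self.samples[name].ravel()

    @property
    def beta_samples(self) -> pd.DataFrame:
        return pd.DataFrame({t: self.draws(f"beta_{t}") for t in self.model.mean_names})

    @property
    def gamma_samples(self) -> pd.DataFrame:
        return pd.DataFrame({t: self.draws(f"gamma_{t}") for t in self.model.disp_names})

    @property
    def r_int_riiv_samples(self) -> np.ndarray:
        return self.draws("r_int_riiv")

    # -- diagnostics -----------------------------------------------------
    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.samples.items():
            if np.isnan(arr).all():
                continue
            rows.append(dict(parameter=name, rhat=_split_rhat(arr), ess=_ess(arr)))
        return pd.DataFrame(rows)

    def diagnostics_ok(self, rhat_max=1.1, ess_min=200) -> bool:
        d = self.diagnostics()
        return bool((d["rhat"].fillna(1.0) <= rhat_max).all()
                    and (d["ess"] >= ess_min).all())

    # -- summaries -------------------------------------------------------
    def summary_frame(self, level: float = 0.95, force: bool = False,
                      variance_floor: float = 0.01) -> pd.DataFrame:
        """Posterior mean, equal-tailed credible interval and support flag.

        ``supported`` means the CrI excludes 0 (for variances: the lower
        bound exceeds ``variance_floor``).
        """
        if not force and not self.diagnostics_ok():
            d = self.diagnostics()
            bad = d[(d["rhat"] > 1.1) | (d["ess"] < 200)]["parameter"].tolist()
            warnings.warn(f"convergence diagnostics failed for {bad}", stacklevel=2)
            raise DiagnosticsError(
                f"split-Rhat > 1.1 or ESS < 200 for {bad}; rerun longer or pass force=True"
            )
        a = (1.0 - level) / 2.0
        rows = []
        for name, arr in self.samples.items():
            x = arr.ravel()
            if np.isnan(x).all():
                continue
            lo, hi = np.quantile(x, [a, 1.0 - a])
            is_var = name.startswith("sigma2")
            supported = lo > variance_floor if is_var else (lo > 0 or hi < 0)
            rows.append(dict(parameter=name, mean=float(x.mean()),
                             cri_low=float(lo), cri_high=float(hi),
                             supported=bool(supported)))
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self, level: float = 0.95, force: bool = False) -> str:
        df = self.summary_frame(level=level, force=force)
        lines = [f"DHGLM posterior summary ({int(level*100)}% CrI, "
                 f"{self.settings.chains} chains x "
                 f"{self.settings.iterations} iterations)"]
        for name, row in df.iterrows():
            star = " *" if row["supported"] else ""
            lines.append(f"  {name:28s} {row['mean']:8.3f} "
                         f"({row['cri_low']:.3f} to {row['cri_high']:.3f}){star}")
        lines.append("  * = 95% CrI excludes 0 (variances: lower bound > 0.01)")
        return "\n".join(lines)


def summarize_fit(results: DHGLMResults, level: float = 0.95,
                  force: bool = False) -> pd.DataFrame:
    """Module-level convenience wrapper over ``DHGLMResults.summary_frame``."""
    if not results.samples:
        raise ValueError("empty sample store")
    return results.summary_frame(level=level, force=force)


# ---------------------------------------------------------------------------
# homogeneous-variance likelihood-ratio tests for the random intercepts


def random_intercept_lrt(trials: pd.DataFrame, colonies: pd.DataFrame,
                         trait: str, term: str) -> tuple[float, float, float]:
    """LRT for dropping one random intercept from the Gaussian LMM.

    Fits the homogeneous-residual mixed model (individual and colony
    random intercepts) by ML via statsmodels, refits without ``term`` and
    returns ``(chi2, df, p)`` with the boundary-corrected p-value from the
    0.5*chi2_0 + 0.5*chi2_1 mixture.
    """
    import statsmodels.formula.api as smf

    if term not in ("individual", "colony"):
        raise ValueError(f"term {term!r} is not a random intercept of this model")
    d = build_design(trials, colonies, trait)
    fe = "y ~ worker_size + colony_size + myrmica_nests + allo_nests + habitat + repeat_index"

    def _fit(include_individual: bool, include_colony: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if include_individual and include_colony:
                m = smf.mixedlm(fe, d, groups=d["colony_id"], re_formula="1",
                                vc_formula={"individual": "0 + C(individual_id)"})
            elif include_colony:
                m = smf.mixedlm(fe, d, groups=d["colony_id"], re_formula="1")
            elif include_individual:
                m = smf.mixedlm(fe, d, groups=d["individual_id"], re_formula="1")
            else:
                raise ValueError("at least one random term required")
            res = None
            for method in ("lbfgs", "bfgs", "cg", "powell"):
                res = m.fit(reml=False, method=method, maxiter=500)
                if np.isfinite(res.llf):
                    break
        if res is None or not np.isfinite(res.llf):
            raise RuntimeError(f"LMM did not converge: {res.summary()}")
        return res

    full = _fit(True, True)
    if term == "individual":
        reduced = _fit(False, True)
    else:
        reduced = _fit(True, False)
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if chi2 == 0.0 else 0.5 * stats.chi2.sf(chi2, 1)
    return float(chi2), 1.0, float(p)


def lmm_limit_estimates(trials: pd.DataFrame, colonies: pd.DataFrame,
                        trait: str) -> pd.DataFrame:
    """ML LMM fixed-effect estimates for the homogeneous-variance limit.

    Independent cross-check for the DHGLM mean submodel: with no
    dispersion covariates and no rIIV variance, DHGLM posterior means of
    beta should agree with these ML estimates.
    """
    import statsmodels.formula.api as smf

    d = build_design(trials, colonies, trait)
    fe = "y ~ worker_size + colony_size + myrmica_nests + allo_nests + habitat + repeat_index"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = smf.mixedlm(fe, d, groups=d["colony_id"], re_formula="1",
                        vc_formula={"individual": "0 + C(individual_id)"})
        res = m.fit(reml=False, method="lbfgs", maxiter=500)
    out = pd.DataFrame({"estimate": res.fe_params, "se": res.bse_fe})
    out.index = ["intercept" if i == "Intercept" else i for i in out.index]
    return out
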