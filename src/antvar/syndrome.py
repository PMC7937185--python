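"""Multivariate mixed models and level-wise correlation decomposition.

Behavioural syndromes are among-unit correlations between distinct
traits.  With repeated measures on individuals nested in colonies, the
phenotypic covariance of a trait vector y splits into

    Sigma_P = Sigma_colony + Sigma_individual + Sigma_residual,

and the correlation computed from each component matrix is the syndrome
at that level: among colonies, among individuals within colonies, and
within individuals (residual).  The model fitted here is the Gaussian
multivariate mixed model

    y_i = mu + b * habitat_i + c_k(i) + u_j(i) + e_i,

with c ~ MVN(0, Sigma_colony), u ~ MVN(0, Sigma_individual) and
e ~ MVN(0, Sigma_residual), sampled by MCMC.  Random effects and fixed
effects have closed-form Gaussian updates (individual effects
hierarchically centred on their colony effect for good mixing);
covariance matrices use a separation-strategy parameterisation — SDs
with half-Normal(0, 1) priors and a correlation matrix uniform over the
positive-definite region — updated by adaptive Metropolis steps.  Every
stored covariance draw is symmetric positive definite by construction,
so per-draw correlations are bounded in [-1, 1] automatically.

Two model forms are supported: the four individual-level traits with
colony and individual random effects, and the five-trait form that adds
colony-level nest displacement with a colony random effect only, where
rows missing a trait (displacement on worker rows, worker traits on
displacement rows) are completed by conditional-normal data
augmentation.  In the five-trait form only the among-colony component is
interpretable — the residual mixes within-individual and within-colony
variation measured on different units — and its output is flagged so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import log_transform, Standardizer
from .dhglm import McmcSettings, _split_rhat, _ess


class _CovState:
    """Separation-strategy covariance block: Sigma = D R D.

    SDs carry half-Normal(0, 1) priors (log-scale random walk with
    Jacobian), the correlation matrix a flat prior over the positive-
    definite region (off-diagonal random walks; a failed Cholesky of the
    proposal rejects it).  Adaptive step sizes are tuned during burn-in.
    This parameterisation avoids the near-singularity spike of a
    small-scale inverse Wishart, which otherwise drags weakly identified
    level covariances toward |r| = 1.
    """

    def __init__(self, t: int, sd0: float = 0.5):
        self.sd = np.full(t, sd0)
        self.R = np.eye(t)
        self.pairs = [(i, j) for i in range(t) for j in range(i + 1, t)]
        self.step_sd = np.full(t, 0.3)
        self.step_r = np.full(len(self.pairs), 0.3)
        self.acc_sd = np.zeros(t)
        self.acc_r = np.zeros(len(self.pairs))

    @property
    def cov(self) -> np.ndarray:
        return self.R * np.outer(self.sd, self.sd)

    @staticmethod
    def _loglik(cov, gram, n):
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        inv = np.linalg.inv(cov)
        return -0.5 * n * logdet - 0.5 * float(np.sum(inv * gram))

    def update(self, gram, n, rng):
        """One MH sweep over SDs and correlations given effects' Gram matrix."""
        cur = self._loglik(self.cov, gram, n)
        for j in range(len(self.sd)):
            prop = self.sd[j] * np.exp(self.step_sd[j] * rng.standard_normal())
            sd_new = self.sd.copy()
            sd_new[j] = prop
            new = self._loglik(self.R * np.outer(sd_new, sd_new), gram, n)
            dlp = ((new - 0.5 * prop**2 + np.log(prop))
                   - (cur - 0.5 * self.sd[j]**2 + np.log(self.sd[j])))
            if np.log(rng.uniform()) < dlp:
                self.sd = sd_new
                cur = new
                self.acc_sd[j] += 1
        for idx, (i, j) in enumerate(self.pairs):
            prop = self.R[i, j] + self.step_r[idx] * rng.standard_normal()
            if abs(prop) >= 1.0:
                continue
            r_new = self.R.copy()
            r_new[i, j] = r_new[j, i] = prop
            new = self._loglik(r_new * np.outer(self.sd, self.sd), gram, n)
            if np.log(rng.uniform()) < new - cur:
                self.R = r_new
                cur = new
                self.acc_r[idx] += 1

    def adapt(self, window: int, target: float = 0.44):
        self.step_sd *= np.exp(np.clip(self.acc_sd / window - target, -0.5, 0.5))
        self.step_r *= np.exp(np.clip(self.acc_r / window - target, -0.5, 0.5))
        self.acc_sd[:] = 0
        self.acc_r[:] = 0


def _group_sums(idx: np.ndarray, mat: np.ndarray, n_groups: int) -> np.ndarray:
    out = np.empty((n_groups, mat.shape[1]))
    for t in range(mat.shape[1]):
        out[:, t] = np.bincount(idx, mat[:, t], minlength=n_groups)
    return out


def _draw_effects(rng, sums, counts, r_prec, level_prec, prior_mean=None):
    """Gaussian full-conditional draws of per-group random effect vectors.

    ``sums`` holds per-group residual sums, ``prior_mean`` the per-group
    prior means (hierarchical centring).  Groups sharing a count share the
    posterior covariance, so the solve is batched per unique count.
    """
    n_g, t = sums.shape
    eff = np.empty((n_g, t))
    for cnt in np.unique(counts):
        mask = counts == cnt
        prec = cnt * r_prec + level_prec
        cov = np.linalg.inv(prec)
        chol = np.linalg.cholesky(cov)
        b = sums[mask] @ r_prec.T
        if prior_mean is not None:
            b = b + prior_mean[mask] @ level_prec.T
        mean = b @ cov.T
        eff[mask] = mean + rng.standard_normal((mask.sum(), t)) @ chol.T
    return eff


@dataclass
class LevelCorrelations:
    """Posterior summary of one level's trait-trait correlation matrix."""

    level: str
    traits: tuple
    matrix: np.ndarray          # posterior means
    cri_low: np.ndarray
    cri_high: np.ndarray
    supported: np.ndarray       # CrI excludes 0
    interpretable: bool = True

    def pair(self, a: str, b: str) -> dict:
        i, j = self.traits.index(a), self.traits.index(b)
        return dict(r=float(self.matrix[i, j]),
                    cri=(float(self.cri_low[i, j]), float(self.cri_high[i, j])),
                    supported=bool(self.supported[i, j]))


def decompose_correlations(cov_draws: np.ndarray, traits, level: str,
                           level_name_interpretable: bool = True,
                           level_prob: float = 0.95) -> LevelCorrelations:
    """Turn covariance-matrix draws into correlation summaries.

    Per draw, r_ab = cov_ab / sqrt(var_a * var_b); zero-variance draws are
    dropped (their count is recorded in the result's ``n_dropped``).
    Summaries are posterior means with equal-tailed credible intervals.
    """
    draws = np.asarray(cov_draws, dtype=float)
    var = np.diagonal(draws, axis1=1, axis2=2)
    ok = (var > 0).all(axis=1)
    n_dropped = int((~ok).sum())
    draws = draws[ok]
    if len(draws) == 0:
        raise ValueError("no usable covariance draws (all had a zero variance)")
    sd = np.sqrt(np.diagonal(draws, axis1=1, axis2=2))
    corr = draws / sd[:, :, None] / sd[:, None, :]
    a = (1.0 - level_prob) / 2.0
    lo = np.quantile(corr, a, axis=0)
    hi = np.quantile(corr, 1.0 - a, axis=0)
    supported = (lo > 0) | (hi < 0)
    np.fill_diagonal(supported, False)
    out = LevelCorrelations(level=level, traits=tuple(traits),
                            matrix=corr.mean(axis=0), cri_low=lo, cri_high=hi,
                            supported=supported,
                            interpretable=level_name_interpretable)
    out.n_dropped = n_dropped
    return out


def fixed_effect_pmcmc(draws: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """Posterior mean, 95% CrI and the two-tailed sign probability pMCMC.

    pMCMC = 2 * min(P(draw > 0), P(draw < 0)), capped at 1, with the
    (1 + count) / (1 + n) finite-sample floor so an all-positive sample
    yields a small but nonzero value.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("empty draw vector")
    n = len(x)
    p_pos = (1 + np.sum(x > 0)) / (1 + n)
    p_neg = (1 + np.sum(x < 0)) / (1 + n)
    p = min(1.0, 2.0 * min(p_pos, p_neg))
    lo, hi = np.quantile(x, [0.025, 0.975])
    return float(x.mean()), (float(lo), float(hi)), float(p)


class MultiTraitModel:
    """Multivariate Gaussian mixed model over standardized trait values.

    Parameters
    ----------
    endog : (n, T) response matrix; NaN marks a trait unobserved on that
        row (five-trait form only).
    habitat : 0/1 per row.
    colony, individual : group labels; pass ``individual=None`` for the
        colony-only form.
    """

    def __init__(self, endog, habitat, colony, individual=None, traits=None):
        self.Y = np.asarray(endog, dtype=float)
        n, t = self.Y.shape
        if t < 2:
            raise ValueError("at least 2 traits required")
        self.traits = tuple(traits) if traits else tuple(f"trait{i}" for i in range(t))
        self.habitat = np.asarray(habitat, dtype=float)
        self.col_labels, self.col = np.unique(colony, return_inverse=True)
        if individual is not None:
            self.ind_labels, self.ind = np.unique(individual, return_inverse=True)
            if np.isnan(self.Y).any():
                raise ValueError(
                    "unbalanced trait availability: some rows miss a trait; "
                    "run filter_complete_cases first"
                )
        else:
            self.ind_labels, self.ind = None, None
        self.missing = np.isnan(self.Y)
        # fixed missingness patterns, computed once
        self._patterns = []
        if self.missing.any():
            for key in np.unique(self.missing, axis=0):
                if key.any():
                    rows = (self.missing == key).all(axis=1)
                    self._patterns.append((key.copy(), rows))

    # ------------------------------------------------------------------
    @classmethod
    def from_trials(cls, trials, traits=("activity", "meandering",
                                         "exploration", "aggression")):
        """Four-trait form: one row per (individual, repeat), colony and
        individual random effects."""
        if len(traits) < 2:
            raise ValueError("at least 2 traits required")
        sub = trials[trials["assay"].isin(traits)]
        counts = sub.groupby(["individual_id", "assay"]).size().unstack(fill_value=0)
        counts = counts.reindex(columns=list(traits), fill_value=0)
        if counts.nunique().max() > 1 or (counts == 0).any().any():
            raise ValueError(
                "unbalanced trait availability across individuals; "
                "run filter_complete_cases first"
            )
        wide = sub.pivot_table(index=["colony_id", "individual_id", "habitat",
                                      "repeat_index"],
                               columns="assay", values="z_value").reset_index()
        y = wide[list(traits)].to_numpy(dtype=float)
        return cls(y, (wide["habitat"] == "invaded").to_numpy(float),
                   wide["colony_id"], wide["individual_id"], traits=traits)

    @classmethod
    def from_trials_and_displacement(cls, trials, colonies,
                                     traits=("activity", "meandering",
                                             "exploration", "aggression")):
        """Five-trait form: adds repeat-level nest displacement with a
        colony random effect only; unobserved cells are NaN."""
        sub = trials[trials["assay"].isin(traits)]
        wide = sub.pivot_table(index=["colony_id", "habitat", "individual_id",
                                      "repeat_index"],
                               columns="assay", values="z_value").reset_index()
        wide["displacement"] = np.nan
        std = Standardizer()
        disp_long = []
        all_times = np.concatenate([
            colonies[f"displacement_{r}"].to_numpy(float) for r in (1, 2, 3)])
        std.fit("displacement", log_transform(all_times, "displacement"))
        for r in (1, 2, 3):
            z = std.apply("displacement",
                          log_transform(colonies[f"displacement_{r}"], "displacement"))
            d = pd.DataFrame({"colony_id": colonies["colony_id"],
                              "habitat": colonies["habitat"],
                              "individual_id": "_colony_", "repeat_index": r,
                              "displacement": z})
            disp_long.append(d)
        disp = pd.concat(disp_long, ignore_index=True)
        for t in traits:
            disp[t] = np.nan
        full = pd.concat([wide, disp], ignore_index=True)
        all_traits = tuple(traits) + ("displacement",)
        y = full[list(all_traits)].to_numpy(dtype=float)
        return cls(y, (full["habitat"] == "invaded").to_numpy(float),
                   full["colony_id"], individual=None, traits=all_traits)

    # ------------------------------------------------------------------
    def fit(self, chains=2, iterations=4000, burn_in=1000, thin=2,
            seed=0) -> "MultiTraitResults":
        settings = McmcSettings(chains, iterations, burn_in, thin, seed).validate()
        stores = []
        root = np.random.SeedSequence(int(seed) % 2**31)
        for ss in root.spawn(settings.chains):
            stores.append(self._run_chain(settings, np.random.default_rng(ss)))
        merged = {}
        for key in stores[0]:
            merged[key] = np.stack([s[key] for s in stores])
        return MultiTraitResults(self, merged, settings)

    def _run_chain(self, settings, rng):
        y = self.Y.copy()
        n, t = y.shape
        miss = self.missing
        col, ind = self.col, self.ind
        n_col = len(self.col_labels)
        n_ind = len(self.ind_labels) if ind is not None else 0
        counts_col = np.bincount(col, minlength=n_col)
        counts_ind = np.bincount(ind, minlength=n_ind) if ind is not None else None
        if ind is not None:
            # colony of each individual and individuals-per-colony counts
            col_of_ind = np.zeros(n_ind, dtype=int)
            col_of_ind[ind] = col
            ind_per_col = np.bincount(col_of_ind, minlength=n_col)
        hab = self.habitat
        n_hab = float((hab**2).sum())

        # impute starting values for missing cells with trait means
        if miss.any():
            mu0 = np.nanmean(y, axis=0)
            for j in range(t):
                y[miss[:, j], j] = mu0[j]

        alpha = np.nanmean(self.Y, axis=0)
        alpha = np.where(np.isfinite(alpha), alpha, 0.0)
        bhab = np.zeros(t)
        c_eff = np.zeros((n_col, t))
        # hierarchically centred: w_j = c_k(j) + u_j is the individual's
        # total effect; it decouples colony effects from the colony means
        # of the individual effects and mixes far better than the
        # uncentred parameterisation
        w_eff = np.zeros((n_ind, t)) if ind is not None else None
        cs_c = _CovState(t, 0.5)
        cs_i = _CovState(t, 0.5) if ind is not None else None
        cs_r = _CovState(t, max(float(np.nanstd(self.Y)), 0.2))
        prior_prec_fe = 1.0 / 100.0
        adapt_every = 50

        keep = (settings.iterations - settings.burn_in) // settings.thin
        out = {
            "cov_colony": np.empty((keep, t, t)),
            "cov_residual": np.empty((keep, t, t)),
            "alpha": np.empty((keep, t)),
            "habitat_effect": np.empty((keep, t)),
        }
        if ind is not None:
            out["cov_individual"] = np.empty((keep, t, t))
        kept = 0

        for it in range(settings.iterations):
            s_r = cs_r.cov
            r_prec = np.linalg.inv(s_r)

            # --- impute missing responses -------------------------------
            if miss.any():
                if ind is not None:
                    mean_row = alpha + np.outer(hab, bhab) + w_eff[ind]
                else:
                    mean_row = alpha + np.outer(hab, bhab) + c_eff[col]
                for mi, rows in self._patterns:
                    oi = ~mi
                    if oi.any():
                        s_oo = s_r[np.ix_(oi, oi)]
                        s_mo = s_r[np.ix_(mi, oi)]
                        gain = s_mo @ np.linalg.inv(s_oo)
                        cond_cov = s_r[np.ix_(mi, mi)] - gain @ s_mo.T
                        resid_obs = (self.Y[np.ix_(rows, oi)]
                                     - mean_row[np.ix_(rows, oi)])
                        cond_mean = mean_row[np.ix_(rows, mi)] + resid_obs @ gain.T
                    else:
                        cond_mean = mean_row[np.ix_(rows, mi)]
                        cond_cov = s_r[np.ix_(mi, mi)]
                    chol = np.linalg.cholesky(cond_cov)
                    draw = cond_mean + rng.standard_normal(cond_mean.shape) @ chol.T
                    block = y[rows]
                    block[:, mi] = draw
                    y[rows] = block

            # --- fixed effects ------------------------------------------
            e = y - (w_eff[ind] if ind is not None else c_eff[col])
            resid = e - np.outer(hab, bhab)
            prec = n * r_prec + np.eye(t) * prior_prec_fe
            cov_a = np.linalg.inv(prec)
            mean_a = cov_a @ r_prec @ resid.sum(axis=0)
            alpha = mean_a + np.linalg.cholesky(cov_a) @ rng.standard_normal(t)

            resid = e - alpha
            prec = n_hab * r_prec + np.eye(t) * prior_prec_fe
            cov_b = np.linalg.inv(prec)
            mean_b = cov_b @ r_prec @ (resid * hab[:, None]).sum(axis=0)
            bhab = mean_b + np.linalg.cholesky(cov_b) @ rng.standard_normal(t)

            fixed = alpha + np.outer(hab, bhab)

            if ind is not None:
                # --- total individual effects w_j | c (centred) ---------
                e = y - fixed
                sums = _group_sums(ind, e, n_ind)
                i_prec = np.linalg.inv(cs_i.cov)
                w_eff = _draw_effects(rng, sums, counts_ind, r_prec, i_prec,
                                      prior_mean=c_eff[col_of_ind])
                # --- colony effects c_k | w -----------------------------
                wsums = _group_sums(col_of_ind, w_eff, n_col)
                c_eff = _draw_effects(rng, wsums, ind_per_col, i_prec,
                                      np.linalg.inv(cs_c.cov))
                u_dev = w_eff - c_eff[col_of_ind]
                cs_i.update(u_dev.T @ u_dev, n_ind, rng)
                resid = y - fixed - w_eff[ind]
            else:
                e = y - fixed
                sums = _group_sums(col, e, n_col)
                c_eff = _draw_effects(rng, sums, counts_col, r_prec,
                                      np.linalg.inv(cs_c.cov))
                resid = y - fixed - c_eff[col]
            cs_c.update(c_eff.T @ c_eff, n_col, rng)
            cs_r.update(resid.T @ resid, n, rng)

            if it < settings.burn_in and (it + 1) % adapt_every == 0:
                cs_c.adapt(adapt_every)
                cs_r.adapt(adapt_every)
                if cs_i is not None:
                    cs_i.adapt(adapt_every)

            if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
                if kept < keep:
                    out["cov_colony"][kept] = cs_c.cov
                    out["cov_residual"][kept] = cs_r.cov
                    out["alpha"][kept] = alpha
                    out["habitat_effect"][kept] = bhab
                    if ind is not None:
                        out["cov_individual"][kept] = cs_i.cov
                    kept += 1
        return out


class MultiTraitResults:
    """Posterior draws of the multivariate mixed model."""

    LEVEL_KEYS = {"colony": "cov_colony", "individual": "cov_individual",
                  "residual": "cov_residual"}

    def __init__(self, model, samples, settings):
        self.model = model
        self.samples = samples
        self.settings = settings

    @property
    def levels(self):
        return [lvl for lvl, key in self.LEVEL_KEYS.items() if key in self.samples]

    def cov_draws(self, level: str) -> np.ndarray:
        key = self.LEVEL_KEYS[level]
        arr = self.samples[key]
        return arr.reshape(-1, *arr.shape[2:])

    def level_correlations(self, level: str, prob: float = 0.95) -> LevelCorrelations:
        interpretable = not (level == "residual" and self.model.ind is None)
        return decompose_correlations(self.cov_draws(level), self.model.traits,
                                      level, interpretable, prob)

    def habitat_effect(self, trait: str | None = None):
        """pMCMC summary of the habitat fixed effect.

        With ``trait=None`` the draws are averaged over traits (one
        overall habitat effect on the standardized trait battery).
        """
        arr = self.samples["habitat_effect"]
        draws = arr.reshape(-1, arr.shape[-1])
        if trait is None:
            x = draws.mean(axis=1)
        else:
            x = draws[:, self.model.traits.index(trait)]
        return fixed_effect_pmcmc(x)

    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for level in self.levels:
            arr = self.samples[self.LEVEL_KEYS[level]]
            t = arr.shape[-1]
            for i in range(t):
                for j in range(i, t):
                    d = arr[:, :, i, j]
                    rows.append(dict(parameter=f"{level}[{i},{j}]",
                                     rhat=_split_rhat(d), ess=_ess(d)))
        return pd.DataFrame(rows)

    def summary(self, prob: float = 0.95) -> str:
        lines = ["Multivariate mixed model: level-wise trait correlations"]
        for level in self.levels:
            lc = self.level_correlations(level, prob)
            note = "" if lc.interpretable else "  [not interpretable at this level]"
            lines.append(f"-- {level}{note}")
            t = len(lc.traits)
            for i in range(t):
                for j in range(i + 1, t):
                    if np.isnan(lc.matrix[i, j]):
                        continue
                    star = " *" if lc.supported[i, j] else ""
                    lines.append(
                        f"  {lc.traits[i]} - {lc.traits[j]:14s} "
                        f"r = {lc.matrix[i, j]:6.2f} "
                        f"({lc.cri_low[i, j]:.2f} to {lc.cri_high[i, j]:.2f}){star}")
        eff, cri, p = self.habitat_effect()
        lines.append(f"habitat effect = {eff:.3f}, CrI ({cri[0]:.3f}, {cri[1]:.3f}), "
                     f"pMCMC = {p:.3f}")
        return "\n".join(lines)


def fit_multitrait_model(trials, colonies=None, traits=("activity", "meandering",
                                                        "exploration", "aggression"),
                         random_levels=("colony", "individual"),
                         chains=2, iterations=4000, burn_in=1000, thin=2,
                         seed=0) -> MultiTraitResults:
    """Convenience wrapper selecting the four- or five-trait model form."""
    if "individual" in random_levels:
        model = MultiTraitModel.from_trials(trials, traits)
    else:
        if colonies is None:
            raise ValueError("colony table required for the colony-only form")
        model = MultiTraitModel.from_trials_and_displacement(trials, colonies, traits)
    return model.fit(chains=chains, iterations=iterations, burn_in=burn_in,
                     thin=thin, seed=seed)
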