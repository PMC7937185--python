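"""Hierarchical synthetic-data generator.

Generates trial-level behavioural data with exactly the statistical
structure the downstream models assume:

* a mean submodel per trait — fixed effects of worker size, colony size,
  conspecific and allospecific nest density, habitat and repeat number,
  plus an individual intercept ``id_mu`` and a colony intercept;
* a dispersion submodel — the same fixed effects (minus repeat) on the
  log residual SD, plus an individual intercept ``id_sigma``;
* ``(id_mu, id_sigma)`` jointly bivariate normal with a configurable
  covariance (behavioural type coupled to predictability);
* among-trait correlations injected separately at the colony, individual
  and residual levels from the configured correlation matrices.

Latent trait values are produced on the standardised analysis scale and
mapped to observation units through fixed affine/log1p observation
scales, so that the package's own transform-and-standardise step recovers
the latent values exactly (up to rare boundary clipping, which is
counted).  True random-effect draws are returned in a tidy ``truth``
side-table to support parameter-recovery testing.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import SimulationConfig, TRAIT_ORDER, stage_rng
from .data import LOG_TRAITS, derive_production, validate_colonies, validate_trials


class SyntheticDataset(NamedTuple):
    trials: pd.DataFrame
    colonies: pd.DataFrame
    truth: pd.DataFrame


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def _truncated_poisson(rng, lam, size, lo, hi):
    draw = rng.poisson(lam, size=size)
    return np.clip(draw, lo, hi)


def _latent_to_raw(latent: np.ndarray, trait: str, scales: dict) -> tuple[np.ndarray, int]:
    """Map standardised latent values to trait units; returns (raw, n_clipped)."""
    loc, scale = scales[trait]
    obs = loc + scale * latent
    if trait in LOG_TRAITS:
        raw = np.expm1(obs)
    else:
        raw = obs
    hi = 3.0 if trait == "aggression" else np.inf
    clipped = int(np.sum((raw < 0) | (raw > hi)))
    return np.clip(raw, 0.0, hi), clipped


def generate_colony_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw colony-level covariates within the configured ranges.

    Colony sizes are log-uniform over the configured range (matching the
    observed right skew given only median/min/max); nest counts are
    Poisson draws truncated to their ranges.
    """
    rng = stage_rng(config.seed, "colonies")
    n_semi, n_inv = config.n_colonies_per_habitat
    n = n_semi + n_inv
    lo, hi = config.colony_size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).round().astype(int)
    colonies = pd.DataFrame({
        "colony_id": [f"C{i+1:03d}" for i in range(n)],
        "habitat": ["seminatural"] * n_semi + ["invaded"] * n_inv,
        "colony_size": sizes,
        "myrmica_nests": _truncated_poisson(rng, 1.5, n, *config.myrmica_nest_range),
        "allo_nests": _truncated_poisson(rng, 1.0, n, *config.allo_nest_range),
        "n_queens": rng.poisson(3.0, size=n) + 1,
        "mean_worker_size": np.maximum(
            rng.normal(config.worker_size_mean, config.worker_size_sd / 4.0, size=n), 1.0
        ),
    })
    return colonies


def _design_matrices(config, colonies, rng):
    """Expand the colony table to the trial grid and build z-scored designs."""
    n_col = len(colonies)
    n_w = config.n_workers_per_colony
    n_rep = config.n_repeats_per_assay

    col_idx = np.repeat(np.arange(n_col), n_w)
    worker_size = np.maximum(
        rng.normal(config.worker_size_mean, config.worker_size_sd, size=n_col * n_w), 1.0
    )
    ind = pd.DataFrame({
        "individual_id": [
            f"{colonies['colony_id'].iloc[c]}-W{w+1:02d}"
            for c in range(n_col) for w in range(n_w)
        ],
        "colony_idx": col_idx,
        "worker_size": worker_size,
    })

    # trial grid: one row per (individual, repeat); assays add a 4th axis
    ind_idx = np.repeat(np.arange(len(ind)), n_rep)
    rep = np.tile(np.arange(1, n_rep + 1), len(ind))
    grid = pd.DataFrame({
        "ind_idx": ind_idx,
        "colony_idx": ind["colony_idx"].to_numpy()[ind_idx],
        "repeat_index": rep,
    })

    habitat01 = (colonies["habitat"] == "invaded").astype(float).to_numpy()
    cov = {
        "worker_size": _zscore(ind["worker_size"].to_numpy())[ind_idx],
        "colony_size": _zscore(np.log(colonies["colony_size"].to_numpy(float)))[grid["colony_idx"]],
        "myrmica_nests": _zscore(colonies["myrmica_nests"].to_numpy(float))[grid["colony_idx"]],
        "allo_nests": _zscore(colonies["allo_nests"].to_numpy(float))[grid["colony_idx"]],
        "habitat": habitat01[grid["colony_idx"]],
        "repeat_index": _zscore(grid["repeat_index"].to_numpy(float)),
    }
    x_mean = np.column_stack([np.ones(len(grid))] + [cov[k] for k in (
        "worker_size", "colony_size", "myrmica_nests", "allo_nests", "habitat", "repeat_index")])
    x_disp = x_mean[:, :-1]
    return ind, grid, x_mean, x_disp


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the behavioural trial table, colony table and truth table.

    All four individual-level traits are generated jointly: shared fixed
    effects (``config.beta`` / ``config.gamma``), level-specific deviations
    drawn from the configured colony / individual / residual correlation
    matrices, and per-individual dispersion intercepts coupled to the mean
    intercepts through ``cov_mu_sigma``.
    """
    config.validate()
    colonies = generate_colony_covariates(config)
    rng = stage_rng(config.seed, "trials")
    ind, grid, x_mean, x_disp = _design_matrices(config, colonies, rng)

    n_col, n_ind, n_rows = len(colonies), len(ind), len(grid)
    k = len(TRAIT_ORDER)
    r_col = config.level_correlation_matrices["colony"]
    r_ind = config.level_correlation_matrices["individual"]
    r_res = config.level_correlation_matrices["residual"]

    def chol(m):
        w, v = np.linalg.eigh(m)
        return v @ np.diag(np.sqrt(np.clip(w, 0, None)))

    # colony intercepts, correlated across traits
    colony_eff = rng.standard_normal((n_col, k)) @ chol(r_col).T * np.sqrt(config.sigma2_colony)

    # individual mean intercepts correlated across traits; dispersion
    # intercepts coupled to the own-trait mean intercept so that
    # cov(id_mu, id_sigma) = cov_mu_sigma exactly
    id_mu = rng.standard_normal((n_ind, k)) @ chol(r_ind).T * np.sqrt(config.sigma2_id_mu)
    if config.sigma2_id_mu > 0:
        slope = config.cov_mu_sigma / config.sigma2_id_mu
        resid_var = config.sigma2_id_sigma - config.cov_mu_sigma**2 / config.sigma2_id_mu
    else:
        slope, resid_var = 0.0, config.sigma2_id_sigma
    id_sigma = slope * id_mu + rng.standard_normal((n_ind, k)) * np.sqrt(max(resid_var, 0.0))

    beta = np.asarray(config.beta)
    gamma = np.asarray(config.gamma)
    mean_pred = x_mean @ beta  # shared across traits
    log_sd = x_disp @ gamma    # shared across traits

    ind_idx = grid["ind_idx"].to_numpy()
    col_idx = grid["colony_idx"].to_numpy()
    mu = mean_pred[:, None] + id_mu[ind_idx] + colony_eff[col_idx]
    sd = np.exp(log_sd[:, None] + id_sigma[ind_idx])
    resid = rng.standard_normal((n_rows, k)) @ chol(r_res).T * sd
    latent = mu + resid

    rows = []
    n_clipped = 0
    for t, trait in enumerate(TRAIT_ORDER):
        raw, clipped = _latent_to_raw(latent[:, t], trait, config.trait_scales)
        n_clipped += clipped
        if trait == "aggression" and config.discretize_aggression:
            raw = np.clip(np.round(raw), 0, 3)
        rows.append(pd.DataFrame({
            "colony_id": colonies["colony_id"].to_numpy()[col_idx],
            "individual_id": ind["individual_id"].to_numpy()[ind_idx],
            "habitat": colonies["habitat"].to_numpy()[col_idx],
            "assay": trait,
            "repeat_index": grid["repeat_index"].to_numpy(),
            "raw_value": raw,
            "latent_value": latent[:, t],
            "worker_size": ind["worker_size"].to_numpy()[ind_idx],
        }))
    trials = pd.concat(rows, ignore_index=True)
    trials.attrs["n_clipped"] = n_clipped

    truth_rows = []
    for t, trait in enumerate(TRAIT_ORDER):
        for j in range(n_ind):
            truth_rows.append(("individual", ind["individual_id"].iloc[j], trait,
                               id_mu[j, t], id_sigma[j, t]))
        for c in range(n_col):
            truth_rows.append(("colony", colonies["colony_id"].iloc[c], trait,
                               colony_eff[c, t], np.nan))
    truth = pd.DataFrame(truth_rows,
                         columns=["level", "unit_id", "trait", "effect_mu", "effect_sigma"])

    # placeholder brood columns so the colony table validates before the
    # productivity stage fills them in
    for c in ("n_larvae", "pupae_worker", "pupae_male", "pupae_gyne",
              "winged_gynes", "winged_males"):
        if c not in colonies.columns:
            colonies[c] = 0
    for c in ("displacement_1", "displacement_2", "displacement_3"):
        if c not in colonies.columns:
            colonies[c] = 1.0

    validate_trials(trials)
    return SyntheticDataset(trials, validate_colonies(colonies), truth)


def generate_nest_displacement(config: SimulationConfig,
                               colonies: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw three nest-displacement times per colony from a colony-level
    location/dispersion model.

    The mean submodel applies ``config.disp_beta`` to standardised colony
    covariates plus a colony intercept; the log-SD submodel applies
    ``config.disp_gamma`` plus a second colony intercept, the two
    intercepts bivariate normal with covariance ``disp_cov``.  Times are
    generated on the log scale, so positivity is structural.  Returns the
    augmented colony table and a truth table of colony effects.
    """
    if colonies is None or len(colonies) == 0:
        raise ValueError("colony table required before displacement generation")
    rng = stage_rng(config.seed, "displacement")
    n = len(colonies)
    n_rep = 3
    habitat01 = (colonies["habitat"] == "invaded").astype(float).to_numpy()
    covs = np.column_stack([
        np.ones(n),
        _zscore(colonies["mean_worker_size"].to_numpy(float)),
        _zscore(np.log(colonies["colony_size"].to_numpy(float))),
        _zscore(colonies["myrmica_nests"].to_numpy(float)),
        _zscore(colonies["allo_nests"].to_numpy(float)),
        habitat01,
    ])
    beta = np.asarray(config.disp_beta)
    gamma = np.asarray(config.disp_gamma)

    s2m, s2s, cv = (config.disp_sigma2_colony_mu,
                    config.disp_sigma2_colony_sigma, config.disp_cov)
    cov = np.array([[s2m, cv], [cv, s2s]])
    w, v = np.linalg.eigh(cov)
    eff = rng.standard_normal((n, 2)) @ (v @ np.diag(np.sqrt(np.clip(w, 0, None)))).T
    c_mu, c_sigma = eff[:, 0], eff[:, 1]

    rep_z = _zscore(np.arange(1.0, n_rep + 1))
    out = colonies.copy()
    latents = np.empty((n, n_rep))
    for r in range(n_rep):
        mu = covs @ beta[:6] + beta[6] * rep_z[r] + c_mu
        sd = np.exp(covs @ gamma + c_sigma)
        latents[:, r] = mu + rng.standard_normal(n) * sd
    loc, scale = config.trait_scales["displacement"]
    # exp, not expm1: positivity must be structural; at this scale
    # (hundreds of seconds) log1p and log differ negligibly
    times = np.exp(loc + scale * latents)
    for r in range(n_rep):
        out[f"displacement_{r+1}"] = times[:, r]
        out[f"displacement_latent_{r+1}"] = latents[:, r]
    truth = pd.DataFrame({
        "level": "colony", "unit_id": colonies["colony_id"],
        "trait": "displacement", "effect_mu": c_mu, "effect_sigma": c_sigma,
    })
    return out, truth


def generate_productivity(config: SimulationConfig, trials: pd.DataFrame,
                          colonies: pd.DataFrame) -> pd.DataFrame:
    """Draw brood counts from a negative-binomial model linked to colony
    behavioural summaries.

    The log expected total production is ``productivity_link`` applied to
    the standardised per-colony means and SDs of the (transformed) traits
    plus a habitat term; the realised total is split multinomially into
    larvae, pupae castes and winged sexuals so that the production-
    component identities hold by construction.
    """
    from .data import colony_trait_summaries, transform_and_standardize

    rng = stage_rng(config.seed, "productivity")
    tz = transform_and_standardize(trials)
    summ = colony_trait_summaries(tz, "z_value").set_index("colony_id")

    disp = np.log1p(colonies[["displacement_1", "displacement_2", "displacement_3"]]
                    .to_numpy(float))
    disp_z = (disp - disp.mean()) / disp.std()
    summ["mean_displacement"] = pd.Series(disp_z.mean(axis=1),
                                          index=colonies["colony_id"]).reindex(summ.index)
    summ["sd_displacement"] = pd.Series(disp_z.std(axis=1, ddof=1),
                                        index=colonies["colony_id"]).reindex(summ.index)

    link = config.productivity_link
    eta = np.full(len(summ), float(link.get("intercept", 0.0)))
    hab = colonies.set_index("colony_id")["habitat"].reindex(summ.index)
    eta += float(link.get("habitat", 0.0)) * (hab == "invaded").to_numpy(float)
    for key, coef in link.items():
        if key in ("intercept", "habitat") or coef == 0.0:
            continue
        if key not in summ.columns:
            raise ValueError(f"productivity_link references unknown summary {key!r}")
        eta += coef * _zscore(summ[key].to_numpy(float))

    mu = np.exp(eta)
    size = config.nb_size
    total = rng.negative_binomial(size, size / (size + mu))
    shares = np.array([0.50, 0.30, 0.08, 0.07, 0.03, 0.02])  # larvae, wpup, mpup, gpup, wg, wm
    parts = np.array([rng.multinomial(t, shares) for t in total])

    out = colonies.copy().set_index("colony_id").loc[summ.index].reset_index()
    for i, c in enumerate(("n_larvae", "pupae_worker", "pupae_male", "pupae_gyne",
                           "winged_gynes", "winged_males")):
        out[c] = parts[:, i]
    for c in ("total_production", "new_workers", "new_gynes", "new_males"):
        if c in out.columns:
            out = out.drop(columns=c)
    out = derive_production(out)
    out["true_log_mean"] = eta
    return validate_colonies(out)


def simulate_individual_production(n_individuals=300, n_series=3,
                                   coefficients=None, intercept=6.37,
                                   sigma_individual=0.3, nb_size=5.0,
                                   seed=0):
    """Row-level NB-GLMM data: counts driven by trial-series trait values.

    Returns ``(frame, exog_names)`` with one row per (individual, trial
    series): standardized trait columns, an ``individual_id`` and a count
    response whose log mean is intercept + coefficients . traits + a
    N(0, sigma_individual^2) individual intercept.
    """
    from .data import INDIVIDUAL_TRAITS

    coefficients = dict(coefficients or {})
    rng = stage_rng(seed, "ind-production")
    g = np.repeat(np.arange(n_individuals), n_series)
    n = len(g)
    traits = {t: rng.standard_normal(n) for t in INDIVIDUAL_TRAITS}
    u = rng.normal(0.0, sigma_individual, size=n_individuals)
    eta = np.full(n, float(intercept)) + u[g]
    for t, coef in coefficients.items():
        eta = eta + coef * traits[t]
    mu = np.exp(eta)
    y = rng.negative_binomial(nb_size, nb_size / (nb_size + mu))
    frame = pd.DataFrame(traits)
    frame["individual_id"] = [f"I{i:04d}" for i in g]
    frame["count"] = y
    return frame, list(INDIVIDUAL_TRAITS)


def analysis_scale_truth(config: SimulationConfig, trials: pd.DataFrame,
                         trait: str) -> dict:
    """Generating parameters mapped to the standardized analysis scale.

    The analysis pipeline z-scores the (transformed) response over the
    analysis rows; because the model is equivariant under affine maps of
    the response, the generating parameters correspond exactly to scaled
    versions of themselves on the fitted scale: slopes and random-effect
    SDs divide by the realized total SD, the dispersion intercept shifts
    by its log, and the mean-rIIV correlation is unchanged.
    """
    sub = trials[trials["assay"] == trait]
    lat = sub["latent_value"].to_numpy(dtype=float)
    m, sd = lat.mean(), lat.std()
    beta = np.asarray(config.beta, dtype=float)
    gamma = np.asarray(config.gamma, dtype=float)
    out = {}
    names = ("intercept", "worker_size", "colony_size", "myrmica_nests",
             "allo_nests", "habitat", "repeat_index")
    for p, name in enumerate(names):
        val = beta[p] / sd if p else (beta[0] - m) / sd
        out[f"beta_{name}"] = val
    for p, name in enumerate(names[:-1]):
        out[f"gamma_{name}"] = gamma[p] - np.log(sd) if p == 0 else gamma[p]
    out["sigma2_id_mu"] = config.sigma2_id_mu / sd**2
    out["sigma2_colony"] = config.sigma2_colony / sd**2
    out["sigma2_id_sigma"] = config.sigma2_id_sigma
    out["cov_mu_sigma"] = config.cov_mu_sigma / sd
    if config.sigma2_id_mu > 0 and config.sigma2_id_sigma > 0:
        out["r_int_riiv"] = config.cov_mu_sigma / np.sqrt(
            config.sigma2_id_mu * config.sigma2_id_sigma)
    else:
        out["r_int_riiv"] = 0.0
    return out


def generate_study(config: SimulationConfig) -> SyntheticDataset:
    """Full study generation: behaviour, displacement, productivity."""
    trials, colonies, truth = generate_dataset(config)
    colonies, disp_truth = generate_nest_displacement(config, colonies)
    colonies = generate_productivity(config, trials, colonies)
    truth = pd.concat([truth, disp_truth], ignore_index=True)
    return SyntheticDataset(trials, colonies, truth)
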