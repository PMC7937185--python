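"""Repeatability (intraclass correlation) with bootstrap and permutation.

Repeatability of a behavioural trait is the share of phenotypic variance
attributable to differences among groups,

    R = sigma2_group / (sigma2_group + sigma2_residual),

estimated from the Gaussian random-intercept model y_ij = mu + a_i +
e_ij by maximum likelihood.  At the individual level the group is the
individual (its repeated assays); at the colony level the group is the
colony (its workers' trials pooled).  Confidence intervals come from a
parametric bootstrap — simulate from the fitted model with the observed
group structure, refit, take percentiles — and significance from a
randomization test that permutes group labels across observations
(optionally permuting whole individuals for colony-level tests, which
preserves within-individual correlation).

The ML fit profiles the mean and residual variance out of the likelihood
and optimises the single variance ratio numerically, which makes the
thousands of bootstrap/permutation refits cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


class _GroupedData:
    """Sufficient statistics of one-way grouped data."""

    def __init__(self, y, groups):
        y = np.asarray(y, dtype=float)
        labels, idx = np.unique(groups, return_inverse=True)
        self.n = len(y)
        self.n_groups = len(labels)
        self.idx = idx
        self.counts = np.bincount(idx).astype(float)
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if (self.counts < 2).all():
            raise ValueError("degenerate grouping: every group is a singleton")
        self.sums = np.bincount(idx, y)
        self.means = self.sums / self.counts
        self.ss_within = float(np.sum(y**2) - np.sum(self.sums**2 / self.counts))
        self.y = y


def _profile_nll(log_lam, d: _GroupedData):
    """-2 log likelihood profiled over the mean and residual variance.

    lam = sigma2_group / sigma2_residual.
    """
    lam = np.exp(log_lam)
    w = d.counts / (1.0 + d.counts * lam)
    mu = np.sum(w * d.means) / np.sum(w)
    q = d.ss_within + np.sum(w * (d.means - mu) ** 2)
    s2w = q / d.n
    if s2w <= 0:
        return np.inf
    logdet = np.sum(np.log1p(d.counts * lam))
    return d.n * np.log(s2w) + logdet + d.n


def _fit_icc(d: _GroupedData) -> tuple[float, float, float]:
    """ML variance components; returns (R, sigma2_group, sigma2_resid)."""
    between = float(np.sum(d.counts * (d.means - d.y.mean()) ** 2))
    if d.ss_within <= 1e-12 * max(between, 1.0):
        # groups internally constant: perfect repeatability
        return 1.0, between / d.n, 0.0
    res = optimize.minimize_scalar(_profile_nll, bounds=(-12.0, 8.0),
                                   args=(d,), method="bounded",
                                   options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    if _profile_nll(-30.0, d) <= res.fun:   # boundary: no group variance
        lam = 0.0
    w = d.counts / (1.0 + d.counts * lam)
    mu = np.sum(w * d.means) / np.sum(w)
    s2w = (d.ss_within + np.sum(w * (d.means - mu) ** 2)) / d.n
    s2b = lam * s2w
    r = s2b / (s2b + s2w) if (s2b + s2w) > 0 else 0.0
    return float(np.clip(r, 0.0, 1.0)), float(s2b), float(s2w)


@dataclass
class RepeatabilityResults:
    """ICC point estimate with bootstrap CI and permutation p-value."""

    trait: str
    level: str
    R: float
    sigma2_group: float
    sigma2_residual: float
    ci: tuple
    p: float
    n_bootstrap: int
    n_permutations: int
    truncated: bool = False   # a variance hit the zero boundary

    def summary(self) -> str:
        return (f"repeatability of {self.trait} at the {self.level} level: "
                f"R = {self.R:.3f} (95% CI {self.ci[0]:.3f}-{self.ci[1]:.3f}), "
                f"permutation p = {self.p:.4g}")


class RepeatabilityModel:
    """One-way random-intercept repeatability model.

    Parameters
    ----------
    y : trait values (standardized).
    groups : group labels (individual IDs or colony IDs).
    permute : "observations" permutes group labels across all rows;
        "blocks" permutes whole blocks (e.g. individuals) across groups,
        preserving within-block correlation — only meaningful with
        ``block_labels``.
    """

    def __init__(self, y, groups, trait="trait", level="group",
                 permute="observations", block_labels=None):
        self.data = _GroupedData(y, groups)
        self.trait = trait
        self.level = level
        if permute not in ("observations", "blocks"):
            raise ValueError("permute must be 'observations' or 'blocks'")
        if permute == "blocks" and block_labels is None:
            raise ValueError("block permutation requires block_labels")
        self.permute = permute
        self.block_labels = None if block_labels is None else np.asarray(block_labels)
        self.groups = np.asarray(groups)

    def fit(self, n_bootstrap=1000, n_permutations=1000, seed=0) -> RepeatabilityResults:
        d = self.data
        r_obs, s2b, s2w = _fit_icc(d)
        truncated = s2b == 0.0
        rng = np.random.default_rng(int(seed) % 2**31)

        # parametric bootstrap under the fitted model
        boot = np.empty(n_bootstrap)
        mu = float(np.mean(d.y))
        for b in range(n_bootstrap):
            a = rng.normal(0.0, np.sqrt(s2b), size=d.n_groups)
            yb = mu + a[d.idx] + rng.normal(0.0, np.sqrt(s2w), size=d.n)
            boot[b], _, _ = _fit_icc(_GroupedData(yb, d.idx))
        ci = tuple(np.quantile(boot, [0.025, 0.975])) if n_bootstrap else (np.nan, np.nan)

        # randomization test: break the group structure
        exceed = 0
        for _ in range(n_permutations):
            if self.permute == "observations":
                perm_y = rng.permutation(d.y)
                r_p, _, _ = _fit_icc(_GroupedData(perm_y, d.idx))
            else:
                # permute whole blocks across the dataset: shuffle block
                # identities, keeping each block's rows together
                blocks = pd.unique(self.block_labels)
                shuffled = rng.permutation(blocks)
                remap = dict(zip(blocks, shuffled))
                # block -> group mapping from the original data
                block_to_group = pd.Series(self.groups,
                                           index=self.block_labels).groupby(level=0).first()
                new_groups = np.array([block_to_group[remap[b]] for b in self.block_labels])
                r_p, _, _ = _fit_icc(_GroupedData(d.y, new_groups))
            exceed += r_p >= r_obs
        p = (1.0 + exceed) / (1.0 + n_permutations)

        return RepeatabilityResults(self.trait, self.level, r_obs, s2b, s2w,
                                    (float(ci[0]), float(ci[1])), float(p),
                                    n_bootstrap, n_permutations, truncated)


def estimate_repeatability(trials: pd.DataFrame, trait: str, level: str,
                           n_bootstrap=1000, n_permutations=1000, seed=0,
                           value_col="z_value",
                           permute="observations") -> RepeatabilityResults:
    """Repeatability of one trait at the colony or individual level."""
    if level not in ("colony", "individual"):
        raise ValueError("level must be 'colony' or 'individual'")
    if trait == "displacement":
        raise ValueError("use estimate_displacement_repeatability for the colony trait")
    sub = trials[trials["assay"] == trait]
    if sub.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    groups = sub["colony_id"] if level == "colony" else sub["individual_id"]
    blocks = sub["individual_id"].to_numpy() if permute == "blocks" else None
    model = RepeatabilityModel(sub[value_col], groups, trait=trait, level=level,
                               permute=permute, block_labels=blocks)
    return model.fit(n_bootstrap, n_permutations, seed)


def estimate_displacement_repeatability(colonies: pd.DataFrame,
                                        n_bootstrap=1000, n_permutations=1000,
                                        seed=0) -> RepeatabilityResults:
    """Colony-level repeatability of nest displacement (3 repeats/colony)."""
    from .data import log_transform, Standardizer

    times = np.concatenate([colonies[f"displacement_{r}"].to_numpy(float)
                            for r in (1, 2, 3)])
    groups = np.tile(colonies["colony_id"].to_numpy(), 3)
    z = Standardizer().fit_apply("displacement",
                                 log_transform(times, "displacement"))
    model = RepeatabilityModel(z, groups, trait="displacement", level="colony")
    return model.fit(n_bootstrap, n_permutations, seed)


def repeatability_table(trials, colonies=None, traits=("activity", "meandering",
                                                       "exploration", "aggression"),
                        levels=("colony", "individual"), by_habitat=False,
                        n_bootstrap=1000, n_permutations=1000,
                        seed=0) -> pd.DataFrame:
    """Repeatability of every trait at every level, optionally per habitat."""
    rows = []
    strata = [("all", trials)]
    if by_habitat:
        strata = [(h, trials[trials["habitat"] == h])
                  for h in trials["habitat"].unique()]
    for stratum, sub in strata:
        for trait in traits:
            for level in levels:
                est = estimate_repeatability(sub, trait, level, n_bootstrap,
                                             n_permutations, seed)
                rows.append(dict(habitat=stratum, trait=trait, level=level,
                                 R=est.R, ci_low=est.ci[0], ci_high=est.ci[1],
                                 p=est.p))
        if colonies is not None and not by_habitat:
            est = estimate_displacement_repeatability(colonies, n_bootstrap,
                                                      n_permutations, seed)
            rows.append(dict(habitat=stratum, trait="displacement", level="colony",
                             R=est.R, ci_low=est.ci[0], ci_high=est.ci[1], p=est.p))
    return pd.DataFrame(rows)
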