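"""Simulation configuration: the hierarchical design and generating values.

The defaults reproduce the field design this package models: 12 colonies
from seminatural meadows and 11 from meadows invaded by *Solidago*, 12
focal foragers per colony each tested three times per assay, colony sizes
spanning 219-5964 workers, 0-9 conspecific (*Myrmica*) and 0-3
allospecific nests per 9 m^2, and three nest-displacement trials per
colony.  Generating coefficients default to the published posterior means
for activity (mean and dispersion submodels), the published among-trait
correlation matrices at the colony / individual / residual levels, and the
published total-production regression coefficients, so that the default
synthetic dataset is the study's own effect-size regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

MEAN_COVARIATES = (
    "worker_size",
    "colony_size",
    "myrmica_nests",
    "allo_nests",
    "habitat",
    "repeat_index",
)
DISPERSION_COVARIATES = MEAN_COVARIATES[:-1]

TRAIT_ORDER = ("activity", "meandering", "exploration", "aggression")


def _corr(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    """Build a 4x4 trait correlation matrix from the upper-triangle pairs."""
    k = len(TRAIT_ORDER)
    m = np.eye(k)
    for (a, b), r in pairs.items():
        i, j = TRAIT_ORDER.index(a), TRAIT_ORDER.index(b)
        m[i, j] = m[j, i] = r
    return m


# Published level-specific among-trait correlations (posterior means),
# nudged where needed to the nearest positive-semidefinite matrix.
COLONY_CORR = _corr({
    ("activity", "meandering"): -0.83,
    ("activity", "exploration"): 0.89,
    ("activity", "aggression"): 0.15,
    ("meandering", "exploration"): -0.76,
    ("meandering", "aggression"): -0.23,
    ("exploration", "aggression"): 0.28,
})
INDIVIDUAL_CORR = _corr({
    ("activity", "meandering"): -0.89,
    ("activity", "exploration"): 0.91,
    ("activity", "aggression"): 0.35,
    ("meandering", "exploration"): -0.86,
    ("meandering", "aggression"): -0.27,
    ("exploration", "aggression"): 0.35,
})
RESIDUAL_CORR = _corr({
    ("activity", "meandering"): -0.60,
    ("activity", "exploration"): 0.02,
    ("activity", "aggression"): -0.04,
    ("meandering", "exploration"): -0.003,
    ("meandering", "aggression"): -0.029,
    ("exploration", "aggression"): 0.027,
})

#: total-production regression on standardised colony trait means/SDs
#: (log link): intercept, habitat, then mean/SD per trait
DEFAULT_PRODUCTIVITY_LINK = {
    "intercept": 6.39,
    "habitat": -0.28,
    "mean_activity": -0.23,
    "sd_activity": 0.24,
    "mean_meandering": 0.88,
    "sd_meandering": -0.95,
    "mean_exploration": 0.73,
    "sd_exploration": -0.20,
    "mean_aggression": -0.13,
    "sd_aggression": 0.25,
    "mean_displacement": -0.29,
    "sd_displacement": -0.44,
}


class ConfigError(ValueError):
    """A simulation configuration violates an invariant."""


def nearest_psd(corr: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation-like PSD matrix."""
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= 0:
        return sym
    w = np.clip(w, floor, None)
    m = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def _check_corr(name: str, m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError(f"{name}: correlation matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ConfigError(f"{name}: correlation matrix must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ConfigError(f"{name}: correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise ConfigError(f"{name}: correlation matrix not positive semidefinite")
    return m


@dataclass
class SimulationConfig:
    """Generating values and design sizes for the hierarchical simulator.

    ``beta`` orders the mean-submodel coefficients as (intercept,
    worker size, colony size, Myrmica nests, allospecific nests, habitat,
    repeat index); ``gamma`` orders the log-residual-SD submodel the same
    way without the repeat term.  All coefficients are on the standardised
    analysis scale.  ``disp_*`` fields are the colony-level analogue used
    for nest-displacement times.
    """

    # design
    n_colonies_per_habitat: tuple[int, int] = (12, 11)
    n_workers_per_colony: int = 12
    n_repeats_per_assay: int = 3
    colony_size_range: tuple[int, int] = (219, 5964)
    myrmica_nest_range: tuple[int, int] = (0, 9)
    allo_nest_range: tuple[int, int] = (0, 3)
    worker_size_mean: float = 1000.0   # head width, µm; placeholder scale
    worker_size_sd: float = 60.0

    # individual-trait DHGLM generating values (activity defaults)
    beta: tuple = (-0.11, -0.06, 0.16, 0.04, -0.22, 0.08, -0.17)
    gamma: tuple = (-0.69, 0.03, -0.07, 0.097, -0.098, 0.13)
    sigma2_id_mu: float = 0.58
    sigma2_colony: float = 0.43
    sigma2_id_sigma: float = 0.26
    cov_mu_sigma: float = 0.21 * float(np.sqrt(0.58 * 0.26))

    # among-trait correlation structure per level
    level_correlation_matrices: dict = field(default_factory=lambda: {
        "colony": nearest_psd(COLONY_CORR),
        "individual": nearest_psd(INDIVIDUAL_CORR),
        "residual": nearest_psd(RESIDUAL_CORR),
    })

    # colony-level nest-displacement DHGLM (intercept, head size,
    # colony size, Myrmica nests, allospecific nests, habitat, repeats)
    disp_beta: tuple = (0.11, -0.1, -0.49, 0.06, -0.32, -0.09, -0.1)
    disp_gamma: tuple = (-0.03, 0.06, 0.12, 0.14, -0.02, -0.19)
    disp_sigma2_colony_mu: float = 0.34
    disp_sigma2_colony_sigma: float = 0.5
    disp_cov: float = -0.35 * float(np.sqrt(0.34 * 0.5))

    # productivity link (log scale) and NB size parameter
    productivity_link: dict = field(default_factory=lambda: dict(DEFAULT_PRODUCTIVITY_LINK))
    nb_size: float = 5.0

    seed: int = 0

    # observation scales mapping the latent standardised model scale back
    # to trait units (location, scale on the transformed scale)
    trait_scales: dict = field(default_factory=lambda: {
        "activity": (500.0, 110.0),     # cm
        "meandering": (3.0, 0.45),      # log1p(°/cm)
        "exploration": (14.0, 3.2),     # squares
        "aggression": (0.75, 0.12),     # log1p(score)
        "displacement": (7.0, 0.6),     # log1p(seconds)
    })
    discretize_aggression: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> "SimulationConfig":
        for name in ("n_workers_per_colony", "n_repeats_per_assay"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if min(self.n_colonies_per_habitat) < 1:
            raise ConfigError("n_colonies_per_habitat entries must be >= 1")
        lo, hi = self.colony_size_range
        if not (0 < lo <= hi):
            raise ConfigError("colony_size_range must be positive and ordered")
        for name in ("myrmica_nest_range", "allo_nest_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ConfigError(f"{name} must be ordered non-negative")
        for name in ("sigma2_id_mu", "sigma2_colony", "sigma2_id_sigma",
                     "disp_sigma2_colony_mu", "disp_sigma2_colony_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        bound = np.sqrt(self.sigma2_id_mu * self.sigma2_id_sigma)
        if abs(self.cov_mu_sigma) > bound + 1e-12:
            raise ConfigError(
                "cov_mu_sigma violates |cov| <= sqrt(sigma2_id_mu * sigma2_id_sigma)"
            )
        bound = np.sqrt(self.disp_sigma2_colony_mu * self.disp_sigma2_colony_sigma)
        if abs(self.disp_cov) > bound + 1e-12:
            raise ConfigError("disp_cov violates its Cauchy-Schwarz bound")
        if len(self.beta) != 7:
            raise ConfigError("beta must have 7 entries (beta0..beta6)")
        if len(self.gamma) != 6:
            raise ConfigError("gamma must have 6 entries (gamma0..gamma5)")
        if self.nb_size <= 0:
            raise ConfigError("nb_size must be > 0")
        for level, m in self.level_correlation_matrices.items():
            self.level_correlation_matrices[level] = _check_corr(level, m)
        return self

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["level_correlation_matrices"] = {
            k: np.asarray(v).tolist() for k, v in self.level_correlation_matrices.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("n_colonies_per_habitat", "colony_size_range",
                    "myrmica_nest_range", "allo_nest_range", "beta", "gamma",
                    "disp_beta", "disp_gamma"):
            if key in d:
                d[key] = tuple(d[key])
        if "level_correlation_matrices" in d:
            d["level_correlation_matrices"] = {
                k: np.asarray(v, dtype=float)
                for k, v in d["level_correlation_matrices"].items()
            }
        if "trait_scales" in d:
            d["trait_scales"] = {k: tuple(v) for k, v in d["trait_scales"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream of one shared seed."""
    tag = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))
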