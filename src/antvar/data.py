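"""Shared data model, CSV interchange and preprocessing.

Two tidy tables drive every analysis in the package:

``trials``
    one row per behavioural trial: ``colony_id``, ``individual_id``,
    ``habitat`` (``seminatural`` / ``invaded``), ``assay`` (``activity``,
    ``meandering``, ``exploration``, ``aggression``), ``repeat_index``
    (1-3) and ``raw_value`` in trait units (cm travelled; degrees/cm;
    grid squares entered; ordinal aggression score 0-3).

``colonies``
    one row per colony: habitat, worker count (``colony_size``), queen and
    brood counts, conspecific (``myrmica_nests``) and allospecific
    (``allo_nests``) nest densities per 9 m^2, mean worker head width, and
    three nest-displacement times ``displacement_1..3`` (seconds until the
    last larva is carried into the new nest chamber).

Preprocessing mirrors the analysis conventions: aggression, meandering and
nest displacement are log(1+x)-transformed before modelling (aggression
scores include 0, so a plain log is undefined; one rule covers all three),
and every modelled variable is centred and scaled to unit SD on the
analysis subset actually fed to each model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

INDIVIDUAL_TRAITS = ("activity", "meandering", "exploration", "aggression")
COLONY_TRAIT = "displacement"
ALL_TRAITS = INDIVIDUAL_TRAITS + (COLONY_TRAIT,)

#: traits modelled on the log(1+x) scale
LOG_TRAITS = frozenset({"aggression", "meandering", "displacement"})

HABITATS = ("seminatural", "invaded")
N_REPEATS = 3

TRIAL_COLUMNS = [
    "colony_id",
    "individual_id",
    "habitat",
    "assay",
    "repeat_index",
    "raw_value",
]

COLONY_COLUMNS = [
    "colony_id",
    "habitat",
    "colony_size",
    "n_queens",
    "n_larvae",
    "pupae_worker",
    "pupae_male",
    "pupae_gyne",
    "winged_gynes",
    "winged_males",
    "myrmica_nests",
    "allo_nests",
    "mean_worker_size",
    "displacement_1",
    "displacement_2",
    "displacement_3",
]

PRODUCTION_COMPONENTS = [
    "n_larvae",
    "pupae_worker",
    "pupae_male",
    "pupae_gyne",
    "winged_gynes",
    "winged_males",
]


class ValidationError(ValueError):
    """A table violates the data-model contract."""


def _require_columns(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing column(s): {', '.join(missing)}")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against its invariants; returns the table.

    Checks column presence, repeat_index in 1-3, habitat and assay levels,
    non-negative locomotion/exploration values, aggression within [0, 3],
    uniqueness of (individual, assay, repeat) and a single colony per
    individual.
    """
    _require_columns(trials, TRIAL_COLUMNS, "trial table")
    rep = trials["repeat_index"].to_numpy()
    bad_rep = (rep < 1) | (rep != np.floor(rep))
    if bad_rep.any():
        row = int(trials.index[bad_rep][0])
        raise ValidationError(
            f"repeat_index must be a positive integer (row {row}, column repeat_index)"
        )
    bad_hab = ~trials["habitat"].isin(HABITATS)
    if bad_hab.any():
        row = int(trials.index[bad_hab][0])
        raise ValidationError(f"unknown habitat level (row {row}, column habitat)")
    bad_assay = ~trials["assay"].isin(INDIVIDUAL_TRAITS)
    if bad_assay.any():
        row = int(trials.index[bad_assay][0])
        raise ValidationError(f"unknown assay (row {row}, column assay)")
    vals = trials["raw_value"].to_numpy(dtype=float)
    nonneg = trials["assay"].isin(["activity", "meandering", "exploration"])
    if (vals[nonneg.to_numpy()] < 0).any():
        row = int(trials.index[nonneg & (trials["raw_value"] < 0)][0])
        raise ValidationError(
            f"activity, meandering, exploration must be >= 0 (row {row}, column raw_value)"
        )
    aggr = trials["assay"] == "aggression"
    agg_vals = trials.loc[aggr, "raw_value"]
    out = (agg_vals < 0) | (agg_vals > 3)
    if out.any():
        row = int(agg_vals.index[out][0])
        raise ValidationError(f"aggression ∈ [0,3] violated (row {row}, column raw_value)")
    dup = trials.duplicated(subset=["individual_id", "assay", "repeat_index"])
    if dup.any():
        row = int(trials.index[dup][0])
        raise ValidationError(
            f"duplicate (individual_id, assay, repeat_index) key (row {row})"
        )
    n_col = trials.groupby("individual_id")["colony_id"].nunique()
    multi = n_col[n_col > 1]
    if len(multi):
        raise ValidationError(
            f"individual {multi.index[0]!r} maps to more than one colony_id"
        )
    return trials


def derive_production(colonies: pd.DataFrame) -> pd.DataFrame:
    """Add the derived production components (integer identities).

    total_production = larvae + all pupae + winged sexuals;
    new_workers = larvae + worker pupae; new_gynes = gyne pupae + winged
    gynes; new_males = male pupae + winged males.
    """
    out = colonies.copy()
    out["total_production"] = sum(out[c] for c in PRODUCTION_COMPONENTS)
    out["new_workers"] = out["n_larvae"] + out["pupae_worker"]
    out["new_gynes"] = out["pupae_gyne"] + out["winged_gynes"]
    out["new_males"] = out["pupae_male"] + out["winged_males"]
    return out


def validate_colonies(colonies: pd.DataFrame) -> pd.DataFrame:
    """Validate a colony table; derives production components if absent."""
    _require_columns(colonies, COLONY_COLUMNS, "colony table")
    if colonies["colony_id"].duplicated().any():
        raise ValidationError("duplicate colony_id")
    count_cols = ["colony_size", "n_queens", "myrmica_nests", "allo_nests"] + PRODUCTION_COMPONENTS
    for c in count_cols:
        neg = colonies[c] < 0
        if neg.any():
            row = int(colonies.index[neg][0])
            raise ValidationError(f"count must be >= 0 (row {row}, column {c})")
    for c in ("displacement_1", "displacement_2", "displacement_3"):
        bad = ~(colonies[c] > 0)
        if bad.any():
            row = int(colonies.index[bad][0])
            raise ValidationError(f"displacement times must be > 0 (row {row}, column {c})")
    if "total_production" not in colonies.columns:
        colonies = derive_production(colonies)
    else:
        expect = sum(colonies[c] for c in PRODUCTION_COMPONENTS)
        if not (colonies["total_production"] == expect).all():
            raise ValidationError(
                "total_production != sum of brood components (identity violated)"
            )
    return colonies


def read_trial_table(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    return validate_trials(trials)


def read_colony_table(path) -> pd.DataFrame:
    colonies = pd.read_csv(path)
    return validate_colonies(colonies)


def write_trial_table(trials: pd.DataFrame, path) -> None:
    validate_trials(trials).to_csv(path, index=False)


def write_colony_table(colonies: pd.DataFrame, path) -> None:
    validate_colonies(colonies).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transforms and standardisation


def log_transform(values: np.ndarray | pd.Series, trait: str) -> np.ndarray:
    """log1p for aggression / meandering / displacement, identity otherwise."""
    arr = np.asarray(values, dtype=float)
    if trait in LOG_TRAITS:
        return np.log1p(arr)
    return arr


@dataclass
class Standardizer:
    """Centre/scale statistics computed on one analysis subset.

    Stored so that downstream stages (and simulated replicates) can apply
    exactly the statistics of the subset each model was fitted on.
    """

    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def fit(self, name: str, values) -> "Standardizer":
        arr = np.asarray(values, dtype=float)
        m = float(np.mean(arr))
        s = float(np.std(arr, ddof=0))
        if s == 0.0:
            raise ValidationError(f"standardization undefined: {name!r} has zero variance")
        self.mean[name] = m
        self.sd[name] = s
        return self

    def apply(self, name: str, values) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        return (arr - self.mean[name]) / self.sd[name]

    def fit_apply(self, name: str, values) -> np.ndarray:
        return self.fit(name, values).apply(name, values)


def transform_and_standardize(trials: pd.DataFrame) -> pd.DataFrame:
    """Add ``transformed_value`` and ``z_value`` columns, per assay.

    The log1p transform is applied where the trait is modelled on the log
    scale; standardisation statistics are computed per assay over the rows
    present in ``trials`` (the analysis subset).
    """
    out = trials.copy()
    transformed = np.empty(len(out), dtype=float)
    z = np.empty(len(out), dtype=float)
    for assay, idx in out.groupby("assay").groups.items():
        pos = out.index.get_indexer(idx)
        t = log_transform(out.loc[idx, "raw_value"], assay)
        transformed[pos] = t
        z[pos] = Standardizer().fit_apply(assay, t)
    out["transformed_value"] = transformed
    out["z_value"] = z
    return out


def standardize_columns(df: pd.DataFrame, columns) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score the named continuous columns; returns (table, statistics)."""
    out = df.copy()
    std = Standardizer()
    for c in columns:
        out[c] = std.fit_apply(c, out[c])
    return out, std


def filter_complete_cases(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only individuals tested three times in all four assays.

    Returns ``(filtered_trials, report)`` where the report counts retained
    and dropped individuals per habitat.
    """
    counts = (
        trials.groupby(["individual_id", "assay"])["repeat_index"]
        .count()
        .unstack(fill_value=0)
    )
    complete = counts.index[
        (counts.reindex(columns=list(INDIVIDUAL_TRAITS), fill_value=0) == N_REPEATS).all(axis=1)
    ]
    kept = trials[trials["individual_id"].isin(complete)].copy()
    info = trials[["individual_id", "habitat"]].drop_duplicates("individual_id")
    info = info.assign(retained=info["individual_id"].isin(complete))
    report = (
        info.groupby(["habitat", "retained"])
        .size()
        .rename("n_individuals")
        .reset_index()
    )
    if kept.empty:
        import warnings

        warnings.warn("complete-case filter removed every individual", stacklevel=2)
    return kept, report


def collinearity_screen(
    colonies: pd.DataFrame,
    variables=("n_queens", "n_larvae", "colony_size"),
    rho_threshold: float = 0.45,
) -> pd.DataFrame:
    """Pairwise Spearman screen among colony-level covariates.

    Returns one row per pair with Spearman rho, the S statistic
    (S = (n^3 - n)(1 - rho)/6 for untied data), the t-approximation
    p-value and a flag for |rho| above the threshold.  By convention the
    recommendation retains ``colony_size`` when a correlated set includes
    it (the covariate used in all downstream models).
    """
    if len(colonies) < 3:
        raise ValidationError("collinearity screen needs at least 3 colonies")
    n = len(colonies)
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            xa = colonies[a].to_numpy(dtype=float)
            xb = colonies[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                rows.append(
                    dict(var_a=a, var_b=b, rho=np.nan, s_statistic=np.nan,
                         p_value=np.nan, flagged=False,
                         note="rho undefined: constant variable")
                )
                continue
            rho, p = stats.spearmanr(xa, xb)
            s_stat = (n**3 - n) * (1.0 - rho) / 6.0
            rows.append(
                dict(var_a=a, var_b=b, rho=float(rho), s_statistic=float(s_stat),
                     p_value=float(p), flagged=bool(abs(rho) > rho_threshold), note="")
            )
    report = pd.DataFrame(rows)
    flagged_vars = set()
    for _, r in report[report["flagged"]].iterrows():
        flagged_vars.update((r["var_a"], r["var_b"]))
    if flagged_vars:
        keep = "colony_size" if "colony_size" in flagged_vars else sorted(flagged_vars)[0]
        rec = f"correlated set {sorted(flagged_vars)}; retain {keep!r}"
    else:
        rec = "no pair exceeds the threshold; retain all"
    report.attrs["recommendation"] = rec
    return report


def colony_trait_summaries(trials: pd.DataFrame, value_col: str = "z_value") -> pd.DataFrame:
    """Per-colony mean and SD of each individual-level trait.

    A colony needs at least two workers' worth of trials per assay for the
    SD to be defined.
    """
    g = trials.groupby(["colony_id", "assay"])[value_col]
    n_ind = trials.groupby(["colony_id", "assay"])["individual_id"].nunique()
    if (n_ind < 2).any():
        bad = n_ind[n_ind < 2].index[0]
        raise ValidationError(
            f"colony {bad[0]!r} has fewer than 2 individuals for assay {bad[1]!r}; "
            "trait SD undefined (minimum group size 2)"
        )
    summ = g.agg(["mean", "std"]).unstack("assay")
    summ.columns = [f"{'sd' if stat == 'std' else stat}_{assay}" for stat, assay in summ.columns]
    return summ.reset_index()
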