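"""Reproductive-success aggregation and cognition-fitness model sets.

Breeding attempts are attributed to the dominant pair holding the group
at the time of the attempt.  Per individual-year records accumulate the
three reproduction measures — fledglings produced, fledglings surviving
to independence (90 days post-hatch), and fledglings recruited (1 year) —
with explicit zero rows for dominant-tenure years without breeding
success.  Missing recruitment outcomes stay missing (never coerced to
zero) and drop the row from the recruitment model set only.

Each reproduction measure gets its own candidate set of Poisson mixed
models with crossed year and individual random intercepts: the null
model, single-term models for GCP, age, sex, group size and drought, and
the GCP-by-sex interaction.  Group identity is deliberately not a random
term in these models (with few groups and repeated dominants it produces
singular fits); pass ``random_terms`` to swap it in as a robustness check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cogbattery.mixed import (
    ModelFit,
    ModelSpec,
    MixedModelError,
    build_candidate_set,
    coefficient_table,
    fit_mixed,
    scale_predictors,
    select_top_models,
)

MEASURES = ("fledglings", "independents", "recruits")


class FitnessError(ValueError):
    """Invalid input to a fitness-analysis operation."""


def aggregate_reproduction(
    attempts: pd.DataFrame, tenure: pd.DataFrame
) -> pd.DataFrame:
    """Cumulate breeding attempts into per individual-year records.

    Parameters
    ----------
    attempts
        One row per breeding attempt: ``individual_id``, ``year`` and any
        of ``fledglings``, ``independents``, ``recruits`` (counts; a
        missing recruitment outcome may be NaN).
    tenure
        One row per dominant individual-year: ``individual_id``, ``year``
        plus the covariates to carry through (e.g. age, sex, group_size,
        drought).  Defines which individual-years exist; tenure years with
        no attempt become explicit zero rows.

    Raises
    ------
    FitnessError
        If an attempt references an individual-year not present in the
        tenure table (attempts must belong to dominants).
    """
    for col in ("individual_id", "year"):
        if col not in attempts.columns or col not in tenure.columns:
            raise FitnessError(f"both tables need column {col!r}")
    key = ["individual_id", "year"]
    tenure_keys = set(map(tuple, tenure[key].itertuples(index=False)))
    attempt_keys = set(map(tuple, attempts[key].itertuples(index=False)))
    orphans = attempt_keys - tenure_keys
    if orphans:
        raise FitnessError(
            f"attempts attributed to non-dominant individual-years: {sorted(orphans)}"
        )
    measures = [m for m in MEASURES if m in attempts.columns]
    if not measures:
        raise FitnessError(f"attempts table has none of {MEASURES}")
    # cumulative within year; a NaN outcome poisons the yearly sum (stays missing)
    sums = attempts.groupby(key)[measures].sum(min_count=1).reset_index()
    out = tenure.merge(sums, on=key, how="left")
    for m in measures:
        # tenure years without any attempt are true zeroes
        no_attempt = ~out.set_index(key).index.isin(attempt_keys)
        out.loc[no_attempt, m] = out.loc[no_attempt, m].fillna(0)
    present = [m for m in measures]
    complete = out[present].dropna()
    if {"fledglings", "independents"}.issubset(complete.columns):
        if (complete["independents"] > complete["fledglings"]).any():
            raise FitnessError("independents exceed fledglings in aggregated records")
    if {"independents", "recruits"}.issubset(complete.columns):
        if (complete["recruits"] > complete["independents"]).any():
            raise FitnessError("recruits exceed independents in aggregated records")
    return out


def mean_fledglings_since_age2(records: pd.DataFrame) -> pd.Series:
    """Per-individual mean yearly fledgling count over years at age >= 2.

    Two is the earliest breeding age in the study system, so younger
    individual-years are excluded before averaging.  Individuals with no
    eligible years get NaN.
    """
    if "age" not in records.columns:
        raise FitnessError("records need an 'age' column")
    eligible = records[records["age"] >= 2]
    means = eligible.groupby("individual_id")["fledglings"].mean()
    all_ids = records["individual_id"].unique()
    return means.reindex(all_ids).rename("mean_fledglings")


def age_sex_trend(records: pd.DataFrame) -> pd.DataFrame:
    """Age-by-sex trend in per-individual mean fledglings per year.

    A gaussian linear model of per-individual mean fledglings (since age
    2) on age, sex and their interaction — an approximation for checking
    whether the attributes that shape cognition also track average
    reproductive output.  Age here is the individual's mean age over its
    eligible years, standardized.
    """
    import statsmodels.formula.api as smf

    eligible = records[records["age"] >= 2]
    per_ind = (
        eligible.groupby("individual_id")
        .agg(
            mean_fledglings=("fledglings", "mean"),
            age=("age", "mean"),
            sex=("sex", "first"),
        )
        .reset_index()
    )
    per_ind = scale_predictors(per_ind, ["age"])
    fit = smf.ols("mean_fledglings ~ age * sex", data=per_ind).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )


def run_fitness_models(
    records: pd.DataFrame,
    gcp: pd.Series,
    measure: str = "fledglings",
    random_terms: tuple[str, ...] = ("year", "individual_id"),
) -> tuple[pd.DataFrame, pd.DataFrame, list[ModelFit]]:
    """AICc-ranked Poisson mixed models for one reproduction measure.

    Candidate set: null, GCP, age, sex, group size, drought, and GCP x
    sex.  Continuous predictors (GCP, age, group size) are standardized;
    rows missing the chosen measure are dropped from this set only.
    Returns (selection table, coefficient table for top-set members,
    fitted models).
    """
    if measure not in MEASURES:
        raise FitnessError(f"measure must be one of {MEASURES}, got {measure!r}")
    if measure not in records.columns:
        raise FitnessError(f"records lack the {measure!r} column")
    data = records.copy()
    data["gcp"] = data["individual_id"].map(gcp)
    if data["gcp"].isna().any():
        missing = data.loc[data["gcp"].isna(), "individual_id"].unique().tolist()
        raise FitnessError(f"no GCP value for individuals {missing}")
    data = data.dropna(subset=[measure])
    data[measure] = data[measure].astype(int)
    data = scale_predictors(data, ["gcp", "age", "group_size"])
    specs = build_candidate_set(
        single_terms=["gcp", "age", "sex", "group_size", "drought"],
        interaction_pool=["gcp", "sex"],
        response=measure,
        random_terms=random_terms,
        family="poisson",
    )
    fits = [fit_mixed(spec, data) for spec in specs]
    selection = select_top_models(fits)
    coefs = coefficient_table(fits, selection)
    return selection, coefs, fits
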