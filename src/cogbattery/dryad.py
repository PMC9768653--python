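"""Loading and re-analysis of the deposited pied babbler dataset.

The study's field data are deposited in the Dryad Digital Repository
(doi:10.5061/dryad.d51c5b06v).  This module does not download anything:
place the deposited tables, exported to the schema below, under a local
directory and point :func:`reproduce_published_analysis` at it.

Expected files
--------------
``scores.csv``
    One row per tested individual: ``individual_id``, ``associative``,
    ``reversal``, ``inhibitory`` (trials-to-criterion, 6-120).
``attributes.csv``
    One row per individual: ``individual_id``, ``sex`` (female/male, may
    be missing), ``age``, ``group_id`` plus any further covariates.
``breeding.csv``
    One row per dominant individual-year: ``individual_id``, ``year``,
    ``age``, ``sex``, ``group_size``, ``fledglings``, ``independents``,
    ``recruits`` (NaN where unrecorded), ``drought`` (0/1).
``scores_replicate.csv`` (optional)
    Second-battery scores for retested individuals, same schema as
    ``scores.csv``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from cogbattery.gcp import extract_gcp, permutation_null, repeatability, spearman_pairs
from cogbattery.mixed import ModelSpec, fit_mixed, scale_predictors
from cogbattery.fitness import run_fitness_models


class DryadDataError(FileNotFoundError):
    """The deposited dataset is not available at the given path."""


def load_deposited(data_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load the deposited tables from ``data_dir`` (schema in module docstring)."""
    data_dir = Path(data_dir)
    required = ["scores.csv", "attributes.csv", "breeding.csv"]
    missing = [f for f in required if not (data_dir / f).exists()]
    if missing:
        raise DryadDataError(
            f"deposited dataset not found under {data_dir} (missing {missing}); "
            "download doi:10.5061/dryad.d51c5b06v and export tables to the "
            "schema documented in cogbattery.dryad"
        )
    out = {
        "scores": pd.read_csv(data_dir / "scores.csv", index_col="individual_id"),
        "attributes": pd.read_csv(data_dir / "attributes.csv"),
        "breeding": pd.read_csv(data_dir / "breeding.csv"),
    }
    rep = data_dir / "scores_replicate.csv"
    if rep.exists():
        out["scores_replicate"] = pd.read_csv(rep, index_col="individual_id")
    return out


def reproduce_published_analysis(data_dir: str | Path, seed: int = 0) -> dict:
    """Re-run the headline analyses on the deposited data.

    Returns a dictionary with the PCA loadings and percent variance, the
    associative-reversal Spearman correlation, repeatability R (when
    replicate scores are present), the female age slope on GCP, and the
    GCP coefficient from the yearly-fledglings Poisson model set.
    """
    tables = load_deposited(data_dir)
    scores = tables["scores"]
    res = extract_gcp(scores)
    null = permutation_null(scores, n_sims=10_000, seed=seed)
    corr = {
        (c.task_a, c.task_b): c.rho for c in spearman_pairs(scores)
    }
    out = {
        "pc1_loadings": dict(zip(res.tasks, res.pc1_loadings.round(4))),
        "eigenvalue_pc1": float(res.eigenvalues[0]),
        "pct_variance_pc1": res.pct_variance_pc1,
        "rho_associative_reversal": corr.get(("associative", "reversal")),
        "loading_mean": res.loading_mean,
        "loading_sd": res.loading_sd,
        "mean_above_null_ci": null.mean_above_ci,
    }

    attrs = tables["attributes"].merge(
        res.gcp.rename("gcp").reset_index(), on="individual_id"
    )
    attrs = attrs.dropna(subset=["sex"])
    attrs = scale_predictors(attrs, ["age"])
    # female age slope: age x sex model with female as the reference level
    fit = fit_mixed(
        ModelSpec(
            response="gcp",
            fixed_terms=("age", "sex", "age:sex"),
            random_terms=("group_id",),
            family="gaussian",
        ),
        attrs,
    )
    out["female_age_slope"] = float(fit.coefficients.loc["age", "estimate"])
    out["female_age_slope_se"] = float(fit.coefficients.loc["age", "se"])

    sel, coefs, _ = run_fitness_models(
        tables["breeding"], res.gcp, measure="fledglings"
    )
    gcp_rows = coefs[(coefs["model"] == "gcp") & (coefs["term"] == "gcp")]
    if not gcp_rows.empty:
        out["gcp_fledgling_coefficient"] = float(gcp_rows["estimate"].iloc[0])
        out["gcp_fledgling_se"] = float(gcp_rows["se"].iloc[0])

    if "scores_replicate" in tables:
        rep_scores = tables["scores_replicate"]
        both = scores.index.intersection(rep_scores.index)
        gcp2 = extract_gcp(rep_scores.loc[both]).gcp
        long = pd.concat(
            [
                res.gcp.loc[both].rename("gcp").reset_index(),
                gcp2.rename("gcp").reset_index(),
            ]
        )
        out["repeatability_R"] = repeatability(long, seed=seed).R
    return out
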