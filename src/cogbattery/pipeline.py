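"""End-to-end orchestration: from trial data to every report table.

``run_full_pipeline`` composes the library stages — scoring, GCP
extraction with its permutation null, determinant model selection,
fitness model sets, and (when battery replicates are present)
repeatability — and writes each result as a CSV plus a human-readable
summary.  A manifest records package versions, seeds, record counts
after every filter, and a hash of the configuration, so a run is a pure
function of (inputs, config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import cogbattery
from cogbattery.scoring import CriterionSpec, build_score_matrix, score_summary
from cogbattery.gcp import extract_gcp, permutation_null, repeatability, spearman_pairs
from cogbattery.mixed import (
    build_candidate_set,
    coefficient_table,
    fit_mixed,
    scale_predictors,
    select_top_models,
)
from cogbattery.fitness import MEASURES, run_fitness_models


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


#: candidate terms for the GCP-determinants stage
DETERMINANT_SINGLE_TERMS = [
    "age",
    "sex",
    "rank",
    "group_size",
    "latency",
    "inter_trial_interval",
    "body_mass",
    "foraging_efficiency",
    "testing_order",
    "time_of_day",
    "study_year",
]
DETERMINANT_POOL = ["sex", "age", "rank", "group_size", "body_mass", "study_year"]
CONTINUOUS_COVARIATES = [
    "age",
    "group_size",
    "latency",
    "inter_trial_interval",
    "body_mass",
    "foraging_efficiency",
    "testing_order",
]


@dataclass
class RunConfig:
    """Inputs, criterion, seeds and output location for a pipeline run."""

    trials_csv: str | Path
    roster_csv: str | Path
    breeding_csv: str | Path | None = None
    replicate_trials_csv: str | Path | None = None
    outdir: str | Path = "cogbattery_out"
    run_length: int = 6
    cap: int = 120
    n_sims: int = 10_000
    seed: int = 0
    criterion_fit: str = "ml"  # ml | reml (variance reporting only)

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, na_rep="NA")


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle to ``outdir``.

    Returns a dictionary of the in-memory results.  Any stage failure is
    re-raised as :class:`PipelineError` naming the stage; artifacts
    written before the failure are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    summary: list[str] = []
    stage = "load"
    try:
        trials = pd.read_csv(config.trials_csv)
        roster = pd.read_csv(config.roster_csv)
        roster["study_year"] = roster["study_year"].astype(str)
        summary.append(
            f"loaded {len(trials)} trial rows, {len(roster)} roster rows"
        )

        stage = "scoring"
        spec = CriterionSpec(run_length=config.run_length, cap=config.cap)
        scores = build_score_matrix(trials, spec)
        _write(scores, out / "scores.csv", index=True)
        results["scores"] = scores
        summary.append(
            f"scored {len(scores)} individuals; per-task summary:\n"
            f"{score_summary(scores).round(2)}"
        )

        stage = "gcp"
        correlations = spearman_pairs(scores)
        gcp_res = extract_gcp(scores)
        null_res = permutation_null(scores, n_sims=config.n_sims, seed=config.seed)
        gcp_df = gcp_res.gcp.rename("gcp").reset_index()
        _write(gcp_df, out / "gcp.csv")
        report = {
            "eigenvalues": [round(float(v), 6) for v in gcp_res.eigenvalues],
            "pc1_loadings": dict(
                zip(gcp_res.tasks, np.round(gcp_res.pc1_loadings, 6).tolist())
            ),
            "pct_variance_pc1": round(gcp_res.pct_variance_pc1, 4),
            "loading_mean": round(gcp_res.loading_mean, 6),
            "loading_sd": round(gcp_res.loading_sd, 6),
            "spearman": [
                {"pair": f"{c.task_a}~{c.task_b}", "rho": round(c.rho, 4), "p": round(c.p, 6)}
                for c in correlations
            ],
            "permutation_null": {
                "n_sims": null_res.n_sims,
                "mean_ci": [round(v, 4) for v in null_res.mean_ci],
                "sd_ci": [round(v, 4) for v in null_res.sd_ci],
                "observed_mean": round(null_res.observed_mean, 4),
                "observed_sd": round(null_res.observed_sd, 4),
                "mean_above_ci": null_res.mean_above_ci,
                "sd_below_ci": null_res.sd_below_ci,
                "sd_within_ci": null_res.sd_within_ci,
                "seed": null_res.seed,
            },
        }
        (out / "gcp_report.json").write_text(json.dumps(report, indent=2))
        results["gcp"] = gcp_res
        results["permutation_null"] = null_res
        summary.append(
            f"PC1 explains {gcp_res.pct_variance_pc1:.2f}% of score variance; "
            f"mean loading {gcp_res.loading_mean:.2f} "
            f"(null 95% CI {null_res.mean_ci[0]:.2f}-{null_res.mean_ci[1]:.2f}; "
            f"above CI: {null_res.mean_above_ci})"
        )

        stage = "determinants"
        data = roster.merge(
            gcp_df, on="individual_id", how="inner", validate="one_to_one"
        )
        n_before = len(data)
        data = data.dropna(subset=["sex"])
        if len(data) < n_before:
            summary.append(
                f"dropped {n_before - len(data)} individuals with unknown sex"
            )
        data = scale_predictors(
            data, [c for c in CONTINUOUS_COVARIATES if data[c].nunique() > 1]
        )
        specs = build_candidate_set(
            single_terms=DETERMINANT_SINGLE_TERMS,
            additive_pool=DETERMINANT_POOL,
            interaction_pool=DETERMINANT_POOL,
            response="gcp",
            random_terms=("group_id",),
            family="gaussian",
        )
        fits, skipped = [], []
        for s in specs:
            try:
                fits.append(fit_mixed(s, data, reml=(config.criterion_fit == "reml")))
            except Exception as fit_exc:  # inestimable candidate (e.g. empty cell)
                skipped.append(f"{s.label} ({fit_exc})")
        if skipped:
            summary.append(
                f"skipped {len(skipped)} inestimable candidate models: "
                + "; ".join(skipped)
            )
        selection = select_top_models(fits)
        coefs = coefficient_table(fits, selection)
        _write(selection, out / "determinants_selection.csv")
        _write(coefs, out / "determinants_coefficients.csv")
        results["determinants"] = (selection, coefs)
        top = selection.loc[selection["in_top_set"], "model"].tolist()
        summary.append(
            f"determinant selection over {len(specs)} candidates "
            f"(n={len(data)}); top model set: {top or 'none'}"
        )

        if config.breeding_csv is not None:
            stage = "fitness"
            breeding = pd.read_csv(config.breeding_csv)
            for measure in MEASURES:
                if measure not in breeding.columns:
                    continue
                sel, cf, _ = run_fitness_models(breeding, gcp_res.gcp, measure)
                _write(sel, out / f"fitness_{measure}_selection.csv")
                _write(cf, out / f"fitness_{measure}_coefficients.csv")
                results[f"fitness_{measure}"] = (sel, cf)
                top = sel.loc[sel["in_top_set"], "model"].tolist()
                summary.append(
                    f"fitness ({measure}, n={int(breeding[measure].notna().sum())}): "
                    f"top model set {top or 'none'}"
                )

        if config.replicate_trials_csv is not None:
            stage = "repeatability"
            rep_trials = pd.read_csv(config.replicate_trials_csv)
            rep_scores = build_score_matrix(rep_trials, spec)
            both = scores.index.intersection(rep_scores.index)
            gcp2 = extract_gcp(rep_scores.loc[both]).gcp
            long = pd.concat(
                [
                    gcp_res.gcp.loc[both].rename("gcp").reset_index(),
                    gcp2.rename("gcp").reset_index(),
                ]
            )
            rep = repeatability(long, seed=config.seed)
            (out / "repeatability.json").write_text(
                json.dumps(
                    {
                        "R": round(rep.R, 4),
                        "se": round(rep.se, 4) if rep.se is not None else None,
                        "ci": [round(v, 4) for v in rep.ci] if rep.ci else None,
                        "p": rep.p,
                        "n_individuals": rep.n_individuals,
                    },
                    indent=2,
                )
            )
            results["repeatability"] = rep
            summary.append(
                f"repeatability over {rep.n_individuals} retested individuals: "
                f"R={rep.R:.2f}, 95% CI {rep.ci[0]:.2f}-{rep.ci[1]:.2f}, p={rep.p:.3f}"
            )

        stage = "manifest"
        import scipy
        import statsmodels

        manifest = {
            "cogbattery": cogbattery.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config_hash": config.digest(),
            "config": {k: str(v) for k, v in asdict(config).items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "summary.txt").write_text("\n\n".join(summary) + "\n")
    except Exception as exc:  # noqa: BLE001 - stage context matters more
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    results["summary"] = summary
    return results
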