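"""Synthetic cohorts, trial-level battery data and breeding histories.

The generator produces data with the structure of a wild cooperative
breeder cognition study: group-living individuals (each group holding
exactly one dominant pair), three learning tasks per individual scored as
trials-to-criterion, and multi-year breeding records for dominants.  All
effect sizes are known ground truth, so every downstream stage of the
pipeline can be validated by parameter recovery.

Generative model
----------------
Each individual carries a latent general cognitive factor ``g`` drawn
N(0, g_sd²), shifted for females by ``female_age_slope`` per standard
deviation of age (males have no age trend) — the age-by-sex structure
reported for wild pied babblers.  Task performance follows a saturating
learning curve: on trial t the probability of a correct choice is

    p_t = 0.5 + 0.49 * (1 - exp(-(r * t) ** learning_shape)),

rising from chance 0.5 toward an asymptote of 0.99 (never 1, so censoring
at the trial cap occurs with positive probability).  The shape exponent
(default 4) gives the curve an onset lag around t = 1/r before a steep
rise — an S-shaped acquisition curve; with a shape of 1 the curve is the
memoryless pure exponential, under which early-trial randomness swamps
the individual's rate and little of the latent factor survives into the
score.  The per-individual, per-task learning rate is

    log r = learning_base_rate[task]
            + latent_link_gain * task_loading[task] * g + N(0, noise_sd).

The latent factor enters through the log learning rate so task loadings
act multiplicatively on learning speed, the simplest link that yields
positive cross-task score correlations.  ``latent_link_gain`` sets the
scale of that link (log-rate change per unit of loading x g); its default
is calibrated so that at reference loadings of 0.8 the synthetic battery
reproduces the shared-variance level observed in the real study (first
principal component near 60% of score variance).  This learning-curve family is a
generative stand-in chosen for monotone learning with a single rate
parameter; it is not a claim about the birds' learning mechanism.

Breeding: only dominants breed.  Yearly fledgling counts are Poisson on a
log link with a per-s.d.-GCP effect ``beta_gcp`` and crossed year and
individual random intercepts; survival of fledglings to independence is
binomial with a logit drought penalty, and recruitment a further binomial
thinning.  Drought is a yearly Bernoulli flag (the rainfall threshold that
defines a drought season is metadata, not simulated weather).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from cogbattery.scoring import TASKS, TrialSequence


class SimulationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for one synthetic study.

    Defaults emulate the pied babbler study conditions: 38 tested adults,
    groups of 2-7 with one dominant pair each, ages 1-13 years, a latent
    factor with unit dispersion loading 0.8 on each task, a female-only
    age decline of -0.77 s.d. of g per s.d. of age, and a -0.18
    per-s.d.-GCP effect on log yearly fledglings.  ``learning_base_rate``
    values (log learning rate per task; onset near 1/rate trials) are
    calibrated so mean trials-to-criterion sit in the published battery's
    range (roughly mid-30s for the associative and inhibitory tasks,
    slower for reversal) while the battery retains enough signal for the
    latent factor to be recoverable from the extracted GCP.
    """

    n_individuals: int = 38
    n_groups: int = 12
    group_size_range: tuple[int, int] = (2, 7)
    sex_ratio: float = 0.5
    age_range: tuple[int, int] = (1, 13)
    g_sd: float = 1.0
    task_loadings: tuple[float, float, float] = (0.8, 0.8, 0.8)
    female_age_slope: float = -0.77
    learning_base_rate: tuple[float, float, float] = (-3.33, -4.01, -3.22)
    latent_link_gain: float = 1.2
    learning_shape: float = 4.0
    noise_sd: float = 0.25
    beta0_fledge: float = 0.4
    beta_gcp: float = -0.18
    sigma_year: float = 0.3
    sigma_id: float = 0.3
    p_drought: float = 0.3
    drought_logit_effect: float = -1.0
    independence_base_logit: float = 0.5
    recruit_survival: float = 0.5
    n_years: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("g_sd", "noise_sd", "sigma_year", "sigma_id"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not all(np.isfinite(self.task_loadings)):
            raise SimulationError("task_loadings must be finite")
        lo, hi = self.group_size_range
        if not (1 <= lo <= hi):
            raise SimulationError("invalid group_size_range")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise SimulationError("sex_ratio must be in [0, 1]")
        if not (0.0 <= self.p_drought <= 1.0):
            raise SimulationError("p_drought must be in [0, 1]")
        if self.age_range[0] < 1 or self.age_range[0] > self.age_range[1]:
            raise SimulationError("ages must be >= 1 and range ordered")

    def ground_truth(self) -> dict:
        """Parameter dictionary for recovery tests / the JSON sidecar."""
        return asdict(self)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per pipeline stage
    return np.random.default_rng([config.seed, stream])


def simulate_roster(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a group-structured roster with a latent general factor per individual.

    Every group receives exactly one dominant female and one dominant male
    (dominants at least 2 years old, the earliest breeding age); remaining
    individuals are subordinates with sex drawn by ``sex_ratio``.  The
    latent factor ``g_true`` is N(0, g_sd²) plus, for females only,
    ``female_age_slope`` times the standardized age.

    Raises
    ------
    SimulationError
        If the roster cannot host one dominant pair per group or exceed
        the group-size range.
    """
    lo, hi = config.group_size_range
    n, G = config.n_individuals, config.n_groups
    if n < 2 * G or n < lo * G:
        raise SimulationError(
            f"{n} individuals cannot fill {G} groups with a dominant pair each"
        )
    if n > hi * G:
        raise SimulationError(f"{n} individuals exceed {G} groups of at most {hi}")
    rng = _rng(config, 1)
    sizes = np.full(G, max(lo, 2))
    for _ in range(n - sizes.sum()):
        open_groups = np.flatnonzero(sizes < hi)
        sizes[rng.choice(open_groups)] += 1

    amin, amax = config.age_range
    rows = []
    years = np.array([2018, 2019, 2021])
    for gi, size in enumerate(sizes):
        group_id = f"G{gi + 1:02d}"
        study_year = int(rng.choice(years))
        order = rng.permutation(size) + 1
        for j in range(size):
            dominant = j < 2
            if dominant:
                sex = "female" if j == 0 else "male"
                age = int(rng.integers(max(amin, 2), amax + 1))
            else:
                sex = "female" if rng.random() < config.sex_ratio else "male"
                age = int(rng.integers(amin, amax + 1))
            rows.append(
                {
                    "individual_id": f"{group_id}-{j + 1:02d}",
                    "sex": sex,
                    "age": age,
                    "rank": "dominant" if dominant else "subordinate",
                    "group_id": group_id,
                    "group_size": int(size),
                    "body_mass": float(rng.normal(75.0, 6.0)),
                    "foraging_efficiency": float(
                        max(rng.normal(0.15, 0.04), 0.01)
                    ),
                    "latency": float(np.exp(rng.normal(3.5, 0.8))),
                    "inter_trial_interval": float(np.exp(rng.normal(0.9, 0.4))),
                    "testing_order": int(order[j]),
                    "time_of_day": "before-0900" if rng.random() < 0.5 else "after-0900",
                    "study_year": study_year,
                }
            )
    roster = pd.DataFrame(rows)
    age = roster["age"].to_numpy(dtype=float)
    z_age = (age - age.mean()) / age.std(ddof=1)
    g = rng.normal(0.0, config.g_sd, size=len(roster))
    g = g + np.where(
        roster["sex"].to_numpy() == "female", config.female_age_slope * z_age, 0.0
    )
    roster["g_true"] = g
    return roster


def simulate_trials(
    roster: pd.DataFrame, config: SyntheticConfig, replicate: int = 0
) -> list[TrialSequence]:
    """Simulate the three-task battery for every individual in the roster.

    Returns one :class:`TrialSequence` per individual x task, terminated
    at the first run of six correct choices or at 120 trials.  Pass a
    different ``replicate`` index to draw an independent battery for the
    same roster (same latent factors, fresh task noise and trial
    outcomes) — the ingredient for repeatability analyses.
    """
    if roster.empty:
        raise SimulationError("roster is empty")
    rng = _rng(config, 10 + replicate)
    cap, run_needed = 120, 6
    sequences: list[TrialSequence] = []
    for _, row in roster.iterrows():
        for ti, task in enumerate(TASKS):
            log_r = (
                config.learning_base_rate[ti]
                + config.latent_link_gain * config.task_loadings[ti] * row["g_true"]
                + rng.normal(0.0, config.noise_sd)
            )
            r = np.exp(log_r)
            outcomes = []
            run = 0
            for t in range(1, cap + 1):
                p = 0.5 + 0.49 * (1.0 - np.exp(-((r * t) ** config.learning_shape)))
                correct = int(rng.random() < p)
                outcomes.append(correct)
                run = run + 1 if correct else 0
                if run >= run_needed:
                    break
            sequences.append(
                TrialSequence(
                    individual_id=row["individual_id"],
                    task=task,
                    outcomes=tuple(outcomes),
                    cap=cap,
                )
            )
    return sequences


def simulate_breeding(
    roster: pd.DataFrame, gcp: pd.Series, config: SyntheticConfig
) -> pd.DataFrame:
    """Multi-year breeding histories for the dominant individuals.

    Yearly fledgling counts are Poisson with log mean
    ``beta0_fledge + beta_gcp * z(gcp) + u_year + u_individual``; years
    without success appear as explicit zero rows.  Independents are a
    binomial thinning of fledglings with a logit drought penalty, and
    recruits a further binomial thinning at ``recruit_survival``.
    """
    rng = _rng(config, 50)
    dominants = roster[roster["rank"] == "dominant"].copy()
    if dominants.empty:
        raise SimulationError("roster has no dominant individuals")
    z = gcp.loc[dominants["individual_id"]].to_numpy(dtype=float)
    z = (z - z.mean()) / z.std(ddof=1) if z.std(ddof=1) > 0 else z * 0.0
    u_year = rng.normal(0.0, config.sigma_year, size=config.n_years)
    drought = (rng.random(config.n_years) < config.p_drought).astype(int)
    u_id = rng.normal(0.0, config.sigma_id, size=len(dominants))
    rows = []
    for i, (_, ind) in enumerate(dominants.iterrows()):
        for y in range(config.n_years):
            lam = np.exp(
                config.beta0_fledge + config.beta_gcp * z[i] + u_year[y] + u_id[i]
            )
            fledglings = int(rng.poisson(lam))
            p_ind = 1.0 / (
                1.0
                + np.exp(
                    -(
                        config.independence_base_logit
                        + config.drought_logit_effect * drought[y]
                    )
                )
            )
            independents = int(rng.binomial(fledglings, p_ind)) if fledglings else 0
            recruits = (
                int(rng.binomial(independents, config.recruit_survival))
                if independents
                else 0
            )
            rows.append(
                {
                    "individual_id": ind["individual_id"],
                    "year": f"season{y + 1:02d}",
                    "age": int(ind["age"]) + y,
                    "sex": ind["sex"],
                    "group_id": ind["group_id"],
                    "group_size": int(ind["group_size"]),
                    "fledglings": fledglings,
                    "independents": independents,
                    "recruits": recruits,
                    "drought": int(drought[y]),
                }
            )
    return pd.DataFrame(rows)


def trials_to_frame(sequences: list[TrialSequence]) -> pd.DataFrame:
    """Long trial table (individual_id, task, trial, correct) from sequences."""
    rows = []
    for seq in sequences:
        for t, c in enumerate(seq.outcomes, start=1):
            rows.append(
                {
                    "individual_id": seq.individual_id,
                    "task": seq.task,
                    "trial": t,
                    "correct": c,
                }
            )
    return pd.DataFrame(rows)
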