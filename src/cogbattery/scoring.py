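"""Trials-to-criterion scoring and chance-level analytics for run criteria.

A learning test presents a sequence of binary trials (1 = correct choice,
0 = incorrect).  An individual passes when it produces ``run_length``
consecutive correct choices; its score is the number of trials taken up to
and including the final trial of that run, so the best possible score
equals ``run_length``.  Tests are stopped (censored) at ``cap`` trials and
scored as ``cap``.

``chance_pass_probability`` gives the exact probability that a random
chooser (Bernoulli with success probability ``chance_p``) passes within a
given number of trials, computed by dynamic programming over the current
run length.  At ``n_trials == run_length`` it reduces to
``chance_p ** run_length`` — e.g. six-in-a-row at chance 0.5 has
probability 0.015625 (p = 0.016 to three decimals), the usual
justification for a six-correct criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TASKS = ("associative", "reversal", "inhibitory")


class ScoringError(ValueError):
    """Invalid input to a scoring operation."""


@dataclass(frozen=True)
class CriterionSpec:
    """Passing criterion: a run of ``run_length`` correct choices within ``cap`` trials."""

    run_length: int = 6
    cap: int = 120
    chance_p: float = 0.5

    def __post_init__(self) -> None:
        if not (1 <= self.run_length <= self.cap):
            raise ScoringError(
                f"run_length must satisfy 1 <= run_length <= cap, got "
                f"run_length={self.run_length}, cap={self.cap}"
            )
        if not (0.0 < self.chance_p < 1.0):
            raise ScoringError(f"chance_p must be in (0, 1), got {self.chance_p}")


@dataclass(frozen=True)
class TrialSequence:
    """Ordered binary outcomes for one individual on one task."""

    individual_id: str
    task: str
    outcomes: tuple[int, ...]
    cap: int = 120

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(int(o) for o in self.outcomes))
        if any(o not in (0, 1) for o in self.outcomes):
            raise ScoringError("trial outcomes must be 0 or 1")
        if len(self.outcomes) > self.cap:
            raise ScoringError(
                f"sequence length {len(self.outcomes)} exceeds cap {self.cap}"
            )


def trials_to_criterion(
    seq: TrialSequence | Sequence[int], spec: CriterionSpec = CriterionSpec()
) -> tuple[int, bool]:
    """Score one trial sequence.

    Returns ``(score, censored)`` where ``score`` is the 1-based index of
    the final trial of the first run of ``spec.run_length`` consecutive
    correct choices, or ``spec.cap`` with ``censored=True`` if no such run
    occurs by the cap.

    Raises
    ------
    ScoringError
        If the sequence is empty.
    """
    outcomes = seq.outcomes if isinstance(seq, TrialSequence) else tuple(int(o) for o in seq)
    if len(outcomes) == 0:
        raise ScoringError("cannot score an empty trial sequence")
    run = 0
    for t, outcome in enumerate(outcomes, start=1):
        run = run + 1 if outcome == 1 else 0
        if run >= spec.run_length:
            return t, False
    return spec.cap, True


def chance_pass_probability(spec: CriterionSpec, n_trials: int) -> float:
    """Exact probability that a Bernoulli(``chance_p``) chooser passes within ``n_trials``.

    Dynamic programming over the state "current run length" (0 ..
    run_length-1, plus an absorbing passed state).  Exact up to floating
    point; equals ``chance_p ** run_length`` at ``n_trials == run_length``
    and is non-decreasing in ``n_trials`` and ``chance_p``.
    """
    if n_trials < 1:
        raise ScoringError("n_trials must be >= 1")
    r, p = spec.run_length, spec.chance_p
    # state[j] = P(current run of exactly j correct, not yet passed)
    state = np.zeros(r)
    state[0] = 1.0
    passed = 0.0
    for _ in range(n_trials):
        advanced = state * p
        passed += advanced[-1]
        new = np.zeros(r)
        new[1:] = advanced[:-1]
        new[0] = state.sum() * (1.0 - p)
        state = new
    return float(passed)


def _sequences_from_frame(trials: pd.DataFrame, cap: int) -> list[TrialSequence]:
    """Assemble TrialSequence objects from a long trial table.

    Expects columns ``individual_id``, ``task``, ``trial`` (1-based order)
    and ``correct`` (0/1).
    """
    required = {"individual_id", "task", "trial", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ScoringError(f"trial table missing columns: {sorted(missing)}")
    out = []
    for (ind, task), grp in trials.groupby(["individual_id", "task"], sort=True):
        grp = grp.sort_values("trial")
        out.append(
            TrialSequence(
                individual_id=str(ind),
                task=str(task),
                outcomes=tuple(int(c) for c in grp["correct"]),
                cap=cap,
            )
        )
    return out


def build_score_matrix(
    sequences: Iterable[TrialSequence] | pd.DataFrame,
    spec: CriterionSpec = CriterionSpec(),
) -> pd.DataFrame:
    """Score a collection of trial sequences into an individuals x tasks matrix.

    Returns a DataFrame indexed by individual with one column per task
    holding trials-to-criterion scores, plus boolean ``censored_<task>``
    columns.  Individuals missing any task keep NaN in that cell.

    Raises
    ------
    ScoringError
        If the same individual x task combination appears twice.
    """
    if isinstance(sequences, pd.DataFrame):
        sequences = _sequences_from_frame(sequences, cap=spec.cap)
    seen: set[tuple[str, str]] = set()
    rows: dict[str, dict[str, object]] = {}
    tasks_present: list[str] = []
    for seq in sequences:
        key = (seq.individual_id, seq.task)
        if key in seen:
            raise ScoringError(f"duplicate record for individual {key[0]!r}, task {key[1]!r}")
        seen.add(key)
        if seq.task not in tasks_present:
            tasks_present.append(seq.task)
        score, censored = trials_to_criterion(seq, spec)
        rows.setdefault(seq.individual_id, {})[seq.task] = score
        rows[seq.individual_id][f"censored_{seq.task}"] = censored
    if not rows:
        raise ScoringError("no trial sequences supplied")
    # keep canonical battery order where applicable
    ordered = [t for t in TASKS if t in tasks_present]
    ordered += [t for t in tasks_present if t not in ordered]
    mat = pd.DataFrame.from_dict(rows, orient="index")
    cols = ordered + [f"censored_{t}" for t in ordered]
    mat = mat.reindex(columns=cols)
    mat.index.name = "individual_id"
    for t in ordered:
        mat[f"censored_{t}"] = mat[f"censored_{t}"].fillna(False).astype(bool)
    return mat.sort_index()


def score_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-task mean, min, max and censoring count of a score matrix."""
    tasks = [c for c in matrix.columns if not c.startswith("censored_")]
    return pd.DataFrame(
        {
            "mean": matrix[tasks].mean(),
            "min": matrix[tasks].min(),
            "max": matrix[tasks].max(),
            "n_censored": [int(matrix[f"censored_{t}"].sum()) for t in tasks],
            "n": matrix[tasks].notna().sum(),
        }
    )
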