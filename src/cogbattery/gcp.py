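"""General cognitive performance (GCP): PCA extraction, permutation null, repeatability.

Individual scores on a battery of learning tasks (trials-to-criterion,
lower = better) tend to correlate positively.  The first unrotated
principal component of the standardized score matrix summarizes this
shared axis; GCP is the individual coordinate along PC1 with the sign
flipped, so that higher GCP means fewer trials, i.e. better performance.

Because a PCA always yields a first component, evidence that PC1 reflects
real cross-task structure comes from a within-task permutation null: each
task's scores are shuffled among individuals, the PCA re-run, and the mean
and standard deviation of the PC1 loadings recorded.  A real general
factor shows a mean loading above the null 95% interval (loadings all
high and positive) and a loading s.d. at the low end (loadings uniform
across tasks rather than dominated by one).

Repeatability (intraclass correlation R) of GCP across replicate
batteries is the between-individual share of total variance from a
one-way random-intercept decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class GCPError(ValueError):
    """Invalid input to a GCP operation."""


# ---------------------------------------------------------------------------
# cross-task correlations


@dataclass(frozen=True)
class CorrelationResult:
    task_a: str
    task_b: str
    rho: float
    p: float


def _score_columns(scores: pd.DataFrame) -> list[str]:
    return [c for c in scores.columns if not c.startswith("censored_")]


def _complete_scores(scores: pd.DataFrame) -> pd.DataFrame:
    cols = _score_columns(scores)
    sub = scores[cols]
    if sub.isna().any().any():
        missing = sub.index[sub.isna().any(axis=1)].tolist()
        raise GCPError(
            f"score matrix has incomplete batteries for individuals {missing}; "
            "drop them explicitly before analysis"
        )
    return sub.astype(float)


def spearman_pairs(scores: pd.DataFrame) -> list[CorrelationResult]:
    """Spearman rank correlation for every pair of task-score columns.

    Average ranks for ties; two-sided p from the t-distribution
    approximation (scipy's default).  Requires >= 4 complete individuals
    and no constant column.
    """
    sub = _complete_scores(scores)
    if len(sub) < 4:
        raise GCPError("need at least 4 complete individuals")
    cols = list(sub.columns)
    out = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            x, y = sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise GCPError(f"constant column among ({cols[i]}, {cols[j]})")
            rho, p = stats.spearmanr(x, y)
            out.append(CorrelationResult(cols[i], cols[j], float(rho), float(p)))
    return out


# ---------------------------------------------------------------------------
# PCA / GCP extraction


@dataclass(frozen=True)
class GCPResult:
    eigenvalues: np.ndarray  # descending
    pc1_loadings: np.ndarray  # variable-PC1 correlations
    pct_variance_pc1: float
    gcp: pd.Series  # per-individual GCP (negated PC1 coordinate)
    loading_mean: float
    loading_sd: float  # n-1 denominator
    tasks: tuple[str, ...]


def _pc1_from_corr(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and PC1 unit eigenvector, sign-oriented.

    PC1 is oriented so that the sum of its loadings is non-negative; ties
    cannot occur away from an exactly zero loading sum.
    """
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    v1 = eigvec[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    return eigval, v1


def extract_gcp(scores: pd.DataFrame) -> GCPResult:
    """Unrotated PCA of the correlation matrix of task scores.

    Columns are standardized (mean 0, s.d. 1 with the n-1 denominator);
    loadings are variable-component correlations, eigenvector *
    sqrt(eigenvalue); eigenvalues sum to the number of tasks.  GCP for
    individual i is minus the projection of its standardized score row on
    the PC1 unit eigenvector, so individuals with uniformly fewer trials
    (better learners) get higher GCP.

    Raises
    ------
    GCPError
        On missing cells (listwise deletion must be explicit), fewer than
        4 complete individuals, or a constant column.
    """
    sub = _complete_scores(scores)
    if len(sub) < 4:
        raise GCPError("need at least 4 complete individuals")
    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(sub.columns, sd) if s == 0]
        raise GCPError(f"constant score column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, v1 = _pc1_from_corr(corr)
    loadings = v1 * np.sqrt(eigval[0])
    gcp = pd.Series(-(Z @ v1), index=sub.index, name="gcp")
    return GCPResult(
        eigenvalues=eigval,
        pc1_loadings=loadings,
        pct_variance_pc1=float(eigval[0] / len(eigval) * 100.0),
        gcp=gcp,
        loading_mean=float(loadings.mean()),
        loading_sd=float(loadings.std(ddof=1)),
        tasks=tuple(sub.columns),
    )


# ---------------------------------------------------------------------------
# within-task permutation null for PC1 loadings


@dataclass(frozen=True)
class PermutationNullResult:
    n_sims: int
    mean_ci: tuple[float, float]
    sd_ci: tuple[float, float]
    observed_mean: float
    observed_sd: float
    mean_above_ci: bool
    sd_below_ci: bool
    sd_within_ci: bool
    seed: int


def _null_loading_stats(
    Z: np.ndarray, n_sims: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and s.d. of oriented PC1 loadings for ``n_sims`` within-column shuffles.

    Vectorized: permutations are drawn for all simulations, correlation
    matrices and 3x3 (k x k) eigen-decompositions computed in batch.  Each
    simulation is mathematically identical to shuffling every column of the
    score matrix independently and calling ``extract_gcp``.
    """
    n, k = Z.shape
    # permute each column independently within each simulation
    perm = np.empty((n_sims, n, k), dtype=Z.dtype)
    for j in range(k):
        idx = np.argsort(rng.random((n_sims, n)), axis=1)
        perm[:, :, j] = Z[idx, j]
    # standardize permuted columns (means/sds unchanged by permutation, but
    # recompute for exactness) and form correlation matrices in batch
    mu = perm.mean(axis=1, keepdims=True)
    sd = perm.std(axis=1, ddof=1, keepdims=True)
    P = (perm - mu) / sd
    corr = np.einsum("sni,snj->sij", P, P) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)  # ascending per batch
    lam1 = eigval[:, -1]
    v1 = eigvec[:, :, -1]
    sign = np.where(v1.sum(axis=1) < 0, -1.0, 1.0)
    loadings = v1 * sign[:, None] * np.sqrt(lam1)[:, None]
    return loadings.mean(axis=1), loadings.std(axis=1, ddof=1)


def permutation_null(
    scores: pd.DataFrame,
    n_sims: int = 10_000,
    seed: int = 0,
) -> PermutationNullResult:
    """Within-task permutation null for the mean and s.d. of PC1 loadings.

    Each simulation independently permutes every task's scores among
    individuals, re-runs the correlation PCA, orients PC1 so its loading
    sum is non-negative, and records the mean and s.d. (n-1 denominator)
    of the PC1 loadings.  The 95% interval is the 2.5th-97.5th percentile
    with linear interpolation.  Verdicts: ``mean_above_ci`` (real mean
    loading exceeds the null upper bound — evidence of a shared factor)
    and ``sd_below_ci`` / ``sd_within_ci`` for the loading s.d.

    Raises
    ------
    GCPError
        If ``n_sims < 100`` (percentile estimates too unstable).
    """
    if n_sims < 100:
        raise GCPError("n_sims must be >= 100 for stable percentile bounds")
    observed = extract_gcp(scores)
    sub = _complete_scores(scores)
    X = sub.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    means, sds = _null_loading_stats(Z, n_sims, rng)
    mean_ci = tuple(np.percentile(means, [2.5, 97.5]))
    sd_ci = tuple(np.percentile(sds, [2.5, 97.5]))
    return PermutationNullResult(
        n_sims=n_sims,
        mean_ci=(float(mean_ci[0]), float(mean_ci[1])),
        sd_ci=(float(sd_ci[0]), float(sd_ci[1])),
        observed_mean=observed.loading_mean,
        observed_sd=observed.loading_sd,
        mean_above_ci=bool(observed.loading_mean > mean_ci[1]),
        sd_below_ci=bool(observed.loading_sd < sd_ci[0]),
        sd_within_ci=bool(sd_ci[0] <= observed.loading_sd <= sd_ci[1]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# repeatability (intraclass correlation)


@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    se: float | None
    ci: tuple[float, float] | None
    p: float | None
    var_between: float
    var_within: float
    n_individuals: int
    n_obs: int


def _icc_reml(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """(R, var_between, var_within) from a one-way random-intercept model.

    Balanced designs use the ANOVA decomposition, which coincides with
    REML for balanced one-way layouts (negative between-group variance
    truncated at zero).  Unbalanced designs fall back to a REML fit via
    ``statsmodels`` MixedLM.
    """
    labels, counts = np.unique(groups, return_counts=True)
    k = counts[0]
    if np.all(counts == k) and k >= 2:
        g = len(labels)
        grand = values.mean()
        group_means = np.array([values[groups == lab].mean() for lab in labels])
        ssb = k * np.sum((group_means - grand) ** 2)
        ssw = sum(
            np.sum((values[groups == lab] - m) ** 2)
            for lab, m in zip(labels, group_means)
        )
        msb = ssb / (g - 1)
        msw = ssw / (g * (k - 1))
        var_w = msw
        var_b = max((msb - msw) / k, 0.0)
    else:
        import statsmodels.api as sm

        df = pd.DataFrame({"y": values, "g": groups})
        fit = sm.MixedLM.from_formula("y ~ 1", groups="g", data=df).fit(reml=True)
        var_b = float(fit.cov_re.iloc[0, 0])
        var_w = float(fit.scale)
    total = var_b + var_w
    return (var_b / total if total > 0 else 0.0), var_b, var_w


def repeatability(
    gcp_long: pd.DataFrame,
    value_col: str = "gcp",
    id_col: str = "individual_id",
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
) -> RepeatabilityResult:
    """Repeatability R of a trait across replicate measurements.

    R = var_between / (var_between + var_within) from a one-way
    random-intercept decomposition.  Standard error and 95% CI by
    parametric bootstrap (draw individual means and residuals from the
    fitted normal components, re-estimate R); p-value by permuting
    individual labels (one-sided: how often a shuffled dataset matches or
    beats the observed R).  Set ``n_boot=0`` / ``n_perm=0`` to skip the
    resampling stages.

    Requires >= 5 individuals with >= 2 replicates each; individuals with
    a single measurement are rejected rather than silently dropped.
    """
    df = gcp_long[[id_col, value_col]].dropna()
    counts = df.groupby(id_col).size()
    if (counts < 2).any():
        single = counts.index[counts < 2].tolist()
        raise GCPError(f"individuals with a single replicate: {single}")
    if len(counts) < 5:
        raise GCPError("need >= 5 individuals with replicates")
    values = df[value_col].to_numpy(dtype=float)
    groups = df[id_col].to_numpy()
    R, var_b, var_w = _icc_reml(values, groups)

    rng = np.random.default_rng(seed)
    se = ci = None
    if n_boot:
        labels, cnt = np.unique(groups, return_counts=True)
        sim_groups = np.repeat(labels, cnt)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            means = rng.normal(0.0, np.sqrt(var_b), size=len(labels))
            sim = np.repeat(means, cnt) + rng.normal(
                0.0, np.sqrt(var_w), size=len(sim_groups)
            )
            boot[b], _, _ = _icc_reml(sim, sim_groups)
        se = float(boot.std(ddof=1))
        lo, hi = np.percentile(boot, [2.5, 97.5])
        ci = (float(lo), float(hi))

    p = None
    if n_perm:
        hits = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(groups)
            r_perm, _, _ = _icc_reml(values, shuffled)
            if r_perm >= R:
                hits += 1
        p = (hits + 1) / (n_perm + 1)

    return RepeatabilityResult(
        R=float(R),
        se=se,
        ci=ci,
        p=p,
        var_between=float(var_b),
        var_within=float(var_w),
        n_individuals=int(len(counts)),
        n_obs=int(len(df)),
    )
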