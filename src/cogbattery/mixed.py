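"""Mixed-model fitting contracts, AICc machinery and top-model-set selection.

Two families are supported, matching the two analysis stages they serve:

* ``gaussian`` — linear mixed models with a single random intercept
  (e.g. social group), fitted by maximum likelihood via
  :class:`statsmodels` MixedLM.  ML rather than REML is the default for
  ranked fits because AICc comparisons across different fixed-effect
  structures require likelihoods on the same scale; a ``reml`` switch is
  provided for variance reporting.

* ``poisson`` — Poisson mixed models with a log link and one or more
  *crossed* random intercepts (e.g. year and individual identity), fitted
  by maximizing the Laplace approximation to the marginal likelihood.
  The inner mode of the random effects is found by Newton iterations on
  the penalized Poisson log-likelihood; the outer optimization runs over
  fixed coefficients and log standard deviations.

Candidate model sets contain the intercept-only (null) model, one model
per single term, all pairwise additive combinations over a designated
pool, and all pairwise interactions (with their main effects) over an
interaction pool.  Models are ranked by AICc,

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1),

where k counts fixed coefficients plus variance components (plus the
residual variance for the gaussian family) and n is the number of
observations.  The top model set contains models within 2 dAICc of the
best whose non-intercept fixed coefficients all have 95% Wald confidence
intervals excluding zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special


class MixedModelError(ValueError):
    """Invalid input to a mixed-model operation."""


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, random intercepts, family.

    Fixed terms are patsy-style: main effects by column name, a pairwise
    interaction as ``"a:b"`` (its main effects must be present).  An empty
    ``fixed_terms`` tuple is the intercept-only null model.
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_terms: tuple[str, ...] = ()
    family: str = "gaussian"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_terms", tuple(self.random_terms))
        if self.family not in ("gaussian", "poisson"):
            raise MixedModelError(f"unknown family {self.family!r}")
        if not self.random_terms:
            raise MixedModelError("at least one random intercept term is required")
        n_inter = sum(":" in t for t in self.fixed_terms)
        if n_inter > 1:
            raise MixedModelError("at most one pairwise interaction per model")
        for t in self.fixed_terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed_terms or b not in self.fixed_terms:
                    raise MixedModelError(
                        f"interaction {t!r} requires both main effects in the model"
                    )

    @property
    def label(self) -> str:
        if not self.fixed_terms:
            return "null model"
        inter = [t for t in self.fixed_terms if ":" in t]
        if inter:
            a, b = inter[0].split(":")
            extras = [t for t in self.fixed_terms if ":" not in t and t not in (a, b)]
            lab = f"{a} x {b}"
            return " + ".join([lab] + extras) if extras else lab
        return " + ".join(self.fixed_terms)

    @property
    def formula_rhs(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "1"


@dataclass
class ModelFit:
    """A fitted candidate model with everything AICc ranking needs."""

    spec: ModelSpec
    loglik: float
    k: int
    n: int
    aicc: float
    coefficients: pd.DataFrame  # index term; estimate, se, ci_low, ci_high
    variance_components: dict[str, float]
    converged: bool

    @property
    def label(self) -> str:
        return self.spec.label


# ---------------------------------------------------------------------------
# elementary machinery


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples.

    -2 loglik + 2k + 2k(k+1)/(n-k-1); undefined when n <= k+1.
    """
    if n <= k + 1:
        raise MixedModelError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def scale_predictors(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Centre named continuous columns on their mean and divide by 1 s.d. (n-1).

    Other columns are untouched; a zero-variance column is an error.
    """
    out = table.copy()
    for col in columns:
        x = pd.to_numeric(out[col], errors="raise").astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise MixedModelError(f"cannot scale zero-variance column {col!r}")
        out[col] = (x - x.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# gaussian LMM (statsmodels MixedLM)


class _GaussianProfile:
    """Profiled (RE)ML for a gaussian LMM with one random intercept.

    For a fixed variance ratio theta = var_group / var_residual the GLS
    estimates of the coefficients and the residual variance are closed
    form (the marginal precision is block diagonal by group, each block
    I - theta/(1 + theta*n_g) * 11'), leaving a one-dimensional bounded
    optimization over theta.  This handles boundary fits (theta -> 0)
    smoothly, which matters because many candidate models in an AICc set
    land there.
    """

    THETA_MAX = 1e4

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.reml = reml
        self.codes, levels = pd.factorize(groups)
        self.n_groups = len(levels)
        self.group_sizes = np.bincount(self.codes)

    def _profile(self, theta: float):
        """GLS at fixed theta: returns (negative profile loglik, beta, cov, sig2)."""
        shrink = theta / (1.0 + theta * self.group_sizes)  # per group
        # W-weighted cross products: W = I - shrink * 11' per group block
        Xg_sum = np.zeros((self.n_groups, self.p))
        yg_sum = np.zeros(self.n_groups)
        np.add.at(Xg_sum, self.codes, self.X)
        np.add.at(yg_sum, self.codes, self.y)
        XtWX = self.X.T @ self.X - (Xg_sum * shrink[:, None]).T @ Xg_sum
        XtWy = self.X.T @ self.y - Xg_sum.T @ (shrink * yg_sum)
        ytWy = self.y @ self.y - shrink @ yg_sum**2
        beta = np.linalg.solve(XtWX, XtWy)
        rss = float(ytWy - beta @ XtWy)  # r' W r
        logdet_v = float(np.log1p(theta * self.group_sizes).sum())
        if self.reml:
            dof = self.n - self.p
            sig2 = rss / dof
            _, logdet_xwx = np.linalg.slogdet(XtWX)
            ll = -0.5 * (
                dof * np.log(2 * np.pi * sig2) + logdet_v + logdet_xwx + dof
            )
        else:
            sig2 = rss / self.n
            ll = -0.5 * (self.n * np.log(2 * np.pi * sig2) + logdet_v + self.n)
        cov_beta = sig2 * np.linalg.inv(XtWX)
        return -ll, beta, cov_beta, sig2

    def fit(self):
        res = optimize.minimize_scalar(
            lambda u: self._profile(np.expm1(u))[0],
            bounds=(0.0, np.log1p(self.THETA_MAX)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(np.expm1(res.x))
        # the bounded optimizer cannot sit exactly on 0; check the boundary
        if self._profile(0.0)[0] <= res.fun + 1e-10:
            theta = 0.0
        negll, beta, cov_beta, sig2 = self._profile(theta)
        return {
            "beta": beta,
            "se": np.sqrt(np.diag(cov_beta)),
            "loglik": -negll,
            "var_group": theta * sig2,
            "var_residual": sig2,
            "converged": True,
        }


def _fit_gaussian(spec: ModelSpec, data: pd.DataFrame, reml: bool) -> ModelFit:
    if len(spec.random_terms) != 1:
        raise MixedModelError("gaussian family supports exactly one random intercept")
    group = spec.random_terms[0]
    if data[group].nunique() < 2:
        raise MixedModelError(f"grouping factor {group!r} needs >= 2 levels")
    y, X = patsy.dmatrices(
        f"{spec.response} ~ {spec.formula_rhs}", data, return_type="dataframe"
    )
    Xv = X.to_numpy()
    p = Xv.shape[1]
    if np.linalg.matrix_rank(Xv) < p:
        raise MixedModelError("rank-deficient fixed-effect design")
    engine = _GaussianProfile(
        y.to_numpy().ravel(), Xv, data.loc[X.index, group].to_numpy(), reml=reml
    )
    result = engine.fit()
    k = p + 1 + 1  # fixed coefficients + random-intercept variance + residual
    n = len(y)
    est = pd.Series(result["beta"], index=X.columns)
    se = pd.Series(result["se"], index=X.columns)
    coef = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
        }
    )
    vc = {
        f"var_{group}": result["var_group"],
        "var_residual": result["var_residual"],
    }
    return ModelFit(
        spec=spec,
        loglik=result["loglik"],
        k=k,
        n=n,
        aicc=aicc(result["loglik"], k, n),
        coefficients=coef,
        variance_components=vc,
        converged=result["converged"],
    )


# ---------------------------------------------------------------------------
# Poisson GLMM with crossed random intercepts, Laplace approximation


class _PoissonLaplace:
    """Laplace-approximated marginal likelihood for a Poisson mixed model.

    y_i ~ Poisson(exp(x_i'beta + sum_f b_{f, g_f(i)})), with independent
    random intercepts b_f ~ N(0, sigma_f^2 I) for each grouping factor f.
    The random-effect mode for fixed (beta, sigma) is found by Newton
    iterations; the marginal log-likelihood is then

        l = log f(y | bhat) + log phi(bhat; 0, D) + (M/2) log 2pi
            - (1/2) log det(Z' W Z + D^-1).
    """

    #: log sd bounds for the outer optimizer; the lower bound is an
    #: effectively-zero variance at which the fit collapses to a GLM
    LOG_SD_MIN = -10.0
    LOG_SD_MAX = 4.0

    def __init__(self, y: np.ndarray, X: np.ndarray, factors: list[np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.sizes = [int(f.max()) + 1 for f in factors]
        self.M = sum(self.sizes)
        Z = np.zeros((self.n, self.M))
        offset = 0
        for f, m in zip(factors, self.sizes):
            Z[np.arange(self.n), offset + f] = 1.0
            offset += m
        self.Z = Z
        self._log_yfact = float(special.gammaln(self.y + 1.0).sum())

    def _dinv_diag(self, log_sd: np.ndarray) -> np.ndarray:
        out = np.empty(self.M)
        offset = 0
        for ls, m in zip(log_sd, self.sizes):
            out[offset : offset + m] = np.exp(-2.0 * ls)
            offset += m
        return out

    def _mode(self, beta: np.ndarray, dinv: np.ndarray, b0: np.ndarray) -> np.ndarray:
        """Newton iterations for the conditional mode of the random effects."""
        b = b0.copy()
        xb = self.X @ beta
        for _ in range(50):
            eta = xb + self.Z @ b
            mu = np.exp(np.clip(eta, -30, 30))
            grad = self.Z.T @ (self.y - mu) - dinv * b
            H = (self.Z.T * mu) @ self.Z
            H[np.diag_indices_from(H)] += dinv
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # dampen to keep the penalized objective increasing
            t = 1.0
            obj0 = self._penalized(b, xb, dinv)
            for _ in range(20):
                cand = b + t * step
                if self._penalized(cand, xb, dinv) >= obj0 - 1e-12:
                    break
                t *= 0.5
            b = b + t * step
            if np.max(np.abs(t * step)) < 1e-10:
                break
        return b

    def _penalized(self, b: np.ndarray, xb: np.ndarray, dinv: np.ndarray) -> float:
        eta = xb + self.Z @ b
        eta = np.clip(eta, -30, 30)
        return float(self.y @ eta - np.exp(eta).sum() - 0.5 * (dinv * b * b).sum())

    def loglik(self, beta: np.ndarray, log_sd: np.ndarray, b0: np.ndarray | None = None):
        """Laplace marginal log-likelihood and the conditional mode."""
        dinv = self._dinv_diag(log_sd)
        b = self._mode(beta, dinv, np.zeros(self.M) if b0 is None else b0)
        eta = np.clip(self.X @ beta + self.Z @ b, -30, 30)
        mu = np.exp(eta)
        H = (self.Z.T * mu) @ self.Z
        H[np.diag_indices_from(H)] += dinv
        sign, logdet_h = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, b
        logdet_d = -float(np.log(dinv).sum())  # log det D
        ll = (
            float(self.y @ eta - mu.sum())
            - self._log_yfact
            - 0.5 * float((dinv * b * b).sum())
            - 0.5 * logdet_d
            - 0.5 * logdet_h
        )
        return ll, b

    def fit(self, beta0: np.ndarray, log_sd0: np.ndarray):
        q = len(self.sizes)
        state = {"b": np.zeros(self.M)}

        def negll(theta: np.ndarray) -> float:
            beta, log_sd = theta[: self.p], theta[self.p :]
            ll, b = self.loglik(beta, log_sd, state["b"])
            state["b"] = b
            return -ll if np.isfinite(ll) else 1e12

        theta0 = np.concatenate([beta0, log_sd0])
        bounds = [(None, None)] * self.p + [(self.LOG_SD_MIN, self.LOG_SD_MAX)] * q
        res = optimize.minimize(
            negll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11},
        )
        beta = res.x[: self.p]
        log_sd = res.x[self.p :]
        ll, b = self.loglik(beta, log_sd, state["b"])
        # Wald covariance of beta: Schur complement of the joint Hessian
        eta = np.clip(self.X @ beta + self.Z @ b, -30, 30)
        mu = np.exp(eta)
        dinv = self._dinv_diag(log_sd)
        H = (self.Z.T * mu) @ self.Z
        H[np.diag_indices_from(H)] += dinv
        XtW = self.X.T * mu
        A = XtW @ self.X
        B = XtW @ self.Z
        S = A - B @ np.linalg.solve(H, B.T)
        cov_beta = np.linalg.inv(S)
        return {
            "beta": beta,
            "se": np.sqrt(np.diag(cov_beta)),
            "sigma": np.exp(log_sd),
            "loglik": float(ll),
            "converged": bool(res.success),
            "mode": b,
        }


def _fit_poisson(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    import statsmodels.api as sm

    y, X = patsy.dmatrices(
        f"{spec.response} ~ {spec.formula_rhs}", data, return_type="dataframe"
    )
    yv = y.to_numpy().ravel()
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise MixedModelError("poisson response must be non-negative integers")
    Xv = X.to_numpy()
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise MixedModelError("rank-deficient fixed-effect design")
    factors = []
    for term in spec.random_terms:
        codes, _ = pd.factorize(data.loc[X.index, term])
        if len(np.unique(codes)) < 2:
            raise MixedModelError(f"grouping factor {term!r} needs >= 2 levels")
        factors.append(codes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(yv, Xv, family=sm.families.Poisson()).fit()
    engine = _PoissonLaplace(yv, Xv, factors)
    result = engine.fit(np.asarray(glm.params), np.full(len(factors), np.log(0.3)))
    p = Xv.shape[1]
    k = p + len(factors)
    n = len(yv)
    est = pd.Series(result["beta"], index=X.columns)
    se = pd.Series(result["se"], index=X.columns)
    coef = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
        }
    )
    vc = {
        f"var_{term}": float(s**2)
        for term, s in zip(spec.random_terms, result["sigma"])
    }
    return ModelFit(
        spec=spec,
        loglik=result["loglik"],
        k=k,
        n=n,
        aicc=aicc(result["loglik"], k, n),
        coefficients=coef,
        variance_components=vc,
        converged=result["converged"],
    )


def fit_mixed(spec: ModelSpec, data: pd.DataFrame, reml: bool = False) -> ModelFit:
    """Fit one candidate mixed model.

    Gaussian fits use maximum likelihood by default (``reml=True`` for
    variance reporting only — REML likelihoods are not comparable across
    fixed-effect structures and must not feed AICc ranking).  Poisson fits
    maximize the Laplace-approximated marginal likelihood over crossed
    random intercepts.  Non-convergence is reported through the
    ``converged`` flag, never by silently dropping the fit.
    """
    cols_needed = set(spec.random_terms) | {spec.response}
    for t in spec.fixed_terms:
        cols_needed.update(t.split(":"))
    missing = cols_needed - set(data.columns)
    if missing:
        raise MixedModelError(f"data missing columns: {sorted(missing)}")
    if spec.family == "gaussian":
        return _fit_gaussian(spec, data, reml=reml)
    return _fit_poisson(spec, data)


# ---------------------------------------------------------------------------
# candidate sets and model selection


def build_candidate_set(
    single_terms: list[str],
    additive_pool: list[str] | None = None,
    interaction_pool: list[str] | None = None,
    response: str = "y",
    random_terms: tuple[str, ...] = ("group_id",),
    family: str = "gaussian",
) -> list[ModelSpec]:
    """Construct the candidate model set for AICc ranking.

    Contains the null (intercept-only) model, one model per entry of
    ``single_terms``, all pairwise additive models over ``additive_pool``,
    and all pairwise interaction models (interaction plus both main
    effects) over ``interaction_pool``.  Duplicate term sets are dropped.
    """
    additive_pool = additive_pool or []
    interaction_pool = interaction_pool or []
    specs: dict[frozenset, ModelSpec] = {}

    def add(terms: tuple[str, ...]) -> None:
        key = frozenset(terms)
        if key not in specs:
            specs[key] = ModelSpec(
                response=response,
                fixed_terms=terms,
                random_terms=random_terms,
                family=family,
            )

    add(())
    for t in single_terms:
        add((t,))
    for a, b in itertools.combinations(additive_pool, 2):
        add((a, b))
    for a, b in itertools.combinations(interaction_pool, 2):
        add((a, b, f"{a}:{b}"))
    return list(specs.values())


def select_top_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits by AICc and flag the top model set.

    dAICc is relative to the smallest AICc among converged fits; ties are
    broken toward fewer parameters.  A model is in the top set when
    dAICc <= 2 and the 95% CI of every interpreted fixed coefficient
    excludes zero.  Main effects that are marginal to an interaction in
    the same model are not interpreted on their own (their coefficients
    are conditional effects at the reference level), so they are exempt
    from the CI screen; everything else non-intercept is checked.  The
    null model row is always present and marked.
    """
    if not fits:
        raise MixedModelError("no fits supplied")
    converged = [f for f in fits if f.converged]
    if not converged:
        raise MixedModelError("all candidate fits failed to converge")
    best = min(f.aicc for f in converged)
    rows = []
    for f in fits:
        delta = f.aicc - best
        interactions = [t for t in f.spec.fixed_terms if ":" in t]
        marginal = {part for t in interactions for part in t.split(":")}

        def interpreted(term: str) -> bool:
            if term == "Intercept":
                return False
            if ":" in term:
                return True
            return term.split("[")[0] not in marginal

        cis_exclude_zero = all(
            (row.ci_low > 0) or (row.ci_high < 0)
            for term, row in f.coefficients.iterrows()
            if interpreted(term)
        )
        rows.append(
            {
                "model": f.label,
                "loglik": f.loglik,
                "k": f.k,
                "n": f.n,
                "aicc": f.aicc,
                "delta_aicc": delta,
                "in_top_set": bool(f.converged and delta <= 2.0 and cis_exclude_zero),
                "is_null": not f.spec.fixed_terms,
                "converged": f.converged,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["aicc", "k"], kind="mergesort")
        .reset_index(drop=True)
    )
    return table


def coefficient_table(fits: list[ModelFit], selection: pd.DataFrame) -> pd.DataFrame:
    """Coefficient estimates +/- se with 95% CI for top-model-set members."""
    top_labels = set(selection.loc[selection["in_top_set"], "model"])
    frames = []
    for f in fits:
        if f.label in top_labels and f.spec.fixed_terms:
            c = f.coefficients.copy()
            c.insert(0, "model", f.label)
            c.index.name = "term"
            frames.append(c.reset_index())
    if not frames:
        return pd.DataFrame(
            columns=["model", "term", "estimate", "se", "ci_low", "ci_high"]
        )
    return pd.concat(frames, ignore_index=True)
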