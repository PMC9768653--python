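"""Noncentral-F power analysis for fixed-effect tests (Cohen's f²).

Power for a fixed-effect test with ``u`` numerator and ``v`` denominator
degrees of freedom is the tail probability of a noncentral F distribution
beyond the central-F critical value::

    power = P( F'(u, v, lambda) > F_crit(1 - alpha; u, v) )

with noncentrality ``lambda = f2 * (u + v + 1)`` by default — the
convention used by Cohen and by the R ``pwr`` package.  Some texts use
``lambda = f2 * v`` instead; pass ``ncp="v"`` to switch.

``min_detectable_f2`` inverts the relation: the effect size at which the
test attains a target power, e.g. f² ≈ 0.26 at u=1, v=30, alpha=0.05,
power=0.80 — a "moderate" effect in Cohen's terms.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats


class PowerError(ValueError):
    """Invalid power-analysis query."""


@dataclass(frozen=True)
class PowerQuery:
    """Degrees of freedom, test size and target power for an f² computation."""

    u: int
    v: int
    alpha: float = 0.05
    power: float = 0.80
    f2: float | None = None

    def __post_init__(self) -> None:
        if self.u < 1 or self.v < 1:
            raise PowerError("u and v must both be >= 1")
        if not (0.0 < self.alpha < self.power < 1.0):
            raise PowerError("require 0 < alpha < power < 1")
        if self.f2 is not None and self.f2 < 0:
            raise PowerError("f2 must be >= 0")


def _ncp(f2: float, u: int, v: int, ncp: str) -> float:
    if ncp == "u+v+1":
        return f2 * (u + v + 1)
    if ncp == "v":
        return f2 * v
    raise PowerError(f"unknown noncentrality convention {ncp!r}")


def power_of_f2(
    u: int, v: int, f2: float, alpha: float = 0.05, ncp: str = "u+v+1"
) -> float:
    """Power of the F test at effect size ``f2``.

    At ``f2 = 0`` the distribution is central F and power equals ``alpha``.
    Power is monotone increasing in ``f2`` and ``v``.
    """
    PowerQuery(u=u, v=v, alpha=alpha, power=max(alpha * 1.0000001, 0.5), f2=f2)
    fcrit = stats.f.isf(alpha, u, v)
    lam = _ncp(f2, u, v, ncp)
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncf.sf(fcrit, u, v, lam))


def min_detectable_f2(
    u: int,
    v: int,
    alpha: float = 0.05,
    power: float = 0.80,
    ncp: str = "u+v+1",
    tol: float = 1e-6,
) -> float:
    """Smallest Cohen's f² at which the F test reaches ``power``.

    Bracketed root-finding (Brent) of ``power_of_f2(f2) = power`` on
    (1e-8, 100) to absolute tolerance ``tol``.
    """
    PowerQuery(u=u, v=v, alpha=alpha, power=power)

    def gap(f2: float) -> float:
        return power_of_f2(u, v, f2, alpha=alpha, ncp=ncp) - power

    lo, hi = 1e-8, 100.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise PowerError("no root bracket for f2 within (1e-8, 100)")
    return float(optimize.brentq(gap, lo, hi, xtol=tol))


def f2_table(
    u_values: list[int],
    v_values: list[int],
    alpha: float = 0.05,
    power: float = 0.80,
    ncp: str = "u+v+1",
) -> "pd.DataFrame":
    """Minimum detectable f² over a grid of (u, v)."""
    import pandas as pd

    rows = {
        u: [min_detectable_f2(u, v, alpha=alpha, power=power, ncp=ncp) for v in v_values]
        for u in u_values
    }
    tab = pd.DataFrame(rows, index=pd.Index(v_values, name="v")).T
    tab.index.name = "u"
    return tab
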