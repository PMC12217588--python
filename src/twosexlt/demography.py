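"""Demographic parameters: R0, intrinsic rate r, finite rate lambda, T.

* Net reproductive rate: ``R0 = sum_x l_x m_x`` — expected lifetime
  offspring per newborn (both sexes in the denominator, so R0 equals
  (females/n01) x mean eggs per female).
* Intrinsic rate of increase r: the root of the Euler-Lotka equation in
  the age-counted-from-0 convention, ``sum_x exp(-r (x+1)) l_x m_x = 1``,
  solved by iterative bisection (the left side is strictly decreasing in
  r, so bisection is monotone and guaranteed).
* Finite rate of increase ``lambda = exp(r)`` (per day).
* Mean generation time ``T = ln(R0) / r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lifetable import ScheduleSet

__all__ = [
    "DemographicParams",
    "EulerLotkaError",
    "net_reproductive_rate",
    "net_reproductive_rate_from_counts",
    "euler_lotka_lhs",
    "solve_intrinsic_rate",
    "finite_rate_of_increase",
    "generation_time",
    "demographic_params",
]

DEFAULT_BRACKET = (-0.5, 1.5)  # per-day rates covering plausible arthropod demography
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 200


class EulerLotkaError(ValueError):
    """The Euler-Lotka equation has no root in the requested bracket."""


@dataclass(frozen=True)
class DemographicParams:
    """Point estimates of the demographic parameters with solver diagnostics.

    ``t`` is NaN when R0 <= 0 or r == 0 (generation time undefined at
    replacement); ``residual`` is |sum exp(-r(x+1)) l_x m_x - 1| at the
    returned root.
    """

    r0: float
    r: float
    lam: float
    t: float
    residual: float
    iterations: int
    bracket: tuple[float, float]


def net_reproductive_rate(schedules: ScheduleSet) -> float:
    """R0 = sum over ages of l_x m_x."""
    return float(np.sum(schedules.l * schedules.m))


def net_reproductive_rate_from_counts(
    n_female: int, n01: int, mean_fecundity: float
) -> float:
    """Two-sex identity R0 = (females / n01) x mean eggs per female.

    Because every individual (both sexes and immature deaths) is in the
    denominator of m_x, summing the net-maternity sequence collapses to
    total cohort eggs / n01 = (n_female/n01) x mean female fecundity.
    """
    if n01 <= 0:
        raise ValueError("n01 must be positive")
    return (n_female / n01) * mean_fecundity


def euler_lotka_lhs(lx_mx: np.ndarray, r: float) -> float:
    """Left side of the Euler-Lotka equation, sum_x exp(-r(x+1)) l_x m_x."""
    x = np.arange(len(lx_mx))
    return float(np.sum(np.exp(-r * (x + 1)) * lx_mx))


def solve_intrinsic_rate(
    schedules: ScheduleSet | np.ndarray,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> DemographicParams:
    """Solve the Euler-Lotka equation for r by iterative bisection.

    Accepts either a ScheduleSet or a raw net-maternity sequence l_x m_x.
    Stops when the residual |lhs - 1| drops to ``tol`` or after
    ``max_iter`` halvings.

    Raises
    ------
    EulerLotkaError
        If R0 = 0 (no reproduction, no root) or the bracket endpoints do
        not straddle lhs = 1.
    """
    lx_mx = (
        schedules.lx_mx if isinstance(schedules, ScheduleSet) else np.asarray(schedules, float)
    )
    r0 = float(lx_mx.sum())
    if r0 <= 0.0:
        raise EulerLotkaError(
            "R0 = 0: the cohort produces no offspring, the Euler-Lotka "
            "equation has no root"
        )
    lo, hi = bracket
    f_lo = euler_lotka_lhs(lx_mx, lo)
    f_hi = euler_lotka_lhs(lx_mx, hi)
    if not (f_lo >= 1.0 >= f_hi):
        raise EulerLotkaError(
            f"bracket {bracket} does not straddle the root: "
            f"lhs({lo}) = {f_lo:.6g}, lhs({hi}) = {f_hi:.6g}"
        )
    residual = min(abs(f_lo - 1.0), abs(f_hi - 1.0))
    r = lo if abs(f_lo - 1.0) <= abs(f_hi - 1.0) else hi
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        f_mid = euler_lotka_lhs(lx_mx, mid)
        if f_mid >= 1.0:
            lo = mid
        else:
            hi = mid
        if abs(f_mid - 1.0) < residual:
            residual = abs(f_mid - 1.0)
            r = mid
        if residual <= tol:
            break
    lam = math.exp(r)
    t = generation_time(r0, r)
    return DemographicParams(
        r0=r0,
        r=r,
        lam=lam,
        t=t,
        residual=residual,
        iterations=iterations,
        bracket=bracket,
    )


def finite_rate_of_increase(r: float) -> float:
    """lambda = exp(r), the daily multiplication factor."""
    return math.exp(r)


def generation_time(r0: float, r: float) -> float:
    """T = ln(R0) / r.  NaN when undefined (r = 0 or R0 <= 0)."""
    if r == 0.0 or r0 <= 0.0:
        return float("nan")
    return math.log(r0) / r


def demographic_params(
    schedules: ScheduleSet,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    tol: float = DEFAULT_TOL,
) -> DemographicParams:
    """All four parameters from one schedule set (bisection for r)."""
    return solve_intrinsic_rate(schedules, bracket=bracket, tol=tol)
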