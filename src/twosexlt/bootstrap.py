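"""Bootstrap standard errors and paired bootstrap tests.

The resampling unit is the whole individual life history: each replicate
draws n01 individuals with replacement from the non-excluded records,
recomputes the schedules and the requested parameters, and the SE of a
parameter is the standard deviation of its replicate distribution
(percentile CIs at the stated level).  Treatment differences use the
paired bootstrap test: replicate b of cohort A is paired with replicate b
of cohort B (independent resamples, common index), and the difference is
significant when the percentile CI of the B differences excludes 0.

Replicates where a parameter is undefined (e.g. no females drawn for
APOP) are dropped from that parameter's distribution and counted;
R0 = 0 is a defined outcome and such replicates are retained for R0.

Internally each parameter is reduced to per-individual arrays (lifetime
eggs, egg-by-age rows, sex and timing scalars) so replicates are sums or
means over resampled rows; the intrinsic rate is solved by a vectorized
bisection over the replicate net-maternity matrices.  Tests cross-check
this path against a literal rebuild-the-cohort-and-recompute oracle on
the same index draws (see ``replicate_indices``).

Randomness: every parameter has its own stream derived from the master
seed and a fixed small parameter id, so adding parameters to a run never
perturbs existing draws, and a fixed seed is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import SEX_FEMALE, SEX_MALE, CohortTable
from .demography import DEFAULT_BRACKET

__all__ = [
    "BootstrapResult",
    "PairedTestResult",
    "PARAMETERS",
    "bootstrap_cohort",
    "paired_bootstrap_test",
    "replicate_indices",
    "replicate_values",
]

# Fixed parameter ids feed the per-parameter RNG streams; append-only.
_PARAM_IDS: dict[str, int] = {
    "R0": 1,
    "r": 2,
    "lambda": 3,
    "T": 4,
    "sex_ratio": 5,
    "fecundity": 6,
    "APOP": 7,
    "TPOP": 8,
    "oviposition_days": 9,
    "female_adult_longevity": 10,
    "male_adult_longevity": 11,
    "immature_mortality": 12,
    "female_preadult": 13,
    "male_preadult": 14,
    "duration_stage_0": 20,
    "duration_stage_1": 21,
    "duration_stage_2": 22,
    "duration_stage_3": 23,
    "duration_stage_4": 24,
    "duration_stage_5": 25,
    "duration_stage_6": 26,
    "duration_stage_7": 27,
}

PARAMETERS: tuple[str, ...] = (
    "R0",
    "r",
    "lambda",
    "T",
    "sex_ratio",
    "fecundity",
    "APOP",
    "TPOP",
    "oviposition_days",
    "female_adult_longevity",
    "male_adult_longevity",
    "immature_mortality",
)

_CHUNK = 4096  # replicates per block when expanding egg-by-age matrices


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap summary for one parameter of one cohort."""

    parameter: str
    estimate: float
    boot_mean: float
    se: float
    ci: tuple[float, float]
    level: float
    b: int
    b_valid: int
    seed: int
    degenerate: bool  # fewer than two valid replicates: SE = 0 by convention


@dataclass(frozen=True)
class PairedTestResult:
    """Paired bootstrap comparison of one parameter between two cohorts."""

    parameter: str
    treatments: tuple[str, str]
    difference: float
    ci: tuple[float, float]
    level: float
    significant: bool
    b: int
    b_valid: int
    seed: int


class _CohortArrays:
    """Per-individual arrays caching everything the resampler needs."""

    def __init__(self, cohort: CohortTable):
        active = cohort.active_records
        n = len(active)
        omega = max(r.death_age for r in active)
        self.n = n
        self.omega = omega
        self.eggs_by_age = np.zeros((n, omega + 1))
        self.total_eggs = np.zeros(n)
        nan = float("nan")
        self.is_female = np.zeros(n)
        self.reached_adult = np.zeros(n)
        self.apop = np.full(n, nan)
        self.tpop = np.full(n, nan)
        self.ovidays = np.full(n, nan)
        self.fecundity = np.full(n, nan)
        self.f_longevity = np.full(n, nan)
        self.m_longevity = np.full(n, nan)
        self.f_preadult = np.full(n, nan)
        self.m_preadult = np.full(n, nan)
        n_imm = cohort.schema.first_adult
        self.durations = np.full((n, n_imm), nan)
        for i, rec in enumerate(active):
            for x, e in enumerate(rec.eggs):
                self.eggs_by_age[i, x] = e
            self.total_eggs[i] = rec.total_eggs
            self.is_female[i] = rec.sex == SEX_FEMALE
            self.reached_adult[i] = rec.reached_adult
            if rec.sex == SEX_FEMALE:
                self.fecundity[i] = rec.total_eggs
                self.f_longevity[i] = rec.death_age - rec.adult_entry
                self.f_preadult[i] = rec.adult_entry
                first = rec.first_egg_age
                if first is not None:
                    self.apop[i] = first - rec.adult_entry
                    self.tpop[i] = first
                    self.ovidays[i] = rec.oviposition_days
            elif rec.sex == SEX_MALE:
                self.m_longevity[i] = rec.death_age - rec.adult_entry
                self.m_preadult[i] = rec.adult_entry
            entries = list(rec.immature_entries) + [rec.adult_entry]
            for j in range(n_imm):
                a, b = entries[j], entries[j + 1]
                if a is not None and b is not None:
                    self.durations[i, j] = b - a


def _solve_r_many(
    phi: np.ndarray,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    iterations: int = 100,
) -> np.ndarray:
    """Vectorized bisection of the Euler-Lotka equation.

    ``phi`` is a (B, omega+1) matrix of net-maternity sequences; returns
    one r per row (NaN where the row has no reproduction or the bracket
    fails).  100 halvings shrink the default bracket below 1e-28, far
    past double precision.
    """
    phi = np.atleast_2d(phi)
    b, w = phi.shape
    ages = np.arange(w) + 1.0
    r = np.full(b, np.nan)
    valid = phi.sum(axis=1) > 0
    if not valid.any():
        return r
    p = phi[valid]
    lo = np.full(p.shape[0], float(bracket[0]))
    hi = np.full(p.shape[0], float(bracket[1]))

    def lhs(rv: np.ndarray) -> np.ndarray:
        return np.einsum("bw,bw->b", np.exp(-np.outer(rv, ages)), p)

    ok = (lhs(lo) >= 1.0) & (lhs(hi) <= 1.0)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        above = lhs(mid) >= 1.0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    out = np.where(ok, 0.5 * (lo + hi), np.nan)
    r[valid] = out
    return r


def _nanmean_rows(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Row-wise mean of values[idx] ignoring NaN; NaN for all-NaN rows."""
    picked = values[idx]
    counts = np.sum(~np.isnan(picked), axis=1)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(picked, axis=1)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _replicate_r(arr: _CohortArrays, idx: np.ndarray) -> np.ndarray:
    out = np.empty(idx.shape[0])
    for start in range(0, idx.shape[0], _CHUNK):
        block = idx[start : start + _CHUNK]
        phi = arr.eggs_by_age[block].sum(axis=1) / arr.n
        out[start : start + _CHUNK] = _solve_r_many(phi)
    return out


def replicate_values(arr_or_cohort, parameter: str, idx: np.ndarray) -> np.ndarray:
    """Parameter value for each resample row of index matrix ``idx``.

    ``idx`` has one replicate per row, each row listing n01 (repeatable)
    positions into the cohort's non-excluded records.  Undefined
    replicates come back NaN.
    """
    arr = arr_or_cohort if isinstance(arr_or_cohort, _CohortArrays) else _CohortArrays(arr_or_cohort)
    idx = np.atleast_2d(np.asarray(idx))
    if parameter == "R0":
        return arr.total_eggs[idx].mean(axis=1)
    if parameter == "r":
        return _replicate_r(arr, idx)
    if parameter == "lambda":
        return np.exp(_replicate_r(arr, idx))
    if parameter == "T":
        r0 = arr.total_eggs[idx].mean(axis=1)
        r = _replicate_r(arr, idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where((r0 > 0) & (r != 0), np.log(r0) / r, np.nan)
    if parameter == "sex_ratio":
        return arr.is_female[idx].mean(axis=1)
    if parameter == "immature_mortality":
        return 1.0 - arr.reached_adult[idx].mean(axis=1)
    simple = {
        "fecundity": arr.fecundity,
        "APOP": arr.apop,
        "TPOP": arr.tpop,
        "oviposition_days": arr.ovidays,
        "female_adult_longevity": arr.f_longevity,
        "male_adult_longevity": arr.m_longevity,
        "female_preadult": arr.f_preadult,
        "male_preadult": arr.m_preadult,
    }
    if parameter in simple:
        return _nanmean_rows(simple[parameter], idx)
    if parameter.startswith("duration_stage_"):
        j = int(parameter.rsplit("_", 1)[1])
        if j >= arr.durations.shape[1]:
            raise KeyError(f"no immature stage {j} in this schema")
        return _nanmean_rows(arr.durations[:, j], idx)
    raise KeyError(f"unknown bootstrap parameter {parameter!r}")


def replicate_indices(
    parameter: str, seed: int, b: int, n: int, cohort_tag: int = 0
) -> np.ndarray:
    """The (b, n) resampling index matrix for a parameter's RNG stream."""
    if parameter not in _PARAM_IDS:
        if parameter.startswith("duration_stage_"):
            raise KeyError(f"no RNG stream registered for {parameter!r}")
        raise KeyError(f"unknown bootstrap parameter {parameter!r}")
    rng = np.random.default_rng([_PARAM_IDS[parameter], int(seed), int(cohort_tag)])
    return rng.integers(0, n, size=(b, n))


def _point_estimate(arr: _CohortArrays, parameter: str) -> float:
    full = np.arange(arr.n)[None, :]
    return float(replicate_values(arr, parameter, full)[0])


def bootstrap_cohort(
    cohort: CohortTable,
    b: int,
    seed: int,
    parameters: tuple[str, ...] | list[str] | None = None,
    level: float = 0.95,
    cohort_tag: int = 0,
) -> list[BootstrapResult]:
    """Bootstrap SEs and percentile CIs for the requested parameters.

    Each replicate resamples n01 individuals with replacement and
    recomputes the parameter; SE is the standard deviation over valid
    replicates.  ``b = 1`` (or no variation) yields SE = 0, flagged
    degenerate.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    params = tuple(parameters) if parameters is not None else PARAMETERS
    arr = _CohortArrays(cohort)
    results = []
    alpha = 1.0 - level
    for p in params:
        idx = replicate_indices(p, seed, b, arr.n, cohort_tag)
        vals = replicate_values(arr, p, idx)
        valid = vals[np.isfinite(vals)]
        estimate = _point_estimate(arr, p)
        if valid.size == 0:
            results.append(
                BootstrapResult(p, estimate, float("nan"), float("nan"),
                                (float("nan"), float("nan")), level, b, 0, seed, True)
            )
            continue
        degenerate = valid.size < 2
        se = 0.0 if degenerate else float(valid.std(ddof=1))
        ci = (
            float(np.quantile(valid, alpha / 2)),
            float(np.quantile(valid, 1 - alpha / 2)),
        )
        results.append(
            BootstrapResult(
                p, estimate, float(valid.mean()), se, ci, level,
                b, int(valid.size), seed, degenerate,
            )
        )
    return results


def paired_bootstrap_test(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    b: int,
    seed: int,
    parameter: str,
    level: float = 0.95,
) -> PairedTestResult:
    """Paired bootstrap test of one parameter between two cohorts.

    Replicate i of A is paired with replicate i of B (independent
    resamples from per-cohort streams of the same master seed); the
    difference is significant at ``level`` when the percentile CI of the
    replicate differences excludes 0.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    arr_a = _CohortArrays(cohort_a)
    arr_b = _CohortArrays(cohort_b)
    vals_a = replicate_values(arr_a, parameter, replicate_indices(parameter, seed, b, arr_a.n, 0))
    vals_b = replicate_values(arr_b, parameter, replicate_indices(parameter, seed, b, arr_b.n, 1))
    diffs = vals_a - vals_b
    valid = diffs[np.isfinite(diffs)]
    alpha = 1.0 - level
    if valid.size == 0:
        ci = (float("nan"), float("nan"))
        significant = False
    else:
        ci = (
            float(np.quantile(valid, alpha / 2)),
            float(np.quantile(valid, 1 - alpha / 2)),
        )
        significant = not (ci[0] <= 0.0 <= ci[1])
    return PairedTestResult(
        parameter=parameter,
        treatments=(cohort_a.treatment, cohort_b.treatment),
        difference=_point_estimate(arr_a, parameter) - _point_estimate(arr_b, parameter),
        ci=ci,
        level=level,
        significant=significant,
        b=b,
        b_valid=int(valid.size),
        seed=seed,
    )
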