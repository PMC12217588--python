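"""Synthetic cohort generator emulating spider-mite life-history data.

Each individual is drawn independently: sequential Bernoulli survival
through the immature stages, integer stage durations from discretized
normal distributions (minimum 1 day), a sex draw on reaching adulthood,
an adult pre-oviposition period (APOP), adult longevity per sex, and
daily egg counts from a unimodal rise-peak-decline fecundity curve
truncated at death.  An individual that dies in stage j dies on the day
it would have molted (it occupies the stage for its full drawn duration).

The fecundity curve is triangular over adult age a (days since adult
emergence): rising linearly to 1 at ``fecundity_peak_day``, declining
linearly to 0 at ``fecundity_end_day``; laying starts at the individual's
APOP.  The curve's scale is calibrated once per spec so the expected
lifetime fecundity per female equals ``fecundity_target`` under the APOP
and longevity distributions; daily counts are Poisson (or negative
binomial when ``fecundity_dispersion`` is set).

Three packaged presets (``control``, ``paw1``, ``paw2``) target the
published stage-death counts, sex ratios, stage durations, adult
longevities and mean fecundities of mite cohorts on untreated and
plasma-activated-water-irrigated tomato plants.

``expected_schedules`` gives the closed-form schedule set implied by a
spec with all dispersions set to zero (analytic mode), the oracle for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .cohort import (
    DEFAULT_SCHEMA,
    SEX_FEMALE,
    SEX_IMMATURE,
    SEX_MALE,
    CohortTable,
    CohortValidationError,
    IndividualRecord,
    StageSchema,
)
from .lifetable import ScheduleSet

__all__ = [
    "TreatmentSpec",
    "generate_cohort",
    "expected_schedules",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("control", "paw1", "paw2")


def _discretized_normal(mean: float, sd: float, minimum: int = 1):
    """Support and pmf of a normal rounded to integers, truncated at minimum.

    ``sd = 0`` degenerates to a point mass at round(mean) (clipped)."""
    if sd < 0:
        raise CohortValidationError("dispersion must be nonnegative")
    if sd == 0:
        return np.array([max(minimum, round(mean))]), np.array([1.0])
    lo = minimum
    hi = max(lo, int(np.ceil(mean + 8 * sd)))
    ks = np.arange(lo, hi + 1)
    upper = norm.cdf(ks + 0.5, mean, sd)
    lower = norm.cdf(ks - 0.5, mean, sd)
    lower[0] = 0.0  # fold the truncated lower tail into the minimum
    pmf = upper - lower
    pmf[-1] += 1.0 - upper[-1]
    return ks, pmf / pmf.sum()


@dataclass(frozen=True)
class TreatmentSpec:
    """Generator configuration for one treatment's cohorts."""

    name: str
    n: int = 50
    seed: int = 1
    stage_death_probs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    stage_duration_means: tuple[float, ...] = (8.0, 3.1, 2.1, 3.1)
    stage_duration_sds: tuple[float, ...] = (0.8, 0.5, 0.5, 0.6)
    p_female: float = 0.8
    apop_mean: float = 1.5
    apop_sd: float = 0.5
    female_longevity_mean: float = 17.0
    female_longevity_sd: float = 5.0
    male_longevity_mean: float = 14.0
    male_longevity_sd: float = 5.0
    fecundity_target: float = 50.0
    fecundity_peak_day: int = 5
    fecundity_end_day: int = 26
    fecundity_dispersion: float | None = None
    schema: StageSchema = field(default=DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        n_imm = self.schema.first_adult
        for name, tup in (
            ("stage_death_probs", self.stage_death_probs),
            ("stage_duration_means", self.stage_duration_means),
            ("stage_duration_sds", self.stage_duration_sds),
        ):
            if len(tup) != n_imm:
                raise CohortValidationError(
                    f"{name} must have one entry per immature stage ({n_imm})"
                )
        if any(not 0 <= q <= 1 for q in self.stage_death_probs):
            raise CohortValidationError("death probabilities must be in [0, 1]")
        if not 0 <= self.p_female <= 1:
            raise CohortValidationError("p_female must be in [0, 1]")
        if any(m < 1 for m in self.stage_duration_means):
            raise CohortValidationError("stage durations must be >= 1 day")
        if any(s < 0 for s in self.stage_duration_sds):
            raise CohortValidationError("duration dispersions must be >= 0")
        if self.fecundity_target < 0:
            raise CohortValidationError("fecundity target must be >= 0")
        if not 1 <= self.fecundity_peak_day < self.fecundity_end_day:
            raise CohortValidationError(
                "need 1 <= fecundity_peak_day < fecundity_end_day"
            )
        if self.n < 1:
            raise CohortValidationError("cohort size must be >= 1")

    @property
    def deterministic(self) -> bool:
        """True when every duration/timing distribution is a point mass."""
        return (
            all(s == 0 for s in self.stage_duration_sds)
            and self.apop_sd == 0
            and self.female_longevity_sd == 0
            and self.male_longevity_sd == 0
        )

    def fecundity_curve_shape(self) -> np.ndarray:
        """Unscaled triangular curve over adult ages 0..fecundity_end_day-1."""
        a = np.arange(self.fecundity_end_day)
        p, z = self.fecundity_peak_day, self.fecundity_end_day
        rise = a / p
        decline = (z - a) / (z - p)
        shape = np.where(a <= p, rise, decline)
        shape[0] = 0.0  # no laying on the day of adult emergence
        return np.clip(shape, 0.0, None)

    def fecundity_scale(self) -> float:
        """Peak daily egg rate making E[lifetime eggs per female] hit target.

        E[F] = scale * sum_a shape(a) P(APOP <= a) P(longevity > a), with
        the expectation over the discretized APOP and female-longevity
        distributions.
        """
        shape = self.fecundity_curve_shape()
        a = np.arange(len(shape))
        ak, ap = _discretized_normal(self.apop_mean, self.apop_sd, minimum=1)
        lk, lp = _discretized_normal(
            self.female_longevity_mean, self.female_longevity_sd, minimum=1
        )
        p_started = np.array([ap[ak <= x].sum() for x in a])
        p_alive = np.array([lp[lk > x].sum() for x in a])
        denom = float(np.sum(shape * p_started * p_alive))
        if denom == 0:
            raise CohortValidationError(
                "fecundity curve has zero expected laying opportunity"
            )
        return self.fecundity_target / denom

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n": self.n,
            "seed": self.seed,
            "stage_death_probs": list(self.stage_death_probs),
            "stage_duration_means": list(self.stage_duration_means),
            "stage_duration_sds": list(self.stage_duration_sds),
            "p_female": self.p_female,
            "apop_mean": self.apop_mean,
            "apop_sd": self.apop_sd,
            "female_longevity_mean": self.female_longevity_mean,
            "female_longevity_sd": self.female_longevity_sd,
            "male_longevity_mean": self.male_longevity_mean,
            "male_longevity_sd": self.male_longevity_sd,
            "fecundity_target": self.fecundity_target,
            "fecundity_peak_day": self.fecundity_peak_day,
            "fecundity_end_day": self.fecundity_end_day,
            "fecundity_dispersion": self.fecundity_dispersion,
        }

    @classmethod
    def from_dict(cls, d: dict, schema: StageSchema = DEFAULT_SCHEMA) -> "TreatmentSpec":
        d = dict(d)
        for key in ("stage_death_probs", "stage_duration_means", "stage_duration_sds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(schema=schema, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TreatmentSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_preset(name: str) -> TreatmentSpec:
    """Load one of the packaged treatment presets (control, paw1, paw2)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    text = resources.files("twosexlt.presets").joinpath(f"{name}.yaml").read_text()
    return TreatmentSpec.from_dict(yaml.safe_load(text))


def _draw(rng: np.random.Generator, values: np.ndarray, pmf: np.ndarray, size: int):
    return rng.choice(values, size=size, p=pmf)


def generate_cohort(
    spec: TreatmentSpec, n: int | None = None, seed: int | None = None
) -> CohortTable:
    """Draw a cohort of independent individual life histories.

    ``n`` and ``seed`` override the spec's own values; a fixed seed gives
    a bit-identical cohort.
    """
    n = spec.n if n is None else int(n)
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    schema = spec.schema
    n_imm = schema.first_adult

    durations = np.empty((n, n_imm), dtype=int)
    for j in range(n_imm):
        ks, pmf = _discretized_normal(
            spec.stage_duration_means[j], spec.stage_duration_sds[j]
        )
        durations[:, j] = _draw(rng, ks, pmf, n)
    dies_in_stage = rng.random((n, n_imm)) < np.asarray(spec.stage_death_probs)
    is_female = rng.random(n) < spec.p_female
    ak, ap = _discretized_normal(spec.apop_mean, spec.apop_sd)
    apops = _draw(rng, ak, ap, n)
    fk, fp = _discretized_normal(spec.female_longevity_mean, spec.female_longevity_sd)
    f_long = _draw(rng, fk, fp, n)
    mk, mp = _discretized_normal(spec.male_longevity_mean, spec.male_longevity_sd)
    m_long = _draw(rng, mk, mp, n)

    scale = spec.fecundity_scale() if spec.fecundity_target > 0 else 0.0
    shape = spec.fecundity_curve_shape()

    records = []
    for i in range(n):
        entries: list[int | None] = [None] * n_imm
        age = 0
        died_immature = False
        for j in range(n_imm):
            entries[j] = age
            age += durations[i, j]
            if dies_in_stage[i, j]:
                died_immature = True
                break
        if died_immature:
            rec = IndividualRecord(
                id=f"{spec.name}-{i + 1:04d}",
                sex=SEX_IMMATURE,
                immature_entries=tuple(entries),
                adult_entry=None,
                death_age=age,
            )
            records.append(rec)
            continue
        adult_entry = age
        if is_female[i]:
            longevity = int(f_long[i])
            death_age = adult_entry + longevity
            eggs = np.zeros(death_age, dtype=int)
            a_hi = min(longevity, len(shape))
            for a in range(int(apops[i]), a_hi):
                mu = scale * shape[a]
                if mu <= 0:
                    continue
                if spec.fecundity_dispersion is None:
                    eggs[adult_entry + a] = rng.poisson(mu)
                else:
                    k = spec.fecundity_dispersion
                    eggs[adult_entry + a] = rng.negative_binomial(k, k / (k + mu))
            while len(eggs) and eggs[-1] == 0:
                eggs = eggs[:-1]
            rec = IndividualRecord(
                id=f"{spec.name}-{i + 1:04d}",
                sex=SEX_FEMALE,
                immature_entries=tuple(entries),
                adult_entry=adult_entry,
                death_age=death_age,
                eggs=tuple(int(e) for e in eggs),
            )
        else:
            rec = IndividualRecord(
                id=f"{spec.name}-{i + 1:04d}",
                sex=SEX_MALE,
                immature_entries=tuple(entries),
                adult_entry=adult_entry,
                death_age=adult_entry + int(m_long[i]),
            )
        records.append(rec)
    return CohortTable(schema=schema, records=tuple(records), treatment=spec.name)


def expected_schedules(spec: TreatmentSpec) -> ScheduleSet:
    """Closed-form expected schedules for a deterministic-duration spec.

    Requires analytic mode (all duration/APOP/longevity dispersions zero);
    survival through stage j multiplies the cohort fraction by
    (1 - q_j), with deaths occurring on the would-be molting day.

    Raises
    ------
    CohortValidationError
        If the spec has any nonzero dispersion.
    """
    if not spec.deterministic:
        raise CohortValidationError(
            "expected_schedules requires a deterministic (zero-dispersion) spec"
        )
    schema = spec.schema
    n_imm = schema.first_adult
    k = schema.k
    dur = [max(1, round(m)) for m in spec.stage_duration_means]
    entries = np.concatenate([[0], np.cumsum(dur)])  # entry age of each stage
    adult_entry = int(entries[-1])
    lf = max(1, round(spec.female_longevity_mean))
    lm = max(1, round(spec.male_longevity_mean))
    apop = max(1, round(spec.apop_mean))
    omega = adult_entry + max(lf, lm)

    frac = np.cumprod([1.0] + [1 - q for q in spec.stage_death_probs])
    adult_frac = frac[-1]
    s = np.zeros((omega + 1, k))
    for j in range(n_imm):
        s[entries[j] : entries[j + 1], j] = frac[j]
    s[adult_entry : adult_entry + lf, schema.female_stage] = adult_frac * spec.p_female
    s[adult_entry : adult_entry + lm, schema.male_stage] = adult_frac * (1 - spec.p_female)

    f = np.zeros((omega + 1, k))
    if spec.fecundity_target > 0:
        scale = spec.fecundity_scale()
        shape = spec.fecundity_curve_shape()
        for a in range(apop, min(lf, len(shape))):
            f[adult_entry + a, schema.female_stage] = scale * shape[a]

    l = s.sum(axis=1)
    E = f * s * spec.n
    with np.errstate(invalid="ignore"):
        m = np.where(l > 0, (s * f).sum(axis=1) / np.where(l > 0, l, 1.0), 0.0)
    return ScheduleSet(
        stage_names=schema.stages, s=s, l=l, f=f, m=m, E=E, n01=spec.n, omega=omega
    )
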