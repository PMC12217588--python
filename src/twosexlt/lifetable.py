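"""Age-stage survival and fecundity schedules and reproductive summaries.

For a cohort started from n01 newly laid eggs, the age-stage, two-sex
framework tracks both the age x (days) and stage j of every individual:

* ``s_xj = n_xj / n01`` — probability a newborn survives to age x and is
  then in stage j (n_xj counts live, non-excluded individuals).
* ``l_x = sum_j s_xj`` — age-specific survival.
* ``f_xj = E_xj / n_xj`` — daily eggs per living stage-j individual of
  age x (nonzero only in the adult-female column); 0 where n_xj = 0.
* ``m_x = sum_j s_xj f_xj / sum_j s_xj`` — daily eggs per living
  individual of age x.

Schedules are raw empirical proportions with no smoothing, capped at the
cohort-specific maximum observed age omega (the greatest death age, where
survival first reaches its final value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    SEX_FEMALE,
    SEX_MALE,
    CohortTable,
    CohortValidationError,
    MeanSE,
)

__all__ = [
    "ScheduleSet",
    "ReproductiveSummary",
    "compute_schedules",
    "reproductive_summary",
]


@dataclass(frozen=True)
class ScheduleSet:
    """The s_xj / l_x / f_xj / m_x arrays over ages 0..omega.

    ``s``, ``f`` and ``E`` are (omega+1, k) matrices (rows ages, columns
    stages in schema order); ``l`` and ``m`` are length omega+1 vectors.
    ``E[x, j]`` is the total number of eggs laid at age x by stage-j
    individuals (an intermediate for f_xj).
    """

    stage_names: tuple[str, ...]
    s: np.ndarray
    l: np.ndarray
    f: np.ndarray
    m: np.ndarray
    E: np.ndarray
    n01: int
    omega: int

    @property
    def lx_mx(self) -> np.ndarray:
        """The net-maternity sequence l_x * m_x (= sum_j s_xj f_xj)."""
        return (self.s * self.f).sum(axis=1)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per (age, stage) with s_xj and f_xj."""
        ages = np.repeat(np.arange(self.omega + 1), len(self.stage_names))
        stages = np.tile(self.stage_names, self.omega + 1)
        return pd.DataFrame(
            {
                "age": ages,
                "stage": stages,
                "s_xj": self.s.ravel(),
                "f_xj": self.f.ravel(),
            }
        )

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide format: age, l_x, m_x and the net-maternity product."""
        return pd.DataFrame(
            {
                "age": np.arange(self.omega + 1),
                "l_x": self.l,
                "m_x": self.m,
                "lx_mx": self.lx_mx,
            }
        )


def compute_schedules(cohort: CohortTable) -> ScheduleSet:
    """Compute the empirical age-stage schedules of a cohort.

    Daily census: an individual with death age d is alive at ages x < d,
    occupying the stage whose entry age is the greatest one <= x.  Eggs
    laid at age x are credited to the layer's stage at that age.
    """
    active = cohort.active_records
    if not active:
        raise CohortValidationError("all individuals are excluded")
    schema = cohort.schema
    k = schema.k
    n01 = len(active)
    omega = max(r.death_age for r in active)

    n_xj = np.zeros((omega + 1, k), dtype=float)
    E = np.zeros((omega + 1, k), dtype=float)
    for r in active:
        for x in range(r.death_age):
            j = r.stage_at_age(schema, x)
            if j is not None:
                n_xj[x, j] += 1
        for x, e in enumerate(r.eggs):
            if e > 0:
                j = r.stage_at_age(schema, x)
                E[x, j] += e

    s = n_xj / n01
    l = s.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_xj > 0, E / np.where(n_xj > 0, n_xj, 1.0), 0.0)
        m = np.where(l > 0, (s * f).sum(axis=1) / np.where(l > 0, l, 1.0), 0.0)
    return ScheduleSet(
        stage_names=schema.stages,
        s=s,
        l=l,
        f=f,
        m=m,
        E=E,
        n01=n01,
        omega=omega,
    )


@dataclass(frozen=True)
class ReproductiveSummary:
    """Reproductive-period statistics of a cohort.

    APOP (adult pre-oviposition period) is first-egg age minus adult
    entry age; TPOP (total pre-oviposition period) is the first-egg age
    itself, both per laying female.  Oviposition days counts ages with at
    least one whole egg.  Adult longevity is death age minus adult entry
    age, per sex.  ``sex_ratio`` is females / n01 (the convention under
    which the published values are recovered from the stage counts);
    ``sex_ratio_of_adults`` is the label-literal females/(females+males).
    ``defined`` is False when no female laid an egg, in which case
    APOP/TPOP/fecundity are NaN rather than zero.
    """

    apop: MeanSE
    tpop: MeanSE
    oviposition_days: MeanSE
    female_longevity: MeanSE
    male_longevity: MeanSE
    fecundity: MeanSE
    sex_ratio: float
    sex_ratio_of_adults: float
    n_female: int
    n_male: int
    n01: int
    defined: bool


def reproductive_summary(cohort: CohortTable) -> ReproductiveSummary:
    active = cohort.active_records
    if not active:
        raise CohortValidationError("all individuals are excluded")
    n01 = len(active)
    females = [r for r in active if r.sex == SEX_FEMALE]
    males = [r for r in active if r.sex == SEX_MALE]
    layers = [r for r in females if r.first_egg_age is not None]

    apop = MeanSE.of([r.first_egg_age - r.adult_entry for r in layers])
    tpop = MeanSE.of([r.first_egg_age for r in layers])
    ovi = MeanSE.of([r.oviposition_days for r in layers])
    fec = MeanSE.of([r.total_eggs for r in females])
    n_adults = len(females) + len(males)
    return ReproductiveSummary(
        apop=apop,
        tpop=tpop,
        oviposition_days=ovi,
        female_longevity=MeanSE.of([r.death_age - r.adult_entry for r in females]),
        male_longevity=MeanSE.of([r.death_age - r.adult_entry for r in males]),
        fecundity=fec,
        sex_ratio=len(females) / n01,
        sex_ratio_of_adults=(len(females) / n_adults) if n_adults else float("nan"),
        n_female=len(females),
        n_male=len(males),
        n01=n01,
        defined=bool(layers),
    )
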