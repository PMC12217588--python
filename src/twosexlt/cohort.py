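"""Individual-level cohort data model, CSV input/output, and stage summaries.

The unit of observation is one organism followed daily from egg to death:
the age (in days, 0-based) at which it entered each developmental stage,
its sex once adult, its death age, and its daily egg counts.  A cohort is
the set of such records for one treatment, started from ``n01`` newly laid
eggs.  Ages are integer days: the day an egg is laid is age 0, and a stage
"entered on day x" means the daily census at age x first records that
stage.  An individual with death age d is counted alive at ages
``x < d`` and dead from age d onward.

Escapees (e.g. mites dead on the cotton barrier) are kept in the file with
``excluded = 1`` but dropped from ``n01`` and from every analysis, keeping
raw data auditable.  Censoring (individual alive at last observation) is
carried by the data model and treated as alive-through-last-observation
for the survival schedules, with a warning; the downstream summary
statistics assume an uncensored cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageSchema",
    "IndividualRecord",
    "CohortTable",
    "CohortValidationError",
    "CohortParseError",
    "StageSummaries",
    "read_cohort",
    "write_cohort",
    "stage_summaries",
    "MeanSE",
]


class CohortValidationError(ValueError):
    """A record or cohort violates an invariant of the data model."""


class CohortParseError(ValueError):
    """A cohort CSV file is malformed (bad header, cell, or row)."""


SEX_FEMALE = "F"
SEX_MALE = "M"
SEX_IMMATURE = "N"  # died (or censored) before reaching any adult stage
VALID_SEXES = (SEX_FEMALE, SEX_MALE, SEX_IMMATURE)


@dataclass(frozen=True)
class StageSchema:
    """Ordered developmental stages with the adult split into female/male.

    Parameters
    ----------
    stages
        Stage names ordered from egg to adult.  The immature path is
        ``stages[:first_adult]``; every individual traverses it in order
        (until death), then enters exactly one adult stage determined by
        its sex.
    first_adult
        Index of the first adult stage.
    female_stage, male_stage
        Indices of the adult-female and adult-male stages.
    """

    stages: tuple[str, ...] = (
        "egg",
        "larva",
        "protonymph",
        "deutonymph",
        "adult-female",
        "adult-male",
    )
    first_adult: int = 4
    female_stage: int = 4
    male_stage: int = 5

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise CohortValidationError("schema needs at least two stages")
        if len(set(self.stages)) != len(self.stages):
            raise CohortValidationError("stage names must be unique")
        if any(not s for s in self.stages):
            raise CohortValidationError("stage names must be nonempty")
        if not (0 < self.first_adult < len(self.stages)):
            raise CohortValidationError("first_adult index out of range")
        if self.female_stage == self.male_stage:
            raise CohortValidationError("female and male stages must differ")
        for idx in (self.female_stage, self.male_stage):
            if not (self.first_adult <= idx < len(self.stages)):
                raise CohortValidationError(
                    "adult stage indices must lie at or after first_adult"
                )

    @property
    def k(self) -> int:
        """Total number of stages."""
        return len(self.stages)

    @property
    def immature_stages(self) -> tuple[str, ...]:
        return self.stages[: self.first_adult]

    def adult_stage_for_sex(self, sex: str) -> int | None:
        if sex == SEX_FEMALE:
            return self.female_stage
        if sex == SEX_MALE:
            return self.male_stage
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": list(self.stages),
                "first_adult": self.first_adult,
                "female_stage": self.female_stage,
                "male_stage": self.male_stage,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StageSchema":
        d = json.loads(text)
        return cls(
            stages=tuple(d["stages"]),
            first_adult=int(d["first_adult"]),
            female_stage=int(d["female_stage"]),
            male_stage=int(d["male_stage"]),
        )


DEFAULT_SCHEMA = StageSchema()


@dataclass(frozen=True)
class IndividualRecord:
    """One organism's full life history.

    ``immature_entries`` holds the entry age for each immature stage in
    schema order, ``None`` once the path was cut short by death.
    ``adult_entry`` is the age of adult emergence (``None`` if the
    individual died immature).  ``eggs`` is the daily egg count indexed by
    age (trailing zeros may be omitted).  ``death_age`` is the first age
    at which the individual was recorded dead; for a censored individual
    it is the last age at which it was seen alive plus one.
    """

    id: str
    sex: str
    immature_entries: tuple[int | None, ...]
    adult_entry: int | None
    death_age: int
    eggs: tuple[int, ...] = ()
    excluded: bool = False
    censored: bool = False

    def validate(self, schema: StageSchema) -> None:
        if self.sex not in VALID_SEXES:
            raise CohortValidationError(
                f"individual {self.id!r}: sex must be one of {VALID_SEXES}, got {self.sex!r}"
            )
        n_imm = schema.first_adult
        if len(self.immature_entries) != n_imm:
            raise CohortValidationError(
                f"individual {self.id!r}: expected {n_imm} immature entry ages, "
                f"got {len(self.immature_entries)}"
            )
        if self.immature_entries[0] != 0:
            raise CohortValidationError(
                f"individual {self.id!r}: egg entry age must be 0"
            )
        traversed = [a for a in self.immature_entries if a is not None]
        # no gaps: once a stage is unreached, all later stages are unreached
        seen_none = False
        for a in self.immature_entries:
            if a is None:
                seen_none = True
            elif seen_none:
                raise CohortValidationError(
                    f"individual {self.id!r}: stage entry after an unreached stage"
                )
        path = list(traversed)
        if self.adult_entry is not None:
            if seen_none:
                raise CohortValidationError(
                    f"individual {self.id!r}: adult entry with incomplete immature path"
                )
            path.append(self.adult_entry)
        if any(b <= a for a, b in zip(path, path[1:])):
            raise CohortValidationError(
                f"individual {self.id!r}: stage entry ages must strictly increase"
            )
        if self.sex == SEX_IMMATURE:
            if self.adult_entry is not None:
                raise CohortValidationError(
                    f"individual {self.id!r}: died-immature individuals cannot "
                    "have an adult entry age"
                )
            if self.total_eggs > 0:
                raise CohortValidationError(
                    f"individual {self.id!r}: died-immature individuals cannot lay eggs"
                )
        elif self.adult_entry is None:
            raise CohortValidationError(
                f"individual {self.id!r}: sex {self.sex!r} requires an adult entry age"
            )
        if self.death_age < path[-1]:
            raise CohortValidationError(
                f"individual {self.id!r}: death age {self.death_age} precedes "
                f"last stage entry {path[-1]}"
            )
        if any(e < 0 for e in self.eggs):
            raise CohortValidationError(
                f"individual {self.id!r}: egg counts must be nonnegative"
            )
        if self.total_eggs > 0:
            if self.sex != SEX_FEMALE:
                raise CohortValidationError(
                    f"individual {self.id!r}: only females lay eggs"
                )
            laying_ages = [x for x, e in enumerate(self.eggs) if e > 0]
            if laying_ages and laying_ages[0] < self.adult_entry:
                raise CohortValidationError(
                    f"individual {self.id!r}: egg laid at age {laying_ages[0]} "
                    f"before adult entry {self.adult_entry}"
                )
            if laying_ages and laying_ages[-1] >= self.death_age:
                raise CohortValidationError(
                    f"individual {self.id!r}: egg laid at age {laying_ages[-1]} "
                    f"at or after death age {self.death_age}"
                )

    @property
    def total_eggs(self) -> int:
        return int(sum(self.eggs))

    @property
    def reached_adult(self) -> bool:
        return self.adult_entry is not None

    @property
    def first_egg_age(self) -> int | None:
        for x, e in enumerate(self.eggs):
            if e > 0:
                return x
        return None

    @property
    def oviposition_days(self) -> int:
        return int(sum(1 for e in self.eggs if e >= 1))

    def stage_at_age(self, schema: StageSchema, x: int) -> int | None:
        """Stage index occupied at age x, or None if not alive at x."""
        if x < 0 or x >= self.death_age:
            return None
        stage = None
        for j, a in enumerate(self.immature_entries):
            if a is not None and a <= x:
                stage = j
        if self.adult_entry is not None and self.adult_entry <= x:
            stage = schema.adult_stage_for_sex(self.sex)
        return stage


@dataclass(frozen=True)
class CohortTable:
    """Validated collection of IndividualRecords for one treatment."""

    schema: StageSchema
    records: tuple[IndividualRecord, ...]
    treatment: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise CohortValidationError(f"duplicate individual ids: {sorted(dupes)}")
        for r in self.records:
            r.validate(self.schema)
        if any(r.censored for r in self.active_records):
            warnings.warn(
                "cohort contains censored individuals; they are treated as "
                "alive through last observation for survival schedules only",
                stacklevel=2,
            )

    @property
    def active_records(self) -> tuple[IndividualRecord, ...]:
        return tuple(r for r in self.records if not r.excluded)

    @property
    def n01(self) -> int:
        """Number of non-excluded individuals starting the life table."""
        return len(self.active_records)

    def with_records(self, records: Iterable[IndividualRecord]) -> "CohortTable":
        return replace(self, records=tuple(records))


# ---------------------------------------------------------------------------
# CSV input/output
#
# Dialect: comma-separated, UTF-8, one row per individual.  Columns:
#   id, treatment, excluded (0/1), censored (0/1), sex (F/M/N),
#   age_<stage> for each immature stage (blank = never reached),
#   age_adult (blank if died immature), death_age,
#   eggs_d0, eggs_d1, ... (daily egg counts by age; trailing zeros
#   omissible; a cohort file carries enough eggs_d columns for its oldest
#   layer).
# The `censored` column is this package's extension carrying the censored
# flag required by the data model.
# ---------------------------------------------------------------------------


def _fixed_columns(schema: StageSchema) -> list[str]:
    return (
        ["id", "treatment", "excluded", "censored", "sex"]
        + [f"age_{s}" for s in schema.immature_stages]
        + ["age_adult", "death_age"]
    )


def _parse_int_cell(value, row: int, col: str, allow_blank: bool = False):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        if allow_blank:
            return None
        raise CohortParseError(f"row {row}: column {col!r} is blank")
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise CohortParseError(
            f"row {row}: column {col!r} has non-numeric value {value!r}"
        ) from None
    if f != int(f):
        raise CohortParseError(
            f"row {row}: column {col!r} must be an integer, got {value!r}"
        )
    return int(f)


def read_cohort(path: str | Path, schema: StageSchema = DEFAULT_SCHEMA) -> CohortTable:
    """Read and validate a cohort CSV file.

    Raises
    ------
    CohortParseError
        Malformed header or cell (the message names the row and column).
    CohortValidationError
        A record violates the data model, or the file contains no
        analyzable (non-excluded) individuals.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=object, keep_default_na=True)
    fixed = _fixed_columns(schema)
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path.name}: missing required columns {missing}")
    egg_cols = [c for c in df.columns if c.startswith("eggs_d")]

    def egg_age(col: str) -> int:
        try:
            return int(col[len("eggs_d"):])
        except ValueError:
            raise CohortParseError(f"malformed egg-count column name {col!r}") from None

    egg_cols.sort(key=egg_age)

    records: list[IndividualRecord] = []
    treatments: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        row_d = dict(zip(df.columns, row))
        rid = row_d["id"]
        if rid is None or (isinstance(rid, float) and np.isnan(rid)):
            raise CohortParseError(f"row {i}: column 'id' is blank")
        treatments.add(str(row_d.get("treatment", "") or ""))
        sex = str(row_d["sex"]).strip()
        immature = tuple(
            _parse_int_cell(row_d[f"age_{s}"], i, f"age_{s}", allow_blank=True)
            for s in schema.immature_stages
        )
        adult = _parse_int_cell(row_d["age_adult"], i, "age_adult", allow_blank=True)
        death = _parse_int_cell(row_d["death_age"], i, "death_age")
        eggs_list = []
        for c in egg_cols:
            v = _parse_int_cell(row_d.get(c), i, c, allow_blank=True)
            eggs_list.append(0 if v is None else v)
        while eggs_list and eggs_list[-1] == 0:
            eggs_list.pop()
        rec = IndividualRecord(
            id=str(rid),
            sex=sex,
            immature_entries=immature,
            adult_entry=adult,
            death_age=death,
            eggs=tuple(eggs_list),
            excluded=bool(_parse_int_cell(row_d["excluded"], i, "excluded")),
            censored=bool(_parse_int_cell(row_d["censored"], i, "censored")),
        )
        records.append(rec)

    treatment = treatments.pop() if len(treatments) == 1 else ""
    cohort = CohortTable(schema=schema, records=tuple(records), treatment=treatment)
    if cohort.n01 == 0:
        raise CohortValidationError(
            f"{path.name}: no non-excluded individuals (n01 = 0 is not analyzable)"
        )
    return cohort


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV; ``read_cohort`` round-trips it losslessly."""
    path = Path(path)
    schema = cohort.schema
    omega = max((len(r.eggs) for r in cohort.records), default=0)
    rows = []
    for r in cohort.records:
        d: dict[str, object] = {
            "id": r.id,
            "treatment": cohort.treatment,
            "excluded": int(r.excluded),
            "censored": int(r.censored),
            "sex": r.sex,
        }
        for s, a in zip(schema.immature_stages, r.immature_entries):
            d[f"age_{s}"] = "" if a is None else a
        d["age_adult"] = "" if r.adult_entry is None else r.adult_entry
        d["death_age"] = r.death_age
        for x in range(omega):
            d[f"eggs_d{x}"] = r.eggs[x] if x < len(r.eggs) else 0
        rows.append(d)
    cols = _fixed_columns(schema) + [f"eggs_d{x}" for x in range(omega)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stage summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeanSE:
    """A sample mean with its standard error and sample size."""

    mean: float
    se: float
    n: int

    @classmethod
    def of(cls, values: Sequence[float]) -> "MeanSE":
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            return cls(float("nan"), float("nan"), 0)
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        return cls(float(v.mean()), se, int(v.size))


@dataclass(frozen=True)
class StageSummaries:
    """Per-stage durations, stage-specific deaths, and cohort composition."""

    durations: dict[str, MeanSE]
    deaths: dict[str, int]
    immature_mortality: float
    female_preadult: MeanSE
    male_preadult: MeanSE
    n_female: int
    n_male: int
    n_immature_dead: int
    n_censored_immature: int
    n01: int


def stage_summaries(cohort: CohortTable) -> StageSummaries:
    """Stage durations, death counts, and immature mortality for a cohort.

    A stage's duration for an individual is the entry age of the next
    stage minus the entry age of this stage; the stage an individual died
    in contributes no duration.  Immature mortality is the proportion of
    the ``n01`` starters that died before reaching any adult stage.
    """
    schema = cohort.schema
    active = cohort.active_records
    n01 = len(active)
    if n01 == 0:
        raise CohortValidationError("cohort has no non-excluded individuals")

    durations: dict[str, list[int]] = {s: [] for s in schema.immature_stages}
    deaths: dict[str, int] = {s: 0 for s in schema.immature_stages}
    n_censored_immature = 0
    for r in active:
        entries = list(r.immature_entries) + [r.adult_entry]
        for j, s in enumerate(schema.immature_stages):
            a, b = entries[j], entries[j + 1]
            if a is not None and b is not None:
                durations[s].append(b - a)
        if not r.reached_adult:
            last = max(j for j, a in enumerate(r.immature_entries) if a is not None)
            if r.censored:
                n_censored_immature += 1
            else:
                deaths[schema.immature_stages[last]] += 1

    n_adult = sum(1 for r in active if r.reached_adult)
    females = [r for r in active if r.sex == SEX_FEMALE]
    males = [r for r in active if r.sex == SEX_MALE]
    return StageSummaries(
        durations={s: MeanSE.of(v) for s, v in durations.items()},
        deaths=deaths,
        immature_mortality=(n01 - n_adult) / n01,
        female_preadult=MeanSE.of([r.adult_entry for r in females]),
        male_preadult=MeanSE.of([r.adult_entry for r in males]),
        n_female=len(females),
        n_male=len(males),
        n_immature_dead=n01 - n_adult - n_censored_immature,
        n_censored_immature=n_censored_immature,
        n01=n01,
    )
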