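"""Shared fixtures: handcrafted and generated cohorts."""

from __future__ import annotations

import pytest

from twosexlt import (
    CohortTable,
    IndividualRecord,
    StageSchema,
    generate_cohort,
    load_preset,
)

SCHEMA = StageSchema()


def make_female(
    rid: str,
    adult_entry: int = 16,
    death_age: int = 33,
    eggs: dict[int, int] | None = None,
    durations: tuple[int, int, int, int] = (8, 3, 2, 3),
    excluded: bool = False,
) -> IndividualRecord:
    entries, a = [], 0
    for d in durations:
        entries.append(a)
        a += d
    # stretch/compress the last immature stage so adult entry lands where asked
    entries = tuple(entries)
    if a != adult_entry:
        entries = tuple(entries[:-1]) + (entries[-1] + (adult_entry - a),)
    egg_vec = ()
    if eggs:
        omega = max(eggs) + 1
        egg_vec = tuple(eggs.get(x, 0) for x in range(omega))
    return IndividualRecord(
        id=rid,
        sex="F",
        immature_entries=entries,
        adult_entry=adult_entry,
        death_age=death_age,
        eggs=egg_vec,
        excluded=excluded,
    )


def make_male(
    rid: str,
    adult_entry: int = 16,
    death_age: int = 30,
    durations: tuple[int, int, int, int] = (8, 3, 2, 3),
) -> IndividualRecord:
    entries, a = [], 0
    for d in durations:
        entries.append(a)
        a += d
    return IndividualRecord(
        id=rid,
        sex="M",
        immature_entries=tuple(entries),
        adult_entry=adult_entry,
        death_age=death_age,
    )


def make_immature_death(
    rid: str,
    dies_in_stage: int,
    durations: tuple[int, int, int, int] = (8, 3, 2, 3),
) -> IndividualRecord:
    entries: list[int | None] = [None] * 4
    a = 0
    for j in range(dies_in_stage + 1):
        entries[j] = a
        a += durations[j]
    return IndividualRecord(
        id=rid,
        sex="N",
        immature_entries=tuple(entries),
        adult_entry=None,
        death_age=a,
    )


def counts_cohort(
    n_female: int,
    n_male: int,
    stage_deaths: tuple[int, int, int, int],
    eggs_per_female: int = 0,
    treatment: str = "fixture",
) -> CohortTable:
    """Deterministic cohort with exact sex and stage-death counts.

    All individuals share the stage durations (8, 3, 2, 3); females die
    17 days after adult emergence, males after 14, and lay
    ``eggs_per_female`` eggs split evenly over days 18-27 of age.
    """
    records = []
    i = 0
    for _ in range(n_female):
        i += 1
        eggs = {}
        if eggs_per_female:
            per_day, rem = divmod(eggs_per_female, 10)
            for d in range(10):
                eggs[18 + d] = per_day + (1 if d < rem else 0)
        records.append(make_female(f"f{i}", 16, 33, eggs))
    for _ in range(n_male):
        i += 1
        records.append(make_male(f"m{i}", 16, 30))
    for j, k in enumerate(stage_deaths):
        for _ in range(k):
            i += 1
            records.append(make_immature_death(f"d{i}", j))
    return CohortTable(schema=SCHEMA, records=tuple(records), treatment=treatment)


@pytest.fixture(scope="session")
def control_cohort() -> CohortTable:
    return generate_cohort(load_preset("control"), n=50, seed=42)


@pytest.fixture(scope="session")
def paw1_cohort() -> CohortTable:
    return generate_cohort(load_preset("paw1"), n=50, seed=43)


@pytest.fixture(scope="session")
def paw2_cohort() -> CohortTable:
    return generate_cohort(load_preset("paw2"), n=50, seed=44)
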