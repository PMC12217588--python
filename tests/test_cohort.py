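"""Data model, CSV round-trip, validation, and stage summaries."""

import dataclasses

import pytest

import twosexlt as t
from twosexlt.cohort import CohortParseError, CohortValidationError

from conftest import (
    SCHEMA,
    counts_cohort,
    make_female,
    make_immature_death,
    make_male,
)


@pytest.mark.parametrize("preset,seed", [("control", 1), ("paw1", 2), ("paw2", 3)])
def test_csv_round_trip_is_lossless(tmp_path, preset, seed):
    cohort = t.generate_cohort(t.load_preset(preset), n=30, seed=seed)
    # add an excluded escapee and a censored survivor to exercise the flags
    extra = (
        dataclasses.replace(make_female("escapee", eggs={18: 2}), excluded=True),
        dataclasses.replace(make_male("cens"), censored=True),
    )
    cohort = cohort.with_records(cohort.records + extra)
    path = tmp_path / "cohort.csv"
    t.write_cohort(cohort, path)
    with pytest.warns(UserWarning, match="censored"):
        back = t.read_cohort(path)
    assert back.records == cohort.records
    assert back.treatment == cohort.treatment
    assert back.n01 == cohort.n01


def test_excluded_individuals_drop_from_n01(tmp_path):
    records = [make_female(f"f{i}") for i in range(9)]
    records.append(dataclasses.replace(make_female("f9"), excluded=True))
    cohort = t.CohortTable(schema=SCHEMA, records=tuple(records))
    assert len(cohort.records) == 10
    assert cohort.n01 == 9
    path = tmp_path / "c.csv"
    t.write_cohort(cohort, path)
    assert t.read_cohort(path).n01 == 9


def test_empty_file_with_valid_header_is_not_analyzable(tmp_path):
    cohort = t.CohortTable(schema=SCHEMA, records=(make_female("f1"),))
    path = tmp_path / "c.csv"
    t.write_cohort(cohort, path)
    text = path.read_text().splitlines()[0]
    path.write_text(text + "\n")
    with pytest.raises(CohortValidationError, match="n01"):
        t.read_cohort(path)


def test_malformed_cell_error_names_row_and_column(tmp_path):
    cohort = t.CohortTable(schema=SCHEMA, records=(make_female("f1"),))
    path = tmp_path / "c.csv"
    t.write_cohort(cohort, path)
    lines = path.read_text().splitlines()
    lines[1] = lines[1].replace("33", "thirty-three")
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(CohortParseError, match="row 2.*death_age"):
        t.read_cohort(path)


def test_missing_column_is_a_parse_error(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text("id,sex\nx,F\n")
    with pytest.raises(CohortParseError, match="missing required columns"):
        t.read_cohort(path)


@pytest.mark.parametrize(
    "build,msg",
    [
        # decreasing entry ages
        (
            lambda: t.IndividualRecord(
                "bad", "F", (0, 8, 7, 13), 16, 33
            ),
            "strictly increase",
        ),
        # died-immature with eggs
        (
            lambda: t.IndividualRecord(
                "bad", "N", (0, 8, None, None), None, 11, eggs=(0,) * 9 + (1,)
            ),
            "cannot lay eggs",
        ),
        # egg laid before adult entry
        (
            lambda: t.IndividualRecord(
                "bad", "F", (0, 8, 11, 13), 16, 33, eggs=(0,) * 15 + (2,)
            ),
            "before adult entry",
        ),
        # death precedes last entry
        (
            lambda: t.IndividualRecord("bad", "M", (0, 8, 11, 13), 16, 15),
            "death age",
        ),
        # male with eggs
        (
            lambda: t.IndividualRecord(
                "bad", "M", (0, 8, 11, 13), 16, 33, eggs=(0,) * 18 + (1,)
            ),
            "only females",
        ),
    ],
)
def test_record_invariant_violations_name_the_individual(build, msg):
    with pytest.raises(CohortValidationError, match="bad"):
        rec = build()
        rec.validate(SCHEMA)
    with pytest.raises(CohortValidationError, match=msg):
        build().validate(SCHEMA)


@pytest.mark.parametrize(
    "n_f,n_m,deaths,expected_mortality",
    [
        (41, 6, (1, 0, 1, 1), 0.06),  # control-like composition
        (25, 12, (6, 6, 1, 0), 0.26),  # PAW2-like composition
        (10, 5, (0, 0, 0, 0), 0.0),  # nobody dies
    ],
)
def test_immature_mortality_from_stage_death_counts(n_f, n_m, deaths, expected_mortality):
    cohort = counts_cohort(n_f, n_m, deaths)
    ss = t.stage_summaries(cohort)
    assert ss.n01 == n_f + n_m + sum(deaths)
    assert ss.immature_mortality == pytest.approx(expected_mortality)
    assert ss.deaths == dict(zip(SCHEMA.immature_stages, deaths))
    assert ss.n_female == n_f and ss.n_male == n_m


def test_identical_individuals_have_zero_duration_se():
    cohort = counts_cohort(5, 0, (0, 0, 0, 0))
    ss = t.stage_summaries(cohort)
    for ms in ss.durations.values():
        assert ms.se == 0.0
    assert ss.female_preadult.se == 0.0


def test_dying_stage_contributes_no_duration():
    cohort = t.CohortTable(
        schema=SCHEMA,
        records=(make_female("f1"), make_immature_death("d1", 1, (8, 3, 2, 3))),
    )
    ss = t.stage_summaries(cohort)
    assert ss.durations["larva"].n == 1  # only the survivor's larval stint counts
    assert ss.deaths["larva"] == 1


@pytest.mark.parametrize("preset", ["control", "paw1", "paw2"])
@pytest.mark.parametrize("seed", [1, 5, 9])
def test_cohort_composition_sums_to_n01(preset, seed):
    cohort = t.generate_cohort(t.load_preset(preset), n=50, seed=seed)
    ss = t.stage_summaries(cohort)
    assert (
        ss.n_female + ss.n_male + ss.n_immature_dead + ss.n_censored_immature
        == ss.n01
        == 50
    )


def test_stage_schema_invariants():
    with pytest.raises(CohortValidationError):
        t.StageSchema(stages=("egg", "egg", "adult-female", "adult-male"),
                      first_adult=2, female_stage=2, male_stage=3)
    with pytest.raises(CohortValidationError):
        t.StageSchema(female_stage=5, male_stage=5)
    with pytest.raises(CohortValidationError):
        t.StageSchema(female_stage=1)
    default = t.StageSchema()
    assert default.stages == (
        "egg", "larva", "protonymph", "deutonymph", "adult-female", "adult-male"
    )
    assert default.k == 6 and len(default.immature_stages) == 4
    assert t.StageSchema.from_json(default.to_json()) == default
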