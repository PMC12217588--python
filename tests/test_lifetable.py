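"""Schedules (s_xj, l_x, f_xj, m_x) against a brute-force census oracle."""

import numpy as np
import pytest

import twosexlt as t

from conftest import SCHEMA, counts_cohort, make_female, make_male


def brute_force_schedules(cohort):
    """Independent per-day, per-individual census recomputation of n_xj, E_xj."""
    active = [r for r in cohort.records if not r.excluded]
    omega = max(r.death_age for r in active)
    k = cohort.schema.k
    n_xj = np.zeros((omega + 1, k))
    e_xj = np.zeros((omega + 1, k))
    for x in range(omega + 1):
        for r in active:
            if x < r.death_age:
                # replay the stage history from scratch
                stage = None
                entries = list(r.immature_entries) + [r.adult_entry]
                names = list(range(cohort.schema.first_adult)) + [
                    cohort.schema.adult_stage_for_sex(r.sex)
                ]
                for j, a in zip(names, entries):
                    if a is not None and a <= x:
                        stage = j
                n_xj[x, stage] += 1
                if x < len(r.eggs):
                    e_xj[x, stage] += r.eggs[x]
    return n_xj, e_xj


def test_single_individual_egg_then_dead():
    rec = t.IndividualRecord("solo", "N", (0, None, None, None), None, 3)
    cohort = t.CohortTable(schema=SCHEMA, records=(rec,))
    sch = t.compute_schedules(cohort)
    assert sch.omega == 3
    assert np.array_equal(sch.l, [1, 1, 1, 0])
    assert np.array_equal(sch.s[:, 0], [1, 1, 1, 0])
    assert not sch.m.any()


def test_two_individuals_one_early_death():
    recs = (
        t.IndividualRecord("a", "N", (0, None, None, None), None, 1),
        t.IndividualRecord("b", "N", (0, None, None, None), None, 4),
    )
    sch = t.compute_schedules(t.CohortTable(schema=SCHEMA, records=recs))
    assert sch.l[1] == 0.5


def test_female_adult_plateau_matches_survivor_fraction():
    cohort = counts_cohort(41, 6, (1, 0, 1, 1), eggs_per_female=50)
    sch = t.compute_schedules(cohort)
    female_col = sch.s[:, SCHEMA.female_stage]
    assert female_col.max() == pytest.approx(41 / 50)


@pytest.mark.parametrize("preset,seed", [("control", 2), ("paw1", 7), ("paw2", 11)])
def test_schedules_match_brute_force_census_exactly(preset, seed):
    cohort = t.generate_cohort(t.load_preset(preset), n=50, seed=seed)
    sch = t.compute_schedules(cohort)
    n_xj, e_xj = brute_force_schedules(cohort)
    np.testing.assert_array_equal(sch.s, n_xj / cohort.n01)
    np.testing.assert_array_equal(sch.E, e_xj)
    with np.errstate(invalid="ignore"):
        f = np.where(n_xj > 0, e_xj / np.where(n_xj > 0, n_xj, 1), 0.0)
    np.testing.assert_array_equal(sch.f, f)
    l = n_xj.sum(axis=1) / cohort.n01
    np.testing.assert_allclose(sch.l, l, atol=0)
    # no resurrection: l_x nonincreasing
    assert np.all(np.diff(sch.l) <= 0 + 1e-15)


@pytest.mark.parametrize("preset,seed", [("control", 3), ("paw2", 8)])
def test_egg_conservation(preset, seed):
    cohort = t.generate_cohort(t.load_preset(preset), n=50, seed=seed)
    sch = t.compute_schedules(cohort)
    total_eggs = sum(r.total_eggs for r in cohort.active_records)
    assert np.sum(sch.l * sch.m) == pytest.approx(total_eggs / cohort.n01, rel=1e-12)
    assert sch.lx_mx.sum() == pytest.approx(total_eggs / cohort.n01, rel=1e-12)


def test_schedule_export_formats(control_cohort):
    sch = t.compute_schedules(control_cohort)
    wide = sch.to_wide_frame()
    assert list(wide.columns) == ["age", "l_x", "m_x", "lx_mx"]
    assert len(wide) == sch.omega + 1
    long = sch.to_long_frame()
    assert len(long) == (sch.omega + 1) * SCHEMA.k
    np.testing.assert_allclose(
        long.groupby("age", sort=True)["s_xj"].sum().to_numpy(), sch.l
    )


def test_reproductive_summary_single_female_arithmetic():
    rec = make_female("f1", adult_entry=16, death_age=33, eggs={17: 3, 18: 2})
    cohort = t.CohortTable(schema=SCHEMA, records=(rec,))
    rs = t.reproductive_summary(cohort)
    assert rs.apop.mean == 1
    assert rs.tpop.mean == 17
    assert rs.female_longevity.mean == 17
    assert rs.oviposition_days.mean == 2
    assert rs.fecundity.mean == 5


def test_sex_ratio_uses_n01_denominator_and_reports_adult_alternative():
    cohort = counts_cohort(41, 6, (1, 0, 1, 1), eggs_per_female=50)
    rs = t.reproductive_summary(cohort)
    assert rs.sex_ratio == pytest.approx(0.82)
    assert rs.sex_ratio_of_adults == pytest.approx(41 / 47)
    # fecundity mean x number of females = total cohort eggs
    total = sum(r.total_eggs for r in cohort.active_records)
    assert rs.fecundity.mean * rs.n_female == pytest.approx(total)


def test_all_male_cohort_has_undefined_reproduction():
    cohort = t.CohortTable(
        schema=SCHEMA, records=tuple(make_male(f"m{i}") for i in range(5))
    )
    rs = t.reproductive_summary(cohort)
    assert not rs.defined
    assert np.isnan(rs.fecundity.mean)
    assert np.isnan(rs.apop.mean)
    sch = t.compute_schedules(cohort)
    assert t.net_reproductive_rate(sch) == 0.0


def test_tpop_equals_apop_plus_preadult_per_individual(control_cohort):
    for r in control_cohort.active_records:
        if r.first_egg_age is not None:
            apop = r.first_egg_age - r.adult_entry
            assert r.first_egg_age == apop + r.adult_entry
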