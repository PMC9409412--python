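import math

import numpy as np
import pandas as pd
import pytest

from agestage.cohort import CohortTable, IndividualRecord
from agestage.lifetable import (
    LifeTableCurves,
    UndefinedParameterError,
    compute_age_stage,
    compute_curves,
    compute_R0,
    export_curves,
    finalize_parameters,
    lambda_from_r,
    r_from_R0_T,
    solve_r,
    summarize_cohort,
)
from agestage.simulate import SimulationConfig, preset_from_table, simulate_cohort

from .conftest import TOY_EXPECTED
from .oracles import grid_search_r, leslie_growth_factor


def _curves_from_schedule(schedule: dict[int, float]) -> LifeTableCurves:
    n = max(schedule) + 1
    phi = np.zeros(n)
    for age, mass in schedule.items():
        phi[age] = mass
    lx = np.ones(n)
    return LifeTableCurves(ages=np.arange(n), lx=lx, mx=phi, product=phi)


class TestCensus:
    def test_single_deterministic_record_convention(self):
        rec = IndividualRecord(
            id="solo",
            stage_durations={"egg": 3, "larva": 5, "pupa": 4},
            sex="female",
            fate="died_adult",
            death_stage="female",
            death_day=14,
            emergence_day=12,
        )
        asm = compute_age_stage(CohortTable("t", 1, [rec]))
        assert asm.S.shape == (14, 5)
        # exactly one unit entry per age, stage switching at 3, 8 and 12
        assert np.allclose(asm.S.sum(axis=1), 1.0)
        stage_idx = asm.S.argmax(axis=1)
        expected = [0] * 3 + [1] * 5 + [2] * 4 + [3] * 2
        assert stage_idx.tolist() == expected

    def test_all_die_in_egg_on_day_one(self):
        recs = [
            IndividualRecord(
                id=f"e{i}",
                stage_durations={},
                sex="unknown",
                fate="died_preadult",
                death_stage="egg",
                death_day=1,
            )
            for i in range(5)
        ]
        # add one survivor so ages extend past 0
        recs.append(
            IndividualRecord(
                id="s",
                stage_durations={"egg": 3, "larva": 5, "pupa": 4},
                sex="male",
                fate="died_adult",
                death_stage="male",
                death_day=14,
                emergence_day=12,
            )
        )
        asm = compute_age_stage(CohortTable("t", 6, recs))
        lx = asm.S.sum(axis=1)
        assert lx[0] == 1.0
        assert np.all(lx[1:] == pytest.approx(1.0 / 6.0))

    def test_toy_cohort_matches_hand_census(self, toy_cohort):
        asm = compute_age_stage(toy_cohort)
        expected = TOY_EXPECTED["S_nonzero"]
        col = {s: j for j, s in enumerate(asm.stages)}
        for x in range(asm.S.shape[0]):
            for stage, j in col.items():
                assert asm.S[x, j] == pytest.approx(
                    expected.get((x, stage), 0.0)
                ), (x, stage)

    def test_toy_fecundity_matrix(self, toy_cohort):
        asm = compute_age_stage(toy_cohort)
        fem = asm.female_column
        for x, value in TOY_EXPECTED["fx_female"].items():
            assert asm.F[x, fem] == pytest.approx(value)
        assert asm.F[:, :fem].sum() == 0.0  # eggs only in the female column


class TestCurves:
    def test_toy_curves(self, toy_cohort):
        curves = compute_curves(compute_age_stage(toy_cohort))
        assert curves.lx.tolist() == pytest.approx(TOY_EXPECTED["lx"])
        for x in range(len(curves.mx)):
            assert curves.mx[x] == pytest.approx(TOY_EXPECTED["mx"].get(x, 0.0))
        assert compute_R0(curves) == pytest.approx(TOY_EXPECTED["R0"])

    def test_l0_is_one_and_lx_monotone(self, toy_cohort):
        curves = compute_curves(compute_age_stage(toy_cohort))
        assert curves.lx[0] == 1.0
        assert np.all(np.diff(curves.lx) <= 1e-12)

    def test_zero_fecundity_gives_zero_R0(self):
        rec = IndividualRecord(
            id="m",
            stage_durations={"egg": 3, "larva": 5, "pupa": 4},
            sex="male",
            fate="died_adult",
            death_stage="male",
            death_day=14,
            emergence_day=12,
        )
        curves = compute_curves(compute_age_stage(CohortTable("t", 1, [rec])))
        assert np.all(curves.mx == 0.0)
        assert compute_R0(curves) == 0.0

    def test_single_female_laying_ten(self):
        rec = IndividualRecord(
            id="f",
            stage_durations={"egg": 3, "larva": 5, "pupa": 4},
            sex="female",
            fate="died_adult",
            death_stage="female",
            death_day=15,
            emergence_day=12,
            daily_eggs=[(12, 7), (13, 3)],
        )
        curves = compute_curves(compute_age_stage(CohortTable("t", 1, [rec])))
        assert compute_R0(curves) == pytest.approx(10.0)


class TestSolveR:
    def test_point_mass_closed_form(self):
        curves = _curves_from_schedule({9: 4.0})
        r = solve_r(curves)
        assert r == pytest.approx(math.log(4.0) / 10.0, abs=1e-10)

    def test_unit_mass_gives_zero(self):
        for age in (0, 3, 9):
            assert solve_r(_curves_from_schedule({age: 1.0})) == pytest.approx(
                0.0, abs=1e-10
            )

    def test_two_age_schedule_matches_grid_search(self):
        schedule = {5: 2.0, 8: 1.5}
        r = solve_r(_curves_from_schedule(schedule))
        assert r == pytest.approx(grid_search_r(schedule, 0.0, 0.4), abs=2e-6)

    def test_random_two_age_schedules_match_grid_search(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x1 = int(rng.integers(2, 10))
            x2 = x1 + int(rng.integers(1, 8))
            schedule = {x1: float(rng.uniform(0.3, 3.0)), x2: float(rng.uniform(0.3, 3.0))}
            r = solve_r(_curves_from_schedule(schedule))
            assert r == pytest.approx(
                grid_search_r(schedule, r - 0.01, r + 0.01), abs=2e-6
            )

    def test_euler_residual_below_tolerance(self, toy_cohort):
        curves = compute_curves(compute_age_stage(toy_cohort))
        r = solve_r(curves, tol=1e-10)
        params = finalize_parameters(curves, r)
        assert params.euler_residual < 1e-10

    def test_zero_R0_raises(self):
        curves = _curves_from_schedule({5: 0.0})
        with pytest.raises(UndefinedParameterError):
            solve_r(curves)

    def test_r_sign_tracks_R0(self):
        assert solve_r(_curves_from_schedule({4: 2.0})) > 0
        assert solve_r(_curves_from_schedule({4: 0.5})) < 0


class TestFinalize:
    def test_lambda_and_T_identities(self, toy_cohort):
        curves = compute_curves(compute_age_stage(toy_cohort))
        r = solve_r(curves)
        p = finalize_parameters(curves, r)
        assert p.lam == math.exp(p.r)
        assert p.T * p.r == pytest.approx(math.log(p.R0), abs=1e-12)

    def test_published_wt_lambda_consistency(self):
        # r = 0.29 implies lambda = 1.34 at two decimals
        assert round(lambda_from_r(0.29), 2) == 1.34
        # and ln(54.43)/13.68 rounds back to 0.29
        assert round(r_from_R0_T(54.43, 13.68), 2) == 0.29

    def test_T_continuity_at_r_zero(self):
        curves = _curves_from_schedule({9: 1.0})
        r = solve_r(curves)
        p = finalize_parameters(curves, r)
        assert p.r == pytest.approx(0.0, abs=1e-10)
        assert p.T == pytest.approx(10.0, abs=1e-6)


class TestSummaries:
    def test_toy_summaries_match_hand_arithmetic(self, toy_cohort):
        stats = summarize_cohort(toy_cohort).as_dict()
        for name, (mean, n) in TOY_EXPECTED["summaries"].items():
            assert stats[name].mean == pytest.approx(mean), name
            assert stats[name].n == n, name

    def test_apop_zero_when_every_female_lays_at_emergence(self):
        cohort = simulate_cohort(preset_from_table("WT"), SimulationConfig(n0=200, seed=3))
        stats = summarize_cohort(cohort)
        assert stats.apop.mean == 0.0

    def test_single_record_preadult(self):
        rec = IndividualRecord(
            id="x",
            stage_durations={"egg": 3, "larva": 5, "pupa": 4},
            sex="male",
            fate="died_adult",
            death_stage="male",
            death_day=20,
            emergence_day=12,
        )
        stats = summarize_cohort(CohortTable("t", 1, [rec]))
        assert stats.preadult_all.mean == 12.0

    def test_no_females_marks_reproduction_undefined(self):
        rec = IndividualRecord(
            id="m",
            stage_durations={"egg": 3, "larva": 5, "pupa": 4},
            sex="male",
            fate="died_adult",
            death_stage="male",
            death_day=14,
            emergence_day=12,
        )
        stats = summarize_cohort(CohortTable("t", 1, [rec]))
        assert stats.fecundity.n == 0 and math.isnan(stats.fecundity.mean)
        assert stats.apop.n == 0


class TestInvariantsAndOracles:
    def test_R0_equals_total_eggs_over_n0(self):
        for seed in range(5):
            cohort = simulate_cohort(
                preset_from_table("WT"), SimulationConfig(n0=80, seed=seed)
            )
            curves = compute_curves(compute_age_stage(cohort))
            total = sum(rec.total_eggs for rec in cohort.records)
            assert compute_R0(curves) == pytest.approx(total / cohort.n0, abs=1e-12)

    def test_leslie_projection_matches_lambda(self):
        hits = 0
        for seed in range(10):
            cohort = simulate_cohort(
                preset_from_table("WT"), SimulationConfig(n0=120, seed=100 + seed)
            )
            curves = compute_curves(compute_age_stage(cohort))
            r = solve_r(curves)
            lam = leslie_growth_factor(curves.lx, curves.mx)
            assert lam == pytest.approx(math.exp(r), abs=1e-4)
            hits += 1
        assert hits == 10

    def test_adding_deaths_never_increases_lx(self, toy_cohort):
        base = compute_curves(compute_age_stage(toy_cohort))
        # kill record A earlier: truncate to a preadult death in the pupa stage
        hurt = toy_cohort
        hurt.records[0] = IndividualRecord(
            id="A",
            stage_durations={"egg": 2, "larva": 3},
            sex="unknown",
            fate="died_preadult",
            death_stage="pupa",
            death_day=6,
        )
        worse = compute_curves(compute_age_stage(hurt))
        n = len(worse.lx)
        assert np.all(worse.lx <= base.lx[:n] + 1e-12)

    def test_removing_eggs_never_increases_R0(self, toy_cohort):
        base_R0 = compute_R0(compute_curves(compute_age_stage(toy_cohort)))
        toy_cohort.records[0].daily_eggs = [(7, 4)]  # drop the day-8 clutch
        assert compute_R0(compute_curves(compute_age_stage(toy_cohort))) < base_R0


class TestExport:
    def test_export_roundtrip_and_monotone(self, toy_cohort, tmp_path):
        asm = compute_age_stage(toy_cohort)
        curves = compute_curves(asm)
        sxj_path = tmp_path / "sxj.csv"
        curves_path = tmp_path / "curves.csv"
        export_curves(asm, curves, sxj_path, curves_path)
        sxj = pd.read_csv(sxj_path)
        assert set(sxj.columns) == {"age", "stage", "Sxj"}
        back = (
            sxj.pivot(index="age", columns="stage", values="Sxj")[list(asm.stages)]
            .to_numpy()
        )
        assert np.allclose(back, asm.S)
        cdf = pd.read_csv(curves_path)
        assert np.all(np.diff(cdf["lx"]) <= 1e-12)
        assert cdf["lx"].tolist() == pytest.approx(TOY_EXPECTED["lx"])
        assert cdf["mx"].sum() == pytest.approx(4.0 / 3.0 + 2.0)
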