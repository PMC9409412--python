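"""Shared fixtures.

``toy_cohort`` is a 4-individual cohort whose census, curves and
summaries were enumerated by hand and frozen in ``TOY_EXPECTED``; it
serves as an exact oracle for the life-table engine.
"""

from __future__ import annotations

import pytest

from agestage.cohort import CohortTable, IndividualRecord

# Hand tabulation of the toy cohort below (age -> {stage: count}/4):
#   A (F): egg 0-1, larva 2-4, pupa 5-6, female 7-9; eggs 4 on day 7, 6 on day 8
#   B (M): egg 0-1, larva 2-4, pupa 5-7, male 8-9
#   C (F): egg 0-1, larva 2-5, pupa 6-7, female 8; no eggs
#   D    : egg 0-1, larva 2 (died after 1 day in larva)
TOY_EXPECTED = {
    "S_nonzero": {
        (0, "egg"): 1.0,
        (1, "egg"): 1.0,
        (2, "larva"): 1.0,
        (3, "larva"): 0.75,
        (4, "larva"): 0.75,
        (5, "larva"): 0.25,
        (5, "pupa"): 0.5,
        (6, "pupa"): 0.75,
        (7, "pupa"): 0.5,
        (7, "female"): 0.25,
        (8, "female"): 0.5,
        (8, "male"): 0.25,
        (9, "female"): 0.25,
        (9, "male"): 0.25,
    },
    "lx": [1.0, 1.0, 1.0, 0.75, 0.75, 0.75, 0.75, 0.75, 0.75, 0.5],
    "fx_female": {7: 4.0, 8: 3.0},
    "mx": {7: 4.0 / 3.0, 8: 2.0},
    "R0": 2.5,
    "summaries": {
        "dur_egg": (2.0, 4),
        "dur_larva": (10.0 / 3.0, 3),
        "dur_pupa": (7.0 / 3.0, 3),
        "preadult_all": (23.0 / 3.0, 3),
        "adult_female": (2.0, 2),
        "adult_male": (2.0, 1),
        "adult_all": (2.0, 3),
        "longevity_all": (8.0, 4),
        "APOP": (0.0, 1),
        "TPOP": (7.0, 1),
        "oviposition_days": (2.0, 1),
        "fecundity": (5.0, 2),
    },
}


def make_toy_cohort() -> CohortTable:
    records = [
        IndividualRecord(
            id="A",
            stage_durations={"egg": 2, "larva": 3, "pupa": 2},
            sex="female",
            fate="died_adult",
            death_stage="female",
            death_day=10,
            emergence_day=7,
            daily_eggs=[(7, 4), (8, 6)],
        ),
        IndividualRecord(
            id="B",
            stage_durations={"egg": 2, "larva": 3, "pupa": 3},
            sex="male",
            fate="died_adult",
            death_stage="male",
            death_day=10,
            emergence_day=8,
        ),
        IndividualRecord(
            id="C",
            stage_durations={"egg": 2, "larva": 4, "pupa": 2},
            sex="female",
            fate="died_adult",
            death_stage="female",
            death_day=9,
            emergence_day=8,
        ),
        IndividualRecord(
            id="D",
            stage_durations={"egg": 2},
            sex="unknown",
            fate="died_preadult",
            death_stage="larva",
            death_day=3,
        ),
    ]
    cohort = CohortTable(strain_label="toy", n0=4, records=records)
    cohort.validate()
    return cohort


@pytest.fixture
def toy_cohort() -> CohortTable:
    return make_toy_cohort()
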