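"""Individual-level life-history records and cohort containers.

A cohort is a set of individuals followed daily from oviposition (day 0)
until death.  Each individual carries the number of whole days spent in
every developmental stage it completed, the stage it died in, and — for
adult females — a daily egg-laying record.  Age is discrete in whole
days; the stage attributed to an individual at age ``x`` is the stage it
occupied at the end-of-day census, so an individual entering a stage is
counted in that stage on the stage's first day.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

#: Default stage ordering: pooled larval stage, adults (by sex) last.
DEFAULT_STAGE_ORDER: tuple[str, ...] = ("egg", "larva", "pupa", "female", "male")

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"
SEXES = (FEMALE, MALE, UNKNOWN)

DIED_PREADULT = "died_preadult"
DIED_ADULT = "died_adult"
FATES = (DIED_PREADULT, DIED_ADULT)

_MAIN_COLUMNS = ("id", "sex", "fate", "death_stage", "emergence_day", "death_day")
_EGG_COLUMNS = ("id", "age_day", "eggs")
_WIDE_EGG_RE = re.compile(r"^eggs_(\d+)$")


class CohortSchemaError(ValueError):
    """A cohort file is missing required columns or metadata."""


class CohortValidationError(ValueError):
    """A record or cohort violates a structural invariant."""


@dataclass
class IndividualRecord:
    """One insect's full life history.

    Parameters
    ----------
    id :
        Unique identifier within the cohort.
    stage_durations :
        Ordered mapping of stage name to whole days spent in each stage the
        individual *completed* (the death stage is excluded; its partial
        duration is implied by ``death_day``).
    sex :
        ``"female"``, ``"male"`` or ``"unknown"`` (individuals are sexed at
        pupation; earlier deaths stay unsexed).
    fate :
        ``"died_preadult"`` or ``"died_adult"``.
    death_stage :
        Stage occupied at death.
    death_day :
        Whole days survived since oviposition; the individual is counted
        alive at ages ``0 .. death_day - 1``.
    emergence_day :
        Day of adult emergence (``None`` for preadult deaths).
    daily_eggs :
        ``(age_day, egg_count)`` pairs for adult females, in increasing age.
    """

    id: str
    stage_durations: dict[str, int]
    sex: str
    fate: str
    death_stage: str
    death_day: int
    emergence_day: int | None = None
    daily_eggs: list[tuple[int, int]] = field(default_factory=list)

    def stage_intervals(self) -> list[tuple[str, int, int]]:
        """Half-open ``(stage, first_age, stop_age)`` occupancy intervals."""
        out: list[tuple[str, int, int]] = []
        day = 0
        for stage, dur in self.stage_durations.items():
            out.append((stage, day, day + dur))
            day += dur
        if self.death_day > day:
            out.append((self.death_stage, day, self.death_day))
        return out

    @property
    def total_eggs(self) -> int:
        return sum(n for _, n in self.daily_eggs)

    @property
    def first_egg_day(self) -> int | None:
        for day, n in self.daily_eggs:
            if n > 0:
                return day
        return None


def validate_record(rec: IndividualRecord, stage_order: Sequence[str]) -> None:
    """Raise :class:`CohortValidationError` if ``rec`` breaks an invariant."""
    err = lambda msg: CohortValidationError(f"record {rec.id!r}: {msg}")  # noqa: E731
    preadult = tuple(stage_order[:-2])
    female_stage, male_stage = stage_order[-2], stage_order[-1]

    if rec.sex not in SEXES:
        raise err(f"unknown sex {rec.sex!r}")
    if rec.fate not in FATES:
        raise err(f"unknown fate {rec.fate!r}")
    if rec.death_stage not in stage_order:
        raise err(f"death stage {rec.death_stage!r} not in stage order")

    for stage, dur in rec.stage_durations.items():
        if stage not in stage_order:
            raise err(f"stage {stage!r} not in stage order")
        if not float(dur).is_integer() or dur < 1:
            raise err(f"duration of completed stage {stage!r} must be a whole day >= 1")

    completed = tuple(rec.stage_durations)
    total_completed = sum(rec.stage_durations.values())
    if rec.death_day < 1:
        raise err("death_day must be >= 1 (alive at the day-0 census)")
    if rec.death_day < total_completed:
        raise err(
            f"death_day {rec.death_day} < {total_completed} days of completed stages"
        )

    if rec.fate == DIED_PREADULT:
        if completed != preadult[: len(completed)]:
            raise err("completed stages must be an in-order prefix of the preadult stages")
        if rec.death_stage not in preadult:
            raise err("preadult death must occur in a preadult stage")
        if rec.death_stage != preadult[len(completed)]:
            raise err("death stage must follow the last completed stage")
        if rec.emergence_day is not None:
            raise err("preadult death cannot have an emergence day")
        if rec.daily_eggs:
            raise err("preadult death cannot have an egg record")
    else:  # died_adult
        if rec.sex == UNKNOWN:
            raise err("adults must be sexed")
        if completed != preadult:
            raise err("adults must have completed every preadult stage")
        expect_stage = female_stage if rec.sex == FEMALE else male_stage
        if rec.death_stage != expect_stage:
            raise err(f"adult death stage must be {expect_stage!r}")
        if rec.emergence_day != total_completed:
            raise err(
                f"emergence_day {rec.emergence_day} != preadult duration {total_completed}"
            )

    if rec.daily_eggs:
        if rec.sex != FEMALE:
            raise err("only females carry an egg record")
        prev = -1
        for day, n in rec.daily_eggs:
            if n < 0:
                raise err(f"negative egg count on day {day}")
            if day <= prev:
                raise err("egg-record days must be strictly increasing")
            if day < rec.emergence_day:  # type: ignore[operator]
                raise err(f"eggs on day {day} before emergence day {rec.emergence_day}")
            if day >= rec.death_day:
                raise err(f"eggs on day {day} not before death day {rec.death_day}")
            prev = day


@dataclass
class CohortTable:
    """A fully observed cohort of ``n0`` individuals started as eggs."""

    strain_label: str
    n0: int
    records: list[IndividualRecord]
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def validate(self) -> None:
        if len(self.stage_order) < 3:
            raise CohortValidationError(
                "stage_order needs at least one preadult stage plus two adult stages"
            )
        if len(self.records) != self.n0:
            raise CohortValidationError(
                f"cohort has {len(self.records)} records but n0={self.n0}"
            )
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise CohortValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            validate_record(rec, self.stage_order)

    @property
    def preadult_stages(self) -> tuple[str, ...]:
        return tuple(self.stage_order[:-2])

    @property
    def female_stage(self) -> str:
        return self.stage_order[-2]

    @property
    def male_stage(self) -> str:
        return self.stage_order[-1]


# ---------------------------------------------------------------------------
# CSV I/O
#
# Main file: one row per individual with a ``dur_<stage>`` column per
# preadult stage; leading ``# key=value`` lines carry cohort metadata.
# Daily fecundity goes in a long companion file (id, age_day, eggs); wide
# ``eggs_<day>`` columns in the main file are accepted on read.
# ---------------------------------------------------------------------------

def default_eggs_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".eggs" + (path.suffix or ".csv"))


def write_cohort(
    cohort: CohortTable, path: str | Path, eggs_path: str | Path | None = None
) -> None:
    """Serialize ``cohort`` to ``path`` plus a long-format egg companion file.

    The pair of files round-trips losslessly through :func:`read_cohort`.
    """
    cohort.validate()
    path = Path(path)
    eggs_path = default_eggs_path(path) if eggs_path is None else Path(eggs_path)

    dur_cols = [f"dur_{s}" for s in cohort.preadult_stages]
    rows = []
    for rec in cohort.records:
        row: dict[str, object] = {
            "id": rec.id,
            "sex": rec.sex,
            "fate": rec.fate,
            "death_stage": rec.death_stage,
            "emergence_day": rec.emergence_day,
            "death_day": rec.death_day,
        }
        for stage in cohort.preadult_stages:
            row[f"dur_{stage}"] = rec.stage_durations.get(stage)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_MAIN_COLUMNS) + dur_cols)
    for col in ["emergence_day", "death_day", *dur_cols]:
        df[col] = df[col].astype("Int64")

    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# strain_label={cohort.strain_label}\n")
        fh.write(f"# n0={cohort.n0}\n")
        fh.write(f"# stage_order={','.join(cohort.stage_order)}\n")
        df.to_csv(fh, index=False, lineterminator="\n")

    egg_rows = [
        {"id": rec.id, "age_day": day, "eggs": n}
        for rec in cohort.records
        for day, n in rec.daily_eggs
    ]
    eggs = pd.DataFrame(egg_rows, columns=list(_EGG_COLUMNS))
    with open(eggs_path, "w", encoding="utf-8", newline="") as fh:
        eggs.to_csv(fh, index=False, lineterminator="\n")


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_cohort(
    path: str | Path,
    eggs_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
    stage_order: Sequence[str] | None = None,
    strain_label: str | None = None,
) -> CohortTable:
    """Read and validate a cohort written by :func:`write_cohort`.

    Parameters
    ----------
    path :
        Main per-individual CSV.
    eggs_path :
        Long-format daily-egg file; defaults to ``<stem>.eggs<suffix>`` and
        is optional when the main file carries wide ``eggs_<day>`` columns.
    schema :
        Optional mapping from the canonical column names to the names used
        in the file.
    stage_order, strain_label :
        Overrides for the file-header metadata.
    """
    path = Path(path)
    meta = _read_metadata(path)
    if stage_order is None:
        if "stage_order" not in meta:
            raise CohortSchemaError(
                f"{path}: no stage_order metadata and none supplied"
            )
        stage_order = tuple(meta["stage_order"].split(","))
    stage_order = tuple(stage_order)
    if strain_label is None:
        strain_label = meta.get("strain_label", path.stem)

    df = pd.read_csv(path, comment="#", dtype={"id": str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})

    dur_cols = {f"dur_{s}": s for s in stage_order[:-2]}
    missing = [c for c in (*_MAIN_COLUMNS, *dur_cols) if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing columns {missing}")

    wide_cols = {
        int(m.group(1)): c
        for c in df.columns
        if (m := _WIDE_EGG_RE.match(str(c)))
    }

    eggs_by_id: dict[str, list[tuple[int, int]]] = {}
    if eggs_path is None:
        candidate = default_eggs_path(path)
        eggs_path = candidate if candidate.exists() else None
    if eggs_path is not None:
        eggs = pd.read_csv(eggs_path, comment="#", dtype={"id": str})
        missing = [c for c in _EGG_COLUMNS if c not in eggs.columns]
        if missing:
            raise CohortSchemaError(f"{eggs_path}: missing columns {missing}")
        for rid, sub in eggs.groupby("id", sort=False):
            eggs_by_id[str(rid)] = [
                (int(d), int(n)) for d, n in zip(sub["age_day"], sub["eggs"])
            ]

    records: list[IndividualRecord] = []
    for _, row in df.iterrows():
        rid = str(row["id"])
        durations = {
            stage: int(row[col])
            for col, stage in dur_cols.items()
            if pd.notna(row[col])
        }
        daily_eggs = eggs_by_id.get(rid, [])
        if not daily_eggs and wide_cols:
            daily_eggs = [
                (day, int(row[col]))
                for day, col in sorted(wide_cols.items())
                if pd.notna(row[col])
            ]
        emergence = row["emergence_day"]
        records.append(
            IndividualRecord(
                id=rid,
                stage_durations=durations,
                sex=str(row["sex"]),
                fate=str(row["fate"]),
                death_stage=str(row["death_stage"]),
                death_day=int(row["death_day"]),
                emergence_day=None if pd.isna(emergence) else int(emergence),
                daily_eggs=daily_eggs,
            )
        )

    cohort = CohortTable(
        strain_label=strain_label,
        n0=int(meta.get("n0", len(records))),
        records=records,
        stage_order=stage_order,
    )
    cohort.validate()
    return cohort
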