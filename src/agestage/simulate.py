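"""Individual-based cohort simulator.

Generates cohorts with the statistical structure the life-table analysis
assumes: integer stage durations (>= 1 day), per-stage Bernoulli survival,
sexing at adult emergence, and a daily egg-laying schedule for females.
Packaged presets reproduce the published strain means; per-stage survival
is calibrated so the expected net reproductive rate (total eggs / n0)
matches each strain's published R0.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .cohort import (
    DIED_ADULT,
    DIED_PREADULT,
    FEMALE,
    MALE,
    UNKNOWN,
    CohortTable,
    IndividualRecord,
)

__all__ = [
    "StrainPreset",
    "SimulationConfig",
    "SimulationConfigError",
    "UnknownStrainError",
    "simulate_cohort",
    "preset_from_table",
    "available_strains",
]

DURATION_FAMILIES = ("shifted_poisson", "discretized_gamma", "deterministic")
ALLOCATION_RULES = ("geometric", "uniform")


class SimulationConfigError(ValueError):
    pass


class UnknownStrainError(KeyError):
    pass


@dataclass
class StrainPreset:
    """Vital-rate parameters for one strain.

    ``stage_duration_means`` covers the preadult stages in rearing order;
    survival probabilities are per stage; fecundity is total eggs per
    female with a negative-binomial dispersion parameter (larger = closer
    to Poisson).
    """

    name: str
    stage_duration_means: dict[str, float]
    stage_survival: dict[str, float]
    adult_longevity_means: dict[str, float]
    apop_mean: float = 0.0
    oviposition_days_mean: float = 1.0
    total_fecundity_mean: float = 0.0
    fecundity_dispersion: float = 10.0
    sex_ratio: float = 0.5

    def validate(self) -> None:
        if not self.stage_duration_means:
            raise SimulationConfigError("preset needs at least one preadult stage")
        for stage, mu in self.stage_duration_means.items():
            if mu <= 0:
                raise SimulationConfigError(f"duration mean for {stage!r} must be > 0")
        for stage, p in self.stage_survival.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError(f"survival for {stage!r} outside [0, 1]")
        if set(self.stage_survival) != set(self.stage_duration_means):
            raise SimulationConfigError("survival and duration stages must match")
        for sex in (FEMALE, MALE):
            if self.adult_longevity_means.get(sex, 0) <= 0:
                raise SimulationConfigError(f"adult longevity mean for {sex} must be > 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise SimulationConfigError("sex_ratio outside [0, 1]")
        if self.apop_mean < 0:
            raise SimulationConfigError("apop_mean must be >= 0")
        if self.total_fecundity_mean < 0:
            raise SimulationConfigError("total_fecundity_mean must be >= 0")
        if self.fecundity_dispersion <= 0:
            raise SimulationConfigError("fecundity_dispersion must be > 0")

    @property
    def stage_order(self) -> tuple[str, ...]:
        return (*self.stage_duration_means, FEMALE, MALE)


@dataclass
class SimulationConfig:
    n0: int = 120
    seed: int | None = None
    duration_distribution: str = "shifted_poisson"
    fecundity_allocation: str = "geometric"
    geometric_q: float = 0.7          # day-to-day decay of the laying schedule
    duration_cv: float = 0.3          # only used by the discretized-gamma family

    def validate(self) -> None:
        if self.n0 < 1:
            raise SimulationConfigError("n0 must be >= 1")
        if self.duration_distribution not in DURATION_FAMILIES:
            raise SimulationConfigError(
                f"unknown duration family {self.duration_distribution!r}; "
                f"choose from {DURATION_FAMILIES}"
            )
        if self.fecundity_allocation not in ALLOCATION_RULES:
            raise SimulationConfigError(
                f"unknown allocation rule {self.fecundity_allocation!r}"
            )
        if not 0.0 < self.geometric_q <= 1.0:
            raise SimulationConfigError("geometric_q must be in (0, 1]")
        if self.duration_cv <= 0:
            raise SimulationConfigError("duration_cv must be > 0")


def _draw_duration(rng: np.random.Generator, mean: float, config: SimulationConfig) -> int:
    family = config.duration_distribution
    if family == "deterministic":
        return max(1, round(mean))
    if family == "shifted_poisson":
        return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
    # discretized gamma with coefficient of variation config.duration_cv
    shape = 1.0 / config.duration_cv**2
    scale = mean / shape
    return max(1, int(np.rint(rng.gamma(shape, scale))))


def _draw_fecundity(rng: np.random.Generator, preset: StrainPreset) -> int:
    mu = preset.total_fecundity_mean
    if mu <= 0:
        return 0
    k = preset.fecundity_dispersion
    return int(rng.negative_binomial(k, k / (k + mu)))


def _allocate_eggs(
    rng: np.random.Generator, total: int, n_days: int, config: SimulationConfig
) -> np.ndarray:
    if config.fecundity_allocation == "uniform":
        weights = np.full(n_days, 1.0 / n_days)
    else:
        weights = config.geometric_q ** np.arange(n_days)
        weights /= weights.sum()
    return rng.multinomial(total, weights)


def simulate_cohort(preset: StrainPreset, config: SimulationConfig) -> CohortTable:
    """Simulate one cohort of ``config.n0`` eggs followed until death.

    The same seed yields an identical cohort; as ``n0`` grows, realized
    per-stage survival, duration means and mean fecundity converge to the
    preset values.
    """
    preset.validate()
    config.validate()
    rng = np.random.default_rng(config.seed)
    preadult = tuple(preset.stage_duration_means)
    records: list[IndividualRecord] = []
    width = len(str(config.n0))

    for i in range(config.n0):
        rid = f"{preset.name}-{i + 1:0{width}d}"
        durations: dict[str, int] = {}
        day = 0
        dead_stage: str | None = None
        death_day = 0
        for stage in preadult:
            dur = _draw_duration(rng, preset.stage_duration_means[stage], config)
            if rng.random() < preset.stage_survival[stage]:
                durations[stage] = dur
                day += dur
            else:
                # died during this stage after 1..dur days in it
                death_day = day + int(rng.integers(1, dur + 1))
                dead_stage = stage
                break
        if dead_stage is not None:
            records.append(
                IndividualRecord(
                    id=rid,
                    stage_durations=durations,
                    sex=UNKNOWN,
                    fate=DIED_PREADULT,
                    death_stage=dead_stage,
                    death_day=death_day,
                )
            )
            continue

        sex = FEMALE if rng.random() < preset.sex_ratio else MALE
        longevity = _draw_duration(rng, preset.adult_longevity_means[sex], config)
        emergence = day
        death_day = emergence + longevity
        daily_eggs: list[tuple[int, int]] = []
        if sex == FEMALE and preset.total_fecundity_mean > 0:
            total = _draw_fecundity(rng, preset)
            apop = int(rng.poisson(preset.apop_mean))
            window = longevity - apop
            if total > 0 and window > 0:
                target = 1 + int(rng.poisson(max(preset.oviposition_days_mean - 1, 0)))
                n_days = min(window, target)
                counts = _allocate_eggs(rng, total, n_days, config)
                daily_eggs = [
                    (emergence + apop + j, int(c))
                    for j, c in enumerate(counts)
                    if c > 0
                ]
        records.append(
            IndividualRecord(
                id=rid,
                stage_durations=durations,
                sex=sex,
                fate=DIED_ADULT,
                death_stage=sex,
                death_day=death_day,
                emergence_day=emergence,
                daily_eggs=daily_eggs,
            )
        )

    cohort = CohortTable(
        strain_label=preset.name,
        n0=config.n0,
        records=records,
        stage_order=preset.stage_order,
    )
    cohort.validate()
    return cohort


def _load_preset_file() -> dict:
    text = resources.files("agestage").joinpath("data/strain_presets.yaml").read_text()
    return yaml.safe_load(text)


def available_strains() -> tuple[str, ...]:
    return tuple(_load_preset_file())


def preset_from_table(strain_name: str) -> StrainPreset:
    """Packaged preset for one of the published strains.

    Per-stage survival is derived from the published net reproductive rate:
    R0 / fecundity gives the probability a newborn becomes an adult female,
    so preadult survival = (R0 / fecundity) / sex_ratio, split evenly
    across the preadult stages.
    """
    table = _load_preset_file()
    if strain_name not in table:
        raise UnknownStrainError(
            f"unknown strain {strain_name!r}; available: {sorted(table)}"
        )
    raw = dict(table[strain_name])
    r0 = float(raw.pop("net_reproductive_rate"))
    fec = float(raw["total_fecundity_mean"])
    sex_ratio = float(raw.get("sex_ratio", 0.5))
    p_female_adult = r0 / fec
    survive_preadult = p_female_adult / sex_ratio
    if not 0.0 < survive_preadult <= 1.0:
        raise SimulationConfigError(
            f"{strain_name}: implied preadult survival {survive_preadult:.3f} "
            "outside (0, 1]"
        )
    stages = tuple(raw["stage_duration_means"])
    per_stage = survive_preadult ** (1.0 / len(stages))
    preset = StrainPreset(
        name=strain_name,
        stage_survival={s: per_stage for s in stages},
        **raw,
    )
    preset.validate()
    return preset
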