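"""Age-stage two-sex life table computation.

Builds the age-stage survival matrix ``S[x, j]`` (fraction of the ``n0``
newborns alive and in stage ``j`` at age ``x``) and the per-female daily
fecundity matrix ``F[x, j]`` from a daily census of individual records,
derives the age-specific curves

    l_x = sum_j S_xj
    m_x = sum_j S_xj f_xj / sum_j S_xj

and the population parameters

    R0     = sum_x l_x m_x
    r      : sum_x exp(-r (x+1)) l_x m_x = 1
    lambda = exp(r)
    T      = ln(R0) / r

The growth-rate equation uses the ``(x+1)`` exponent of the age-from-zero
convention; ``T`` at ``r = 0`` is defined by continuity as the mean age of
the reproductive schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import FEMALE, CohortTable

__all__ = [
    "AgeStageMatrix",
    "LifeTableCurves",
    "PopulationParameters",
    "CohortSummaries",
    "SummaryStat",
    "UndefinedParameterError",
    "SolverError",
    "compute_age_stage",
    "compute_curves",
    "compute_R0",
    "solve_r",
    "finalize_parameters",
    "compute_population_parameters",
    "summarize_cohort",
    "export_curves",
    "r_from_R0_T",
    "lambda_from_r",
]


class UndefinedParameterError(ValueError):
    """A population parameter is undefined (e.g. r with zero reproduction)."""


class SolverError(RuntimeError):
    """The growth-rate solver failed to bracket or converge."""


@dataclass
class AgeStageMatrix:
    ages: np.ndarray            # 0 .. x_max
    stages: tuple[str, ...]
    S: np.ndarray               # (n_ages, n_stages) survival fractions
    F: np.ndarray               # (n_ages, n_stages) eggs per living female

    @property
    def female_column(self) -> int:
        return len(self.stages) - 2


@dataclass
class LifeTableCurves:
    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    product: np.ndarray         # l_x * m_x


@dataclass
class PopulationParameters:
    R0: float
    r: float
    lam: float
    T: float
    euler_residual: float


class SummaryStat(NamedTuple):
    """Mean, sample SD (ddof=1; NaN when n < 2) and count of a cohort trait."""

    mean: float
    sd: float
    n: int


@dataclass
class CohortSummaries:
    stage_durations: dict[str, SummaryStat]
    preadult_all: SummaryStat
    adult_female: SummaryStat
    adult_male: SummaryStat
    adult_all: SummaryStat
    longevity_all: SummaryStat
    apop: SummaryStat
    tpop: SummaryStat
    oviposition_days: SummaryStat
    fecundity: SummaryStat

    def as_dict(self) -> dict[str, SummaryStat]:
        out = {f"dur_{s}": v for s, v in self.stage_durations.items()}
        out.update(
            preadult_all=self.preadult_all,
            adult_female=self.adult_female,
            adult_male=self.adult_male,
            adult_all=self.adult_all,
            longevity_all=self.longevity_all,
            APOP=self.apop,
            TPOP=self.tpop,
            oviposition_days=self.oviposition_days,
            fecundity=self.fecundity,
        )
        return out


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def compute_age_stage(cohort: CohortTable) -> AgeStageMatrix:
    """Daily census of stage occupancy and per-female fecundity."""
    cohort.validate()
    stages = cohort.stage_order
    col = {s: j for j, s in enumerate(stages)}
    n_ages = max(rec.death_day for rec in cohort.records)
    S = np.zeros((n_ages, len(stages)))
    eggs = np.zeros(n_ages)
    for rec in cohort.records:
        for stage, start, stop in rec.stage_intervals():
            S[start:stop, col[stage]] += 1.0
        for day, n in rec.daily_eggs:
            eggs[day] += n
    S /= cohort.n0
    F = np.zeros_like(S)
    fem = col[cohort.female_stage]
    females_alive = S[:, fem] * cohort.n0
    np.divide(eggs, females_alive, out=F[:, fem], where=females_alive > 0)
    return AgeStageMatrix(ages=np.arange(n_ages), stages=stages, S=S, F=F)


def compute_curves(asm: AgeStageMatrix) -> LifeTableCurves:
    lx = asm.S.sum(axis=1)
    weighted = (asm.S * asm.F).sum(axis=1)
    mx = np.divide(weighted, lx, out=np.zeros_like(lx), where=lx > 0)
    return LifeTableCurves(ages=asm.ages.copy(), lx=lx, mx=mx, product=lx * mx)


def compute_R0(curves: LifeTableCurves) -> float:
    return float(curves.product.sum())


# ---------------------------------------------------------------------------
# growth rate
# ---------------------------------------------------------------------------

def _solve_r_from_schedule(
    ages: np.ndarray,
    phi: np.ndarray,
    tol: float = 1e-10,
    bracket: tuple[float, float] = (-1.0, 2.0),
) -> float:
    """Solve sum(exp(-r (x+1)) phi_x) = 1 by bisection plus Newton polish."""
    mask = phi > 0
    if not mask.any():
        raise UndefinedParameterError("r is undefined: no reproduction (R0 = 0)")
    w = ages[mask] + 1.0
    p = phi[mask]

    def f(r: float) -> float:
        return float(np.exp(-r * w) @ p) - 1.0

    lo, hi = bracket
    for _ in range(64):               # expand until the root is bracketed
        if f(lo) > 0:
            break
        lo -= 1.0
    for _ in range(64):
        if f(hi) < 0:
            break
        hi += 1.0
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if not (flo > 0 > fhi):
        raise SolverError(f"failed to bracket r in [{lo}, {hi}]: f={flo:.3g},{fhi:.3g}")
    r = float(brentq(f, lo, hi, xtol=1e-12))
    for _ in range(50):               # Newton steps; f is monotone decreasing
        val = f(r)
        if abs(val) < tol:
            return r
        grad = -float((w * np.exp(-r * w)) @ p)
        r -= val / grad
    raise SolverError(f"Newton polish did not reach |residual| < {tol}")


def solve_r(
    curves: LifeTableCurves,
    tol: float = 1e-10,
    bracket: tuple[float, float] = (-1.0, 2.0),
) -> float:
    """Intrinsic rate of increase from the reproductive schedule l_x m_x."""
    return _solve_r_from_schedule(curves.ages, curves.product, tol=tol, bracket=bracket)


def finalize_parameters(
    curves: LifeTableCurves, r: float, tol: float = 1e-10
) -> PopulationParameters:
    R0 = compute_R0(curves)
    if R0 <= 0:
        raise UndefinedParameterError("population parameters undefined with R0 = 0")
    lam = math.exp(r)
    phi = curves.product
    w = curves.ages + 1.0
    residual = abs(float(np.exp(-r * w) @ phi) - 1.0)
    if abs(r) < 1e-12:
        # ln(R0)/r is 0/0 at r = 0; continuity limit = mean age of reproduction
        T = float((w @ phi) / phi.sum())
    else:
        T = math.log(R0) / r
    return PopulationParameters(R0=R0, r=r, lam=lam, T=T, euler_residual=residual)


def compute_population_parameters(
    cohort: CohortTable, tol: float = 1e-10
) -> PopulationParameters:
    """Convenience one-shot: census -> curves -> r -> parameters."""
    curves = compute_curves(compute_age_stage(cohort))
    r = solve_r(curves, tol=tol)
    return finalize_parameters(curves, r, tol=tol)


def r_from_R0_T(R0: float, T: float) -> float:
    """Invert T = ln(R0)/r for r given a (R0, T) pair."""
    if R0 <= 0 or T <= 0:
        raise UndefinedParameterError("need R0 > 0 and T > 0")
    return math.log(R0) / T


def lambda_from_r(r: float) -> float:
    """Finite (daily) rate of increase, lambda = exp(r)."""
    return math.exp(r)


# ---------------------------------------------------------------------------
# cohort trait summaries
# ---------------------------------------------------------------------------

def _stat(values: list[float]) -> SummaryStat:
    n = len(values)
    if n == 0:
        return SummaryStat(math.nan, math.nan, 0)
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if n > 1 else math.nan
    return SummaryStat(float(arr.mean()), sd, n)


def summarize_cohort(cohort: CohortTable) -> CohortSummaries:
    """Trait means over the subsets the life-table convention prescribes.

    Stage durations average over individuals that completed the stage;
    longevity averages the death day over all ``n0`` individuals including
    preadult deaths; fecundity is per adult female (zero layers included);
    APOP/TPOP/oviposition days cover females that laid at least one egg.
    """
    cohort.validate()
    durations: dict[str, list[float]] = {s: [] for s in cohort.preadult_stages}
    preadult: list[float] = []
    adult_f: list[float] = []
    adult_m: list[float] = []
    longevity: list[float] = []
    apop: list[float] = []
    tpop: list[float] = []
    ovi_days: list[float] = []
    fecundity: list[float] = []

    for rec in cohort.records:
        longevity.append(rec.death_day)
        for stage, dur in rec.stage_durations.items():
            durations[stage].append(dur)
        if rec.emergence_day is None:
            continue
        preadult.append(rec.emergence_day)
        adult_span = rec.death_day - rec.emergence_day
        (adult_f if rec.sex == FEMALE else adult_m).append(adult_span)
        if rec.sex == FEMALE:
            fecundity.append(rec.total_eggs)
            first = rec.first_egg_day
            if first is not None:
                apop.append(first - rec.emergence_day)
                tpop.append(first)
                ovi_days.append(sum(1 for _, n in rec.daily_eggs if n > 0))

    return CohortSummaries(
        stage_durations={s: _stat(v) for s, v in durations.items()},
        preadult_all=_stat(preadult),
        adult_female=_stat(adult_f),
        adult_male=_stat(adult_m),
        adult_all=_stat(adult_f + adult_m),
        longevity_all=_stat(longevity),
        apop=_stat(apop),
        tpop=_stat(tpop),
        oviposition_days=_stat(ovi_days),
        fecundity=_stat(fecundity),
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_curves(
    asm: AgeStageMatrix,
    curves: LifeTableCurves,
    sxj_path: str | Path,
    curves_path: str | Path,
    plot_path: str | Path | None = None,
) -> None:
    """Write tidy long-format CSVs (and optionally a four-panel figure)."""
    sxj = pd.DataFrame(
        {
            "age": np.repeat(asm.ages, len(asm.stages)),
            "stage": list(asm.stages) * len(asm.ages),
            "Sxj": asm.S.ravel(),
        }
    )
    sxj.to_csv(sxj_path, index=False, lineterminator="\n")
    fx_female = asm.F[:, asm.female_column]
    out = pd.DataFrame(
        {"age": curves.ages, "lx": curves.lx, "fx_female": fx_female, "mx": curves.mx}
    )
    out.to_csv(curves_path, index=False, lineterminator="\n")
    if plot_path is not None:
        _plot_curves(asm, curves, plot_path)


def _plot_curves(asm: AgeStageMatrix, curves: LifeTableCurves, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    for j, stage in enumerate(asm.stages):
        axes[0, 0].plot(asm.ages, asm.S[:, j], label=stage)
    axes[0, 0].set_ylabel("S_xj")
    axes[0, 0].legend(fontsize=7)
    axes[0, 1].plot(curves.ages, curves.lx)
    axes[0, 1].set_ylabel("l_x")
    axes[1, 0].plot(asm.ages, asm.F[:, asm.female_column])
    axes[1, 0].set_ylabel("f_x (per female)")
    axes[1, 1].plot(curves.ages, curves.mx)
    axes[1, 1].set_ylabel("m_x")
    for ax in axes.flat:
        ax.set_xlabel("age (d)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
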