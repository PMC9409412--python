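"""Bootstrap standard errors and the paired bootstrap strain comparison.

The resampling unit is the individual (a whole life history), which keeps
within-individual correlation between development and fecundity intact.
Each resample recomputes every population parameter and cohort trait on
``n0`` individuals drawn with replacement; the standard error of a
parameter is the standard deviation of its resample estimates.

Two cohorts are compared with a paired bootstrap test: resamples of the
two cohorts are paired by index (both streams use the same seed), and the
two-sided p-value is ``2 * min(#{d <= 0}, #{d >= 0}) / B`` clamped to
``[1/B, 1]`` where ``d`` is the per-pair difference of estimates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import FEMALE, MALE, CohortTable
from .lifetable import _solve_r_from_schedule

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "PairedTestResult",
    "CohortArrays",
    "bootstrap_parameters",
    "paired_bootstrap_test",
    "POPULATION_PARAMS",
]

POPULATION_PARAMS = ("R0", "r", "lambda", "T")
DEGENERATE_POLICIES = ("nan-exclude", "redraw")

_EXHAUSTIVE_LIMIT = 300_000


class BootstrapConfigError(ValueError):
    pass


@dataclass
class BootstrapConfig:
    """``B`` resamples under ``seed``; the published analysis used B=100000,
    the desk default is 2000."""

    B: int = 2000
    seed: int | None = None
    degenerate_policy: str = "nan-exclude"

    def validate(self) -> None:
        if self.B < 1:
            raise BootstrapConfigError("B must be >= 1")
        if self.degenerate_policy not in DEGENERATE_POLICIES:
            raise BootstrapConfigError(
                f"unknown degenerate policy {self.degenerate_policy!r}"
            )


@dataclass
class BootstrapResult:
    point: dict[str, float]
    boot_mean: dict[str, float]
    se: dict[str, float]
    resamples: dict[str, np.ndarray]
    n_degenerate: int
    B: int


@dataclass
class PairedTestResult:
    parameter: str
    mean_difference: float
    p_value: float
    significant: bool
    n_pairs: int


class CohortArrays:
    """Per-individual trait arrays enabling fast vectorized resampling.

    Trait values undefined for an individual (e.g. adult longevity of a
    preadult death) are NaN and excluded via nanmean, mirroring the
    subset rules of :func:`agestage.lifetable.summarize_cohort`.
    """

    def __init__(self, cohort: CohortTable):
        cohort.validate()
        n = cohort.n0
        n_ages = max(rec.death_day for rec in cohort.records)
        self.n = n
        self.ages = np.arange(n_ages, dtype=float)
        self.eggs_by_age = np.zeros((n, n_ages))
        metrics: dict[str, np.ndarray] = {
            f"dur_{s}": np.full(n, np.nan) for s in cohort.preadult_stages
        }
        for name in (
            "preadult_all",
            "adult_female",
            "adult_male",
            "adult_all",
            "longevity_all",
            "APOP",
            "TPOP",
            "oviposition_days",
            "fecundity",
        ):
            metrics[name] = np.full(n, np.nan)
        for i, rec in enumerate(cohort.records):
            metrics["longevity_all"][i] = rec.death_day
            for stage, dur in rec.stage_durations.items():
                metrics[f"dur_{stage}"][i] = dur
            for day, eggs in rec.daily_eggs:
                self.eggs_by_age[i, day] += eggs
            if rec.emergence_day is None:
                continue
            metrics["preadult_all"][i] = rec.emergence_day
            adult_span = rec.death_day - rec.emergence_day
            metrics["adult_all"][i] = adult_span
            if rec.sex == FEMALE:
                metrics["adult_female"][i] = adult_span
                metrics["fecundity"][i] = rec.total_eggs
                first = rec.first_egg_day
                if first is not None:
                    metrics["APOP"][i] = first - rec.emergence_day
                    metrics["TPOP"][i] = first
                    metrics["oviposition_days"][i] = sum(
                        1 for _, c in rec.daily_eggs if c > 0
                    )
            elif rec.sex == MALE:
                metrics["adult_male"][i] = adult_span
        self.metrics = metrics

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return (*POPULATION_PARAMS, *self.metrics)

    def estimate(self, idx: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
        """Parameter estimates for the resample given by index array ``idx``."""
        out: dict[str, float] = {}
        need_pop = any(p in names for p in POPULATION_PARAMS)
        if need_pop:
            phi = self.eggs_by_age[idx].sum(axis=0) / self.n
            R0 = float(phi.sum())
            if "R0" in names:
                out["R0"] = R0
            if any(p in names for p in ("r", "lambda", "T")):
                if R0 > 0:
                    r = _solve_r_from_schedule(self.ages, phi)
                    T = (
                        math.log(R0) / r
                        if abs(r) >= 1e-12
                        else float(((self.ages + 1.0) @ phi) / phi.sum())
                    )
                else:
                    r = T = math.nan
                if "r" in names:
                    out["r"] = r
                if "lambda" in names:
                    out["lambda"] = math.exp(r) if not math.isnan(r) else math.nan
                if "T" in names:
                    out["T"] = T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            for name in names:
                if name in self.metrics:
                    out[name] = float(np.nanmean(self.metrics[name][idx]))
        return out

    def is_degenerate(self, idx: np.ndarray) -> bool:
        return float(self.eggs_by_age[idx].sum()) <= 0.0


def _resample_matrix(
    arrays: CohortArrays, config: BootstrapConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """(B, n) index matrix plus the count of degenerate resamples.

    Under the ``redraw`` policy degenerate rows are replaced with fresh
    draws (counted, then redrawn); under ``nan-exclude`` they are kept and
    yield NaN growth-rate estimates downstream.
    """
    idx = rng.integers(0, arrays.n, size=(config.B, arrays.n))
    degenerate = np.array([arrays.is_degenerate(row) for row in idx])
    n_degenerate = int(degenerate.sum())
    if config.degenerate_policy == "redraw" and n_degenerate:
        for b in np.nonzero(degenerate)[0]:
            for _ in range(1000):
                row = rng.integers(0, arrays.n, size=arrays.n)
                if not arrays.is_degenerate(row):
                    idx[b] = row
                    break
            else:
                raise BootstrapConfigError(
                    "could not redraw a non-degenerate resample in 1000 tries"
                )
    return idx, n_degenerate


def bootstrap_parameters(
    cohort: CohortTable,
    config: BootstrapConfig,
    parameters: tuple[str, ...] | None = None,
    exhaustive: bool = False,
) -> BootstrapResult:
    """Bootstrap SEs of population parameters and cohort trait means.

    ``exhaustive=True`` enumerates all ``n^n`` ordered with-replacement
    resamples (tiny cohorts only) and reports the exact SD (ddof=0) of the
    estimate over that population; otherwise ``config.B`` Monte-Carlo
    resamples are drawn and the SE is the sample SD (ddof=1).
    """
    config.validate()
    arrays = CohortArrays(cohort)
    names = arrays.parameter_names if parameters is None else tuple(parameters)
    unknown = [p for p in names if p not in arrays.parameter_names]
    if unknown:
        raise BootstrapConfigError(f"unknown parameters {unknown}")
    point = arrays.estimate(np.arange(arrays.n), names)

    if exhaustive:
        if arrays.n**arrays.n > _EXHAUSTIVE_LIMIT:
            raise BootstrapConfigError(
                f"exhaustive enumeration infeasible for n={arrays.n}"
            )
        rows = []
        n_degenerate = 0
        for combo in itertools.product(range(arrays.n), repeat=arrays.n):
            ci = np.asarray(combo, dtype=int)
            if arrays.is_degenerate(ci):
                n_degenerate += 1
            rows.append(arrays.estimate(ci, names))
        resamples = {p: np.array([row[p] for row in rows]) for p in names}
        ddof = 0
        B = len(rows)
    else:
        rng = np.random.default_rng(config.seed)
        idx, n_degenerate = _resample_matrix(arrays, config, rng)
        rows = [arrays.estimate(idx[b], names) for b in range(config.B)]
        resamples = {p: np.array([row[p] for row in rows]) for p in names}
        ddof = 1
        B = config.B

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boot_mean = {p: float(np.nanmean(v)) for p, v in resamples.items()}
        se = {p: float(np.nanstd(v, ddof=ddof)) for p, v in resamples.items()}
    return BootstrapResult(
        point=point,
        boot_mean=boot_mean,
        se=se,
        resamples=resamples,
        n_degenerate=n_degenerate,
        B=B,
    )


def paired_bootstrap_test(
    a: CohortTable,
    b: CohortTable,
    config: BootstrapConfig,
    parameters: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    method: str = "difference",
) -> dict[str, PairedTestResult]:
    """Compare two cohorts parameter-by-parameter.

    Both cohorts are resampled with identically seeded streams so that the
    b-th resamples form a pair (and comparing a cohort to itself under one
    seed gives all-zero differences).  ``method="ci-overlap"`` instead
    flags significance when the two ``1 - alpha`` percentile intervals do
    not overlap (the p-value is still the difference-based one).
    """
    if method not in ("difference", "ci-overlap"):
        raise BootstrapConfigError(f"unknown comparison method {method!r}")
    res_a = bootstrap_parameters(a, config, parameters=parameters)
    res_b = bootstrap_parameters(b, config, parameters=parameters)
    out: dict[str, PairedTestResult] = {}
    for name in res_a.resamples:
        if name not in res_b.resamples:
            continue
        d = res_a.resamples[name] - res_b.resamples[name]
        valid = d[~np.isnan(d)]
        n_pairs = valid.size
        if n_pairs == 0:
            out[name] = PairedTestResult(name, math.nan, math.nan, False, 0)
            continue
        frac_le = float(np.mean(valid <= 0))
        frac_ge = float(np.mean(valid >= 0))
        p = 2.0 * min(frac_le, frac_ge)
        p = min(max(p, 1.0 / n_pairs), 1.0)
        if method == "difference":
            significant = p < alpha
        else:
            qa = np.nanpercentile(res_a.resamples[name], [100 * alpha / 2, 100 * (1 - alpha / 2)])
            qb = np.nanpercentile(res_b.resamples[name], [100 * alpha / 2, 100 * (1 - alpha / 2)])
            significant = bool(qa[0] > qb[1] or qb[0] > qa[1])
        out[name] = PairedTestResult(
            parameter=name,
            mean_difference=float(valid.mean()),
            p_value=p,
            significant=significant,
            n_pairs=n_pairs,
        )
    return out
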