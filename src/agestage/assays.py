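"""Non-demographic assay computations.

* supercooling-point (SCP) / freezing-point (FP) detection from 1-Hz
  cooling curves, plus a planted-parameter curve simulator;
* trehalose quantification from the trehalase-difference glucose assay;
* screening proportions with Wilson confidence intervals;
* thermal-survival replicate summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import binomtest

__all__ = [
    "CoolingCurve",
    "ScpCall",
    "SurvivalReplicate",
    "TrehaloseResult",
    "ProportionSummary",
    "detect_scp",
    "simulate_cooling_curve",
    "trehalose_from_glucose",
    "proportion_summary",
    "survival_summary",
    "TREHALOSE_MOLAR_MASS",
    "GLUCOSE_MOLAR_MASS",
]

# one trehalose hydrolyzes to two glucose units
TREHALOSE_MOLAR_MASS = 342.30
GLUCOSE_MOLAR_MASS = 180.16
_MASS_PER_GLUCOSE_EQUIV = TREHALOSE_MOLAR_MASS / (2.0 * GLUCOSE_MOLAR_MASS)


@dataclass
class CoolingCurve:
    """1-Hz temperature trace for a single pupa."""

    t: np.ndarray       # seconds, uniform 1-s sampling
    temp: np.ndarray    # deg C
    pupa_id: str = ""

    def validate(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.size < 60:
            raise ValueError("cooling curve needs at least 60 samples")
        dt = np.diff(t)
        if not (dt > 0).all():
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, 1.0):
            raise ValueError("expected uniform 1-s sampling")
        if len(self.temp) != t.size:
            raise ValueError("t and temp lengths differ")


@dataclass
class ScpCall:
    detected: bool
    scp: float = math.nan          # pre-exotherm minimum (temperature reversal)
    fp: float = math.nan           # post-exotherm plateau maximum
    reversal_index: int = -1
    pupa_id: str = ""


class TrehaloseResult(NamedTuple):
    value: float
    clipped: bool                  # True when after < before (assay noise)


@dataclass
class ProportionSummary:
    successes: int
    trials: int
    percent: float
    ci_low_percent: float
    ci_high_percent: float


@dataclass
class SurvivalReplicate:
    strain: str
    sex: str
    exposure_minutes: int
    n_total: int
    n_alive: int

    def validate(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_alive <= self.n_total:
            raise ValueError("need 0 <= n_alive <= n_total")


# ---------------------------------------------------------------------------
# supercooling point
# ---------------------------------------------------------------------------

def detect_scp(
    curve: CoolingCurve,
    jump_threshold: float = 0.5,
    smooth_window: int = 3,
) -> ScpCall:
    """Locate the exotherm (temperature reversal) in a cooling curve.

    The trace is smoothed with a moving median; the exotherm is the first
    point after a net-decreasing run where the smoothed temperature rises
    by at least ``jump_threshold`` within the following 3 s.  The SCP is
    the raw minimum in a window around that point, the FP the raw maximum
    between the reversal and the resumption of cooling.  A curve with no
    reversal yields ``detected=False`` rather than an error.
    """
    curve.validate()
    temp = np.asarray(curve.temp, dtype=float)
    n = temp.size
    sm = median_filter(temp, size=max(1, smooth_window), mode="nearest")

    horizon = 3
    start = None
    for i in range(horizon, n - 1):
        k = min(i + horizon, n - 1)
        if sm[i] > sm[i - horizon]:     # not at the end of a decreasing run
            continue
        if np.max(sm[i + 1 : k + 1]) - sm[i] >= jump_threshold:
            start = i
            break
    if start is None:
        return ScpCall(detected=False, pupa_id=curve.pupa_id)

    # raw minimum near the detected rise; extend past `start` because the
    # median filter delays the rise relative to the raw minimum
    lo = max(0, start - smooth_window)
    hi = min(n, start + horizon + 1)
    reversal = lo + int(np.argmin(temp[lo:hi]))
    scp = float(temp[reversal])

    # peak region: until the smoothed trace has fallen jump_threshold
    # below its post-reversal running maximum (cooling has resumed)
    run_max = -math.inf
    end = n - 1
    for j in range(reversal, n):
        run_max = max(run_max, sm[j])
        if run_max - sm[j] >= jump_threshold:
            end = j
            break
    fp = float(np.max(temp[reversal : end + 1]))

    if not fp > scp:
        return ScpCall(detected=False, pupa_id=curve.pupa_id)
    return ScpCall(
        detected=True, scp=scp, fp=fp, reversal_index=reversal, pupa_id=curve.pupa_id
    )


def simulate_cooling_curve(
    scp: float,
    fp: float,
    rate: float = 0.5,
    rate_unit: str = "C/s",
    noise_sd: float = 0.0,
    seed: int | None = None,
    start_temp: float = 5.0,
    plateau_s: int = 30,
    tail_s: int = 60,
    pupa_id: str = "sim",
) -> CoolingCurve:
    """Piecewise planted-parameter curve: decline, exotherm jump, plateau,
    resumed decline, sampled at 1 Hz.

    With ``noise_sd=0`` the raw pre-jump minimum equals ``scp`` and the
    plateau maximum equals ``fp`` exactly, so :func:`detect_scp` inverts
    the simulation.  The default cooling rate follows the assay protocol.
    """
    if not fp > scp:
        raise ValueError(f"need fp > scp, got fp={fp}, scp={scp}")
    if rate_unit == "C/min":        # the protocol's printed per-second rate is
        rate = rate / 60.0          # implausibly fast; per-minute is accepted too
    elif rate_unit != "C/s":
        raise ValueError(f"unknown rate unit {rate_unit!r}")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if start_temp <= fp:
        raise ValueError("start_temp must exceed fp")

    decline = np.arange(start_temp, scp, -rate)   # stops before crossing scp
    segments = [
        decline,
        np.array([scp]),                          # exact reversal minimum
        np.full(plateau_s, fp),                   # exotherm plateau
        fp - rate * np.arange(1, tail_s + 1),     # resumed cooling
    ]
    temp = np.concatenate(segments)
    if temp.size < 60:
        temp = np.concatenate([temp, temp[-1] - rate * np.arange(1, 61 - temp.size)])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        temp = temp + rng.normal(0.0, noise_sd, size=temp.size)
    curve = CoolingCurve(t=np.arange(temp.size, dtype=float), temp=temp, pupa_id=pupa_id)
    curve.validate()
    return curve


# ---------------------------------------------------------------------------
# sugars
# ---------------------------------------------------------------------------

def trehalose_from_glucose(
    before: float, after: float, units: str = "trehalose-mass"
) -> TrehaloseResult:
    """Trehalose from the glucose released by overnight trehalase treatment.

    The released glucose is the post-treatment reading minus the glucose
    already present before treatment.  ``units="glucose-equivalent"``
    returns that difference; ``units="trehalose-mass"`` converts it by the
    1-trehalose-to-2-glucose stoichiometry (342.30 / (2 x 180.16), about
    0.95 per unit of glucose).  A negative difference is assay noise and is
    clamped to zero with a warning, never returned negative.
    """
    if before < 0 or after < 0:
        raise ValueError("glucose readings must be >= 0")
    if units not in ("glucose-equivalent", "trehalose-mass"):
        raise ValueError(f"unknown units {units!r}")
    delta = after - before
    clipped = delta < 0
    if clipped:
        warnings.warn(
            "glucose after trehalase treatment below the pre-treatment reading; "
            "clamping trehalose to 0",
            stacklevel=2,
        )
        delta = 0.0
    if units == "glucose-equivalent":
        return TrehaloseResult(float(delta), clipped)
    return TrehaloseResult(float(delta) * _MASS_PER_GLUCOSE_EQUIV, clipped)


# ---------------------------------------------------------------------------
# proportions and survival
# ---------------------------------------------------------------------------

def proportion_summary(
    successes: int, trials: int, confidence: float = 0.95
) -> ProportionSummary:
    """Percentage with a Wilson score confidence interval."""
    if trials <= 0:
        raise ValueError("trials must be > 0")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    ci = binomtest(successes, trials).proportion_ci(
        confidence_level=confidence, method="wilson"
    )
    return ProportionSummary(
        successes=successes,
        trials=trials,
        percent=100.0 * successes / trials,
        ci_low_percent=100.0 * ci.low,
        ci_high_percent=100.0 * ci.high,
    )


def survival_summary(replicates: Iterable[SurvivalReplicate]) -> pd.DataFrame:
    """Mean survival percentage +/- SE per strain x sex x exposure condition.

    The SE is the across-replicate SD (ddof=1) over the square root of the
    replicate count; conditions with a single replicate report NaN.
    """
    rows = []
    for rep in replicates:
        rep.validate()
        rows.append(
            {
                "strain": rep.strain,
                "sex": rep.sex,
                "exposure_minutes": rep.exposure_minutes,
                "percent": 100.0 * rep.n_alive / rep.n_total,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["strain", "sex", "exposure_minutes", "mean_percent", "se_percent", "n_replicates"]
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["strain", "sex", "exposure_minutes"])["percent"]
        .agg(
            mean_percent="mean",
            se_percent=lambda v: v.std(ddof=1) / math.sqrt(len(v)),
            n_replicates="size",
        )
        .reset_index()
    )
    return grouped
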