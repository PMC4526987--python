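"""PSA kinetics (velocity, doubling time) and cohort-level pathway statistics.

Kinetics quantify how fast the biomarker moves, and are routinely used to
assess prostate-cancer progression and recurrence:

* *velocity* — the ordinary-least-squares slope of PSA (ng/ml) against time
  in days; reported natively per day, with a per-year convenience value
  (x 365.25).
* *doubling time* — ``ln 2`` divided by the OLS slope of ``ln(PSA)`` against
  time in days.  A non-positive log-slope means the level is flat or falling:
  the doubling time is reported as infinite and the (negative) log-slope is
  retained so callers can read off a halving rate.

Left-censored readings (``"<x"``, substituted by ``x/2``) participate at their
substituted value and are flagged in the result.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .core import Activity, Pathway
from .engine import (
    DEFAULT_REGIME_WINDOW,
    Cohort,
    braced_sequence,
    treatment_regime,
)
from .errors import InsufficientDataError, MalformedValueError
from .scoring import ScoringConfig

DAYS_PER_YEAR = 365.25


def _coerce_readings(readings) -> tuple[np.ndarray, np.ndarray, bool]:
    """Normalize readings to (times, values, any_censored)."""
    times, values, censored = [], [], False
    for item in readings:
        if isinstance(item, Activity):
            t, v = item.time, item.value
            censored = censored or item.censored
        else:
            t, v = item
        if not isinstance(v, (int, float)):
            raise MalformedValueError(f"non-numeric biomarker reading {v!r}")
        times.append(float(t))
        values.append(float(v))
    return np.asarray(times), np.asarray(values), censored


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        raise InsufficientDataError("kinetics require at least two readings")
    if np.ptp(x) == 0:
        raise InsufficientDataError("kinetics require readings at distinct times")
    xc = x - x.mean()
    return float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))


def psa_velocity(readings) -> float:
    """OLS slope of biomarker value against time, in ng/ml per day.

    ``readings`` is a sequence of ``(t, value)`` pairs or of biomarker
    :class:`~pathforge.core.Activity` objects.

    Raises
    ------
    InsufficientDataError
        With fewer than two readings or all readings at the same time.
    """
    t, v, _ = _coerce_readings(readings)
    return _ols_slope(t, v)


class DoublingTime(NamedTuple):
    """Doubling time in days (``inf`` for non-positive growth) and the log-slope."""

    days: float
    log_slope: float


def psa_doubling_time(readings) -> DoublingTime:
    """Doubling time from a log-linear fit: ``DT = ln 2 / slope(ln v ~ t)``.

    A non-positive slope (flat or falling level) yields ``days = inf``; the
    slope itself is returned so a halving time ``-ln 2 / slope`` can still be
    formed.

    Raises
    ------
    MalformedValueError
        If any reading is non-positive — substitute left-censored values
        (``"<x"`` becomes ``x/2``) before computing kinetics.
    InsufficientDataError
        With fewer than two readings or all readings at the same time.
    """
    t, v, _ = _coerce_readings(readings)
    if np.any(v <= 0):
        raise MalformedValueError(
            "doubling time needs strictly positive readings; canonicalize "
            "left-censored values ('<x' -> x/2) first"
        )
    slope = _ols_slope(t, np.log(v))
    days = math.log(2) / slope if slope > 0 else math.inf
    return DoublingTime(days=days, log_slope=slope)


@dataclass(frozen=True)
class KineticsResult:
    """Kinetics of one reading series; ``velocity is None`` when under-determined."""

    n_readings: int
    velocity: Optional[float] = None  # ng/ml per day
    velocity_per_year: Optional[float] = None
    doubling_time_days: Optional[float] = None  # inf for non-positive growth
    log_slope: Optional[float] = None
    interval: Optional[tuple[int, int]] = None  # (t_first, t_last)
    residual_std: Optional[float] = None  # of the linear fit, ng/ml
    any_censored: bool = False

    @property
    def empty(self) -> bool:
        return self.velocity is None


def compute_kinetics(readings) -> KineticsResult:
    """Velocity and doubling time for a reading series, tolerant of scarcity.

    Fewer than two readings (or no time spread) produce an explicit empty
    result rather than an error; a warning threshold of three readings is the
    caller's concern.  Doubling time is omitted when a reading is non-positive.
    """
    t, v, censored = _coerce_readings(readings)
    n = len(t)
    if n < 2 or np.ptp(t) == 0:
        return KineticsResult(n_readings=n, any_censored=censored)
    slope = _ols_slope(t, v)
    intercept = float(v.mean() - slope * t.mean())
    residuals = v - (intercept + slope * t)
    dt_days = log_slope = None
    if np.all(v > 0):
        dt = psa_doubling_time(list(zip(t, v)))
        dt_days, log_slope = dt.days, dt.log_slope
    return KineticsResult(
        n_readings=n,
        velocity=slope,
        velocity_per_year=slope * DAYS_PER_YEAR,
        doubling_time_days=dt_days,
        log_slope=log_slope,
        interval=(int(t.min()), int(t.max())),
        residual_std=float(np.sqrt(np.mean(residuals**2))),
        any_censored=censored,
    )


def pretreatment_kinetics(
    pathway: Pathway, config: ScoringConfig = ScoringConfig()
) -> KineticsResult:
    """Kinetics restricted to readings at or before the first radical treatment.

    With no treatment recorded, all readings are used.  A reading exactly at
    the treatment time counts as pre-treatment (baseline sampling).
    """
    readings = [
        a
        for a in pathway
        if a.code == config.biomarker_code and isinstance(a.value, float)
    ]
    ref = None
    for a in pathway:
        if a.code in config.positioning_treatment_codes:
            ref = a.time
            break
    if ref is not None:
        readings = [a for a in readings if a.time <= ref]
    return compute_kinetics(readings)


# ---------------------------------------------------------------------------
# Cohort summary statistics
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Cohort-level pathway statistics.

    Fractions are of the whole cohort; top-k lists are sorted by descending
    count (ties alphabetical).  *Pathway length* is last minus first activity
    time in days; *length from diagnosis* is simply the last activity time.
    """

    n_patients: int
    unique_codes_mean: float
    unique_codes_sd: float
    length_days_mean: float
    length_days_sd: float
    length_from_diagnosis_mean: float
    length_from_diagnosis_sd: float
    most_common_code: tuple[str, int, float]  # (code, n pathways containing it, fraction)
    top_start_codes: list[tuple[str, int, float]]
    top_terminal_codes: list[tuple[str, int, float]]
    n_unique_sequences: int
    top_sequences: list[tuple[str, int, float]]  # collapsed, brace-comma rendered
    regime_counts: dict[str, tuple[int, float]]

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "unique_codes": {"mean": self.unique_codes_mean, "sd": self.unique_codes_sd},
            "length_days": {"mean": self.length_days_mean, "sd": self.length_days_sd},
            "length_from_diagnosis": {
                "mean": self.length_from_diagnosis_mean,
                "sd": self.length_from_diagnosis_sd,
            },
            "most_common_code": list(self.most_common_code),
            "top_start_codes": [list(x) for x in self.top_start_codes],
            "top_terminal_codes": [list(x) for x in self.top_terminal_codes],
            "n_unique_sequences": self.n_unique_sequences,
            "top_sequences": [list(x) for x in self.top_sequences],
            "regimes": {k: list(v) for k, v in self.regime_counts.items()},
        }


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd


def _topk(counter: Counter, n_total: int, k: int) -> list[tuple[str, int, float]]:
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return [(key, count, count / n_total) for key, count in ranked]


def cohort_summary(
    cohort: Cohort,
    window_days: int = DEFAULT_REGIME_WINDOW,
    top_k: int = 5,
) -> CohortSummary:
    """Compute the standard cohort summary over all pathways.

    Raises
    ------
    InsufficientDataError
        On an empty cohort.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("cannot summarize an empty cohort")
    n = len(cohort)
    unique_codes = [len(set(pw.codes)) for pw in cohort]
    lengths = [pw.times[-1] - pw.times[0] for pw in cohort]
    from_diagnosis = [pw.times[-1] for pw in cohort]

    presence = Counter()
    for pw in cohort:
        presence.update(set(pw.codes))
    code, count = min(presence.items(), key=lambda kv: (-kv[1], kv[0]))

    starts = Counter(pw.codes[0] for pw in cohort)
    terminals = Counter(pw.codes[-1] for pw in cohort)
    sequences = Counter(braced_sequence(pw, collapse=True) for pw in cohort)
    regimes = Counter(treatment_regime(pw, window_days=window_days).label for pw in cohort)

    um, us = _mean_sd(unique_codes)
    lm, ls = _mean_sd(lengths)
    dm, ds = _mean_sd(from_diagnosis)
    return CohortSummary(
        n_patients=n,
        unique_codes_mean=um,
        unique_codes_sd=us,
        length_days_mean=lm,
        length_days_sd=ls,
        length_from_diagnosis_mean=dm,
        length_from_diagnosis_sd=ds,
        most_common_code=(code, count, count / n),
        top_start_codes=_topk(starts, n, top_k),
        top_terminal_codes=_topk(terminals, n, top_k),
        n_unique_sequences=len(sequences),
        top_sequences=_topk(sequences, n, top_k),
        regime_counts={
            label: (cnt, cnt / n)
            for label, cnt in sorted(regimes.items(), key=lambda kv: (-kv[1], kv[0]))
        },
    )
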