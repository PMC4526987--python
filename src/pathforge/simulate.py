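"""Seeded synthetic prostate-cancer cohort generator.

Hospital event stores are not publicly shareable, so this module emulates one:
it emits a master activity table with the statistical structure of a routine
prostate-cancer cohort — diagnosis-anchored timelines, PSA rising
exponentially toward diagnosis, treatment events drawn from a regime mixture,
post-treatment PSA decaying toward a nadir with left-censoring at the assay
limit (``"<0.1"``), informational elements at ``t = 0``, and death events —
together with a ground-truth table for every planted quantity.

Completeness classes are planted *by construction*, one recipe per class:

* S0 — all PSA rows withheld;
* S1 — post-treatment PSA withheld (or no radical treatment at all); a
  configurable subset of surveillance-only S1 patients additionally receive a
  *hidden* treatment: their PSA collapses but no radical treatment is
  recorded, which is exactly what the surveillance drop-ratio audit hunts for;
* S2 — pre-treatment PSA withheld;
* S3 — the treatment that actually caused the PSA collapse is withheld and
  the recorded treatment placed after the collapse, so readings straddle
  treatment but the maximum drop goes unexplained;
* S4 — readings only after treatment, spanning a second recorded treatment of
  the same modality (so the regime label is untouched);
* S5 — intact: readings before and after, maximum drop spanning treatment.

Because classes and regimes are drawn jointly with exact marginals, empirical
class and regime fractions converge to the configured mixtures.  All
randomness flows through one :class:`numpy.random.Generator`; the same seed
yields a byte-identical master table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import MASTER_COLUMNS, format_value, sort_master
from .errors import ConfigError

#: Hybrid completeness levels in mixture order.
LEVELS = ("S0", "S1", "S2", "S3", "S4", "S5")

#: Default regime mixture (fractions of the cohort).
DEFAULT_REGIME_MIXTURE = {
    "H": 0.4763,
    "S": 0.2720,
    "W": 0.1670,
    "SW": 0.0309,
    "SH": 0.0115,
    "N": 0.0423,
}

#: Default completeness-class mixture.
DEFAULT_SCORE_MIXTURE = {
    "S0": 0.0473,
    "S1": 0.0404,
    "S2": 0.0536,
    "S3": 0.2064,
    "S4": 0.0294,
    "S5": 0.6229,
}

_HORMONE_DRUGS = ("LHRH agonist", "Cyproterone Acetate", "Bicalutamide")
_GLEASON = ("3+3", "3+4", "4+3", "4+4", "4+5")
_STAGES = ("1", "2", "3", "4")
_DEATH_CAUSES = ("C61", "I25", "J18", "C34", "I64")  # stub ICD-10 list


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of one patient's PSA trajectory.

    Pre-treatment, ``PSA(t) = baseline * 2 ** (t / doubling_time)`` (time in
    days, zeroed at diagnosis); from ``treatment_time`` on, the level decays
    exponentially with ``halving_time`` toward ``nadir``.  Readings get
    multiplicative log-normal noise of standard deviation ``noise_sd`` (on the
    log scale) and are emitted as ``"<limit"`` strings below ``censor_limit``.
    """

    baseline: float  # ng/ml at diagnosis
    doubling_time: float  # days
    treatment_time: Optional[float] = None  # None = never treated
    halving_time: float = 30.0
    nadir: float = 0.05
    noise_sd: float = 0.05
    censor_limit: float = 0.1

    def noiseless(self, t: float) -> float:
        peak_time = self.treatment_time
        if peak_time is None or t <= peak_time:
            return self.baseline * 2.0 ** (t / self.doubling_time)
        peak = self.baseline * 2.0 ** (peak_time / self.doubling_time)
        return max(self.nadir, peak * 2.0 ** (-(t - peak_time) / self.halving_time))


def simulate_psa_trajectory(
    params: TrajectoryParams, times, rng: np.random.Generator
) -> list[tuple[int, object]]:
    """Sample PSA readings at the given times.

    Returns ``(t, value)`` pairs where the value is a float, or the string
    ``"<limit"`` when the noisy value falls below the censor limit.
    """
    out = []
    for t in times:
        value = params.noiseless(t)
        if params.noise_sd > 0:
            value *= math.exp(rng.normal(0.0, params.noise_sd))
        if value < params.censor_limit:
            out.append((int(t), f"<{params.censor_limit:g}"))
        else:
            out.append((int(t), value))
    return out


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    Mixtures must sum to one (to 1e-9).  ``noise_sd`` is the log-scale
    standard deviation of the multiplicative reading noise; ``value_decimals``
    rounds emitted numeric readings (``None`` emits full precision, which
    makes noiseless trajectories exactly exponential after a round trip).
    """

    n_patients: int
    seed: int
    age_mean: float = 72.0
    age_sd: float = 9.0
    regime_mixture: dict = field(default_factory=lambda: dict(DEFAULT_REGIME_MIXTURE))
    score_mixture: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_MIXTURE))
    baseline_range: tuple[float, float] = (5.0, 60.0)
    doubling_time_range: tuple[float, float] = (180.0, 900.0)
    post_halving_time: float = 30.0
    nadir_range: tuple[float, float] = (0.03, 0.08)
    noise_sd: float = 0.05
    censor_limit: float = 0.1
    sampling_interval: float = 90.0  # mean days between routine PSA samples
    first_treatment_range: tuple[int, int] = (20, 80)
    second_treatment_gap_range: tuple[int, int] = (7, 40)
    regime_window_days: int = 92
    death_fraction: float = 0.2111
    hidden_treatment_fraction: float = 0.5  # of surveillance-only S1 patients
    value_decimals: Optional[int] = 2

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for name, mixture in (("regime", self.regime_mixture), ("score", self.score_mixture)):
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} mixture sums to {total}, expected 1")
            if any(p < 0 for p in mixture.values()):
                raise ConfigError(f"{name} mixture has negative weights")
        for value in (
            self.post_halving_time, self.censor_limit, self.sampling_interval
        ):
            if value <= 0:
                raise ConfigError("rates and limits must be positive")
        p_none = self.regime_mixture.get("N", 0.0)
        p_untreated_classes = self.score_mixture.get("S0", 0.0) + self.score_mixture.get("S1", 0.0)
        needs_treatment = 1.0 - p_untreated_classes
        if needs_treatment > 1e-9 and p_none >= 1.0 - 1e-9:
            raise ConfigError(
                "classes S2-S5 require treatment regimes, but the regime "
                "mixture is entirely 'N'"
            )
        if p_none > p_untreated_classes + 1e-9:
            raise ConfigError(
                "regime 'N' mass exceeds the S0+S1 class mass; the joint "
                "distribution cannot honour both marginals"
            )


def _ols_slope(times, values) -> float:
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    tc = t - t.mean()
    return float(np.dot(tc, v - v.mean()) / np.dot(tc, tc))


def _draw_regime(rng, cls: str, cfg: SimulationConfig) -> str:
    """Joint class/regime draw preserving both marginals exactly.

    Untreated pathways (regime ``"N"``) can only be classes S0/S1, so the
    whole ``"N"`` mass is carved out of those two classes proportionally; all
    other mass is spread over treatment regimes in mixture proportion.
    """
    mixture = cfg.regime_mixture
    p_none = mixture.get("N", 0.0)
    treated = {k: v for k, v in mixture.items() if k != "N"}
    total_treated = sum(treated.values())
    if cls in ("S0", "S1") and p_none > 0:
        p_s01 = cfg.score_mixture.get("S0", 0.0) + cfg.score_mixture.get("S1", 0.0)
        if rng.random() < p_none / p_s01:
            return "N"
    labels = list(treated)
    probs = np.array([treated[k] for k in labels], dtype=float)
    probs /= probs.sum()
    return labels[rng.choice(len(labels), p=probs)]


def _format_reading(value, decimals) -> str:
    if isinstance(value, str):  # censored
        return value
    if decimals is not None:
        value = round(value, decimals)
    return format_value(float(value))


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort.

    Returns ``(master, truth)``: the master activity table (sorted, ready for
    :func:`pathforge.core.write_master`) and the per-patient ground truth with
    columns ``Identifier, ScoreClass, Regime, Age, BaselinePSA,
    TrueDoublingTime, TrueVelocity, HiddenTreatment, Death``.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple[str, int, str, str]] = []
    truth_rows = []

    levels = list(config.score_mixture)
    level_probs = np.array([config.score_mixture[k] for k in levels], dtype=float)
    level_probs /= level_probs.sum()

    for i in range(config.n_patients):
        pid = f"{i + 1:05d}"
        cls = levels[rng.choice(len(levels), p=level_probs)]
        regime = _draw_regime(rng, cls, config)
        patient = _simulate_patient(pid, cls, regime, config, rng)
        rows.extend(patient["rows"])
        truth_rows.append(patient["truth"])

    master = sort_master(pd.DataFrame(rows, columns=list(MASTER_COLUMNS)))
    truth = pd.DataFrame(truth_rows)
    return master, truth


def _simulate_patient(pid, cls, regime, cfg, rng) -> dict:
    rows: list[tuple[str, int, str, str]] = []

    def emit(t, code, value):
        rows.append((pid, int(t), code, str(value)))

    age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 40, 95))
    emit(0, "A", age)
    emit(0, "Q", int(rng.integers(1, 6)))
    emit(0, "D", _STAGES[rng.choice(4)])
    if rng.random() < 0.8451:
        emit(int(rng.integers(0, 15)), "G", _GLEASON[rng.choice(len(_GLEASON))])
    if rng.random() < 0.1528:
        emit(int(rng.integers(-30, 61)), "I", "MRI pelvis")
    if rng.random() < 0.2132:
        emit(int(rng.integers(-200, 601)), "X", "other primary")

    baseline = float(rng.uniform(*cfg.baseline_range))
    dt_true = float(rng.uniform(*cfg.doubling_time_range))
    nadir = float(rng.uniform(*cfg.nadir_range))
    t1 = int(rng.integers(cfg.first_treatment_range[0], cfg.first_treatment_range[1] + 1))
    gap = int(
        rng.integers(cfg.second_treatment_gap_range[0], cfg.second_treatment_gap_range[1] + 1)
    )

    def treatment_value(code):
        return {
            "H": _HORMONE_DRUGS[rng.choice(len(_HORMONE_DRUGS))],
            "S": "prostatectomy",
            "W": "active surveillance",
            "R": str(int(rng.integers(20, 40))),
        }.get(code, code)

    hidden = False
    drop_onset = None  # time the PSA starts falling (recorded or hidden)
    t_rx = None  # first *recorded* radical treatment time

    # --- place treatments -------------------------------------------------
    if regime == "N":
        emit(0, "N", "no treatment agreed")
    elif cls == "S3":
        # The treatment that explains the collapse is withheld; the recorded
        # regime treatments land after the collapse has been sampled.
        if regime == "W":
            emit(t1, "W", treatment_value("W"))
            drop_onset = t1 + 30
            t_rx = drop_onset + 135
            emit(t_rx, "H", treatment_value("H"))
        else:
            drop_onset = t1
            t_rx = drop_onset + 135
            emit(t_rx, regime[0], treatment_value(regime[0]))
            if len(regime) == 2:
                emit(t_rx + gap, regime[1], treatment_value(regime[1]))
        hidden = True
    elif regime == "W":
        emit(t1, "W", treatment_value("W"))
        if cls in ("S2", "S4", "S5"):
            # Salvage radical treatment well outside the regime window, so
            # the regime label stays "W".
            t_rx = t1 + int(rng.integers(100, 301))
            emit(t_rx, "H", treatment_value("H"))
            drop_onset = t_rx
    else:
        emit(t1, regime[0], treatment_value(regime[0]))
        if len(regime) == 2:
            emit(t1 + gap, regime[1], treatment_value(regime[1]))
        t_rx = t1
        drop_onset = t1

    # Hidden-treatment surveillance patients: PSA collapses with nothing
    # radical on record.
    if (
        cls == "S1"
        and regime == "W"
        and rng.random() < cfg.hidden_treatment_fraction
    ):
        hidden = True
        drop_onset = t1 + 90 * 3 + 30

    params = TrajectoryParams(
        baseline=baseline,
        doubling_time=dt_true,
        treatment_time=drop_onset,
        halving_time=cfg.post_halving_time,
        nadir=nadir,
        noise_sd=cfg.noise_sd,
        censor_limit=cfg.censor_limit,
    )

    # --- sample reading times per class recipe -----------------------------
    n_pre = int(rng.integers(2, 6))
    t0 = -int(rng.integers(5, 31))
    pre_times = [t0]
    for _ in range(n_pre - 1):
        pre_times.append(pre_times[-1] - int(round(rng.uniform(0.5, 1.5) * cfg.sampling_interval)))
    pre_times = sorted(pre_times)

    n_post = int(rng.integers(3, 7))
    halving = cfg.post_halving_time

    # First post-treatment sample deep enough into the decline that the
    # collapse from the last pre-treatment level dominates every later
    # reading-to-reading decrement, whatever the growth accrued by treatment.
    def first_gap() -> int:
        growth = 2.0 ** (max(drop_onset, 0) / dt_true)
        return int(round(halving * (2.5 + max(0.0, math.log2(growth)))))

    post_times: list[int] = []
    if cls == "S3":
        mid = [drop_onset + int(round(1.5 * halving)) + int(k * halving) for k in range(3)]
        tail = [t_rx + int(halving), t_rx + int(2 * halving)]
        post_times = mid + tail
    elif cls == "S4":
        post_times = [t_rx + 20] + [
            t_rx + 80 + int(k * halving) for k in range(max(1, n_post - 1))
        ]
    elif drop_onset is not None:
        post_times = [drop_onset + first_gap() + int(k * halving) for k in range(n_post)]

    monitor_times: list[int] = []
    if cls == "S1" and hidden:
        # Rising readings sampled while on surveillance, before the hidden
        # treatment: these make the eventual collapse unmistakable.
        monitor_times = [t1 + 90, t1 + 180, t1 + 270]

    pre = simulate_psa_trajectory(params, pre_times + monitor_times, rng)
    post = simulate_psa_trajectory(params, post_times, rng)

    if cls == "S0":
        readings = []
    elif cls == "S1":
        readings = pre + (post if hidden else [])
    elif cls == "S2":
        readings = post
    elif cls == "S4":
        readings = post
        # Second recorded treatment of the same modality, between the first
        # and second post-treatment readings, substantiating the drop.
        salvage_code = "H" if regime == "W" else regime[0]
        emit(t_rx + 50, salvage_code, treatment_value(salvage_code))
    else:  # S3, S5
        readings = pre + post

    for t, value in readings:
        emit(t, "P", _format_reading(value, cfg.value_decimals))

    # --- death -------------------------------------------------------------
    died = rng.random() < cfg.death_fraction
    if died:
        last = max(t for _, t, _, _ in rows)
        t_death = last + 1 + int(rng.exponential(180.0))
        emit(t_death, "Z", _DEATH_CAUSES[rng.choice(len(_DEATH_CAUSES))])

    true_velocity = math.nan
    if len(pre_times) >= 2 and cls not in ("S0", "S2", "S4"):
        true_velocity = _ols_slope(pre_times, [params.noiseless(t) for t in pre_times])

    return {
        "rows": rows,
        "truth": {
            "Identifier": pid,
            "ScoreClass": cls,
            "Regime": regime,
            "Age": age,
            "BaselinePSA": baseline,
            "TrueDoublingTime": dt_true,
            "TrueVelocity": true_velocity,
            "HiddenTreatment": hidden,
            "Death": died,
        },
    }
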