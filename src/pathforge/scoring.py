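"""Biomarker-based completeness scoring of patient pathways.

A pathway is useful for studying a biomarker trend only if the biomarker was
actually sampled around treatment and if large swings in its value can be
explained by recorded care.  Two rule sets capture this for PSA:

*Positioning* (0–3) rates where PSA readings fall relative to the first
radical treatment: 0 — no readings at all; 1 — readings only at or before
treatment (or no treatment recorded); 2 — readings only after; 3 — readings
on both sides.

*Substantiation* asks whether the largest decline between PSA readings is
explained by a radical treatment (surgery, radiotherapy, chemotherapy,
orchidectomy, hormone therapy) recorded inside that interval; a trend that
never falls (constant or always rising) counts as substantiated.  Pathways
with fewer than two readings, or positioning 0/1, cannot be assessed
(``not_applicable``).

The two verdicts combine into a hybrid completeness level ``S0``–``S5``
(``S5`` most complete):

===========  ===========  ==============
overall      positioning  substantiation
===========  ===========  ==============
S0           0            n/a
S1           1            n/a
S2           2            not yes
S3           3            no
S4           2            yes
S5           3            yes
===========  ===========  ==============

A *drop ratio* (maximum PSA drop divided by the PSA at diagnosis) supports an
audit of surveillance-only patients: a large unexplained drop in a patient
with no recorded active treatment suggests an unrecorded intervention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import pandas as pd

from .core import Activity, Pathway
from .engine import Cohort
from .errors import ConfigError

logger = logging.getLogger(__name__)

Verdict = Literal["yes", "no", "not_applicable"]

#: Hybrid completeness levels, least to most complete.
SCORE_LEVELS = ("S0", "S1", "S2", "S3", "S4", "S5")


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the completeness rules.

    ``biomarker_code`` is the tracked serum marker (PSA).  The treatment sets
    default to the radical modalities — those expected to move the biomarker —
    and exclude active surveillance (``W``), which by definition leaves the
    tumour untreated.  ``pair_mode`` selects how the maximum drop is searched:
    ``"consecutive"`` (adjacent readings in time order, the default) or
    ``"all"`` (every ordered pair).
    """

    biomarker_code: str = "P"
    positioning_treatment_codes: frozenset[str] = frozenset("SRCOH")
    radical_codes: frozenset[str] = frozenset("SRCOH")
    surveillance_code: str = "W"
    drop_ratio_thresholds: tuple[float, ...] = (0.5, 1.0)
    surveillance_horizon_days: int = 365
    pair_mode: Literal["consecutive", "all"] = "consecutive"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.drop_ratio_thresholds):
            raise ConfigError("drop-ratio thresholds must be positive")
        if list(self.drop_ratio_thresholds) != sorted(self.drop_ratio_thresholds):
            raise ConfigError("drop-ratio thresholds must be ascending")
        if self.pair_mode not in ("consecutive", "all"):
            raise ConfigError(f"unknown pair_mode {self.pair_mode!r}")
        if self.surveillance_code in self.positioning_treatment_codes:
            raise ConfigError("surveillance is excluded from positioning treatments")


@dataclass(frozen=True)
class MaxDrop:
    """The largest decline between biomarker readings."""

    start: Activity
    end: Activity
    magnitude: float  # ng/ml, > 0


@dataclass(frozen=True)
class ScoreRecord:
    """Per-pathway completeness result."""

    patient_id: str
    positioning: int
    substantiation: Verdict
    overall: str
    max_drop: Optional[MaxDrop] = None
    drop_ratio: Optional[float] = None


def _numeric_readings(pathway: Pathway, config: ScoringConfig) -> list[Activity]:
    return [
        a
        for a in pathway
        if a.code == config.biomarker_code and isinstance(a.value, float)
    ]


def _first_treatment_time(pathway: Pathway, config: ScoringConfig) -> Optional[int]:
    for a in pathway:
        if a.code in config.positioning_treatment_codes:
            return a.time
    return None


def positioning_score(pathway: Pathway, config: ScoringConfig = ScoringConfig()) -> int:
    """Rate the availability and placement of biomarker readings (0–3).

    The reference point is the first activity whose code is a radical
    treatment (active surveillance excluded).  A reading exactly at the
    treatment time counts as *before* — a pre-treatment baseline sample.
    With no treatment recorded, any readings score 1.
    """
    readings = _numeric_readings(pathway, config)
    if not readings:
        return 0
    ref = _first_treatment_time(pathway, config)
    if ref is None:
        return 1
    before = any(a.time <= ref for a in readings)
    after = any(a.time > ref for a in readings)
    if before and after:
        return 3
    if after:
        return 2
    return 1


def max_biomarker_drop(
    pathway: Pathway, config: ScoringConfig = ScoringConfig()
) -> Optional[MaxDrop]:
    """The largest positive decline between biomarker readings.

    In ``"consecutive"`` mode (default) the search runs over adjacent readings
    in time order; in ``"all"`` mode over every ordered pair.  Ties break to
    the earliest start time, then the earliest end.  Returns ``None`` with
    fewer than two readings or when no decline exists.
    """
    readings = _numeric_readings(pathway, config)
    if len(readings) < 2:
        return None
    if config.pair_mode == "consecutive":
        pairs = zip(readings, readings[1:])
    else:
        pairs = (
            (readings[i], readings[j])
            for i in range(len(readings))
            for j in range(i + 1, len(readings))
        )
    best: Optional[MaxDrop] = None
    for start, end in pairs:
        magnitude = start.value - end.value
        if magnitude <= 0:
            continue
        if (
            best is None
            or magnitude > best.magnitude
            or (
                magnitude == best.magnitude
                and (start.time, end.time) < (best.start.time, best.end.time)
            )
        ):
            best = MaxDrop(start=start, end=end, magnitude=magnitude)
    return best


def substantiation(
    pathway: Pathway, config: ScoringConfig = ScoringConfig()
) -> Verdict:
    """Is the largest biomarker decline explained by a recorded radical treatment?

    ``not_applicable`` with fewer than two readings or positioning 0/1 (no
    post-treatment readings, so no treatment effect to explain).  ``yes`` when
    the maximum-drop interval — endpoints included — contains a radical
    treatment, or when the trend never falls (constant or always rising).
    ``no`` otherwise, which flags a drop with no recorded explanation.
    """
    readings = _numeric_readings(pathway, config)
    if len(readings) < 2:
        return "not_applicable"
    if positioning_score(pathway, config) <= 1:
        return "not_applicable"
    drop = max_biomarker_drop(pathway, config)
    if drop is None:
        return "yes"  # constant or always-rising trend
    lo, hi = drop.start.time, drop.end.time
    for act in pathway:
        if act.code in config.radical_codes and lo <= act.time <= hi:
            return "yes"
    return "no"


#: (positioning, substantiated?) -> hybrid level.
_OVERALL = {
    (2, False): "S2",
    (2, True): "S4",
    (3, False): "S3",
    (3, True): "S5",
}


def overall_score(positioning: int, verdict: Verdict) -> str:
    """Combine positioning and substantiation into the hybrid S0–S5 level.

    Raises
    ------
    ConfigError
        On inconsistent input — positioning 0/1 can only pair with
        ``not_applicable``, and positioning 3 always has a yes/no verdict.
    """
    if positioning not in (0, 1, 2, 3):
        raise ConfigError(f"positioning must be 0..3, got {positioning!r}")
    if verdict not in ("yes", "no", "not_applicable"):
        raise ConfigError(f"unknown substantiation verdict {verdict!r}")
    if positioning in (0, 1):
        if verdict != "not_applicable":
            raise ConfigError(
                f"positioning {positioning} cannot carry substantiation {verdict!r}"
            )
        return "S0" if positioning == 0 else "S1"
    if positioning == 3 and verdict == "not_applicable":
        raise ConfigError("positioning 3 implies >=2 readings; verdict cannot be N/A")
    return _OVERALL[(positioning, verdict == "yes")]


def drop_ratio(
    pathway: Pathway, config: ScoringConfig = ScoringConfig()
) -> Optional[float]:
    """Maximum biomarker drop divided by the biomarker value at diagnosis.

    The diagnosis value is the reading closest to ``t = 0`` from below (the
    latest reading with ``t <= 0``), falling back to the earliest reading
    after diagnosis.  ``None`` when there is no drop, no reading to anchor on,
    or a zero anchor value (logged).
    """
    drop = max_biomarker_drop(pathway, config)
    if drop is None:
        return None
    readings = _numeric_readings(pathway, config)
    at_or_before = [a for a in readings if a.time <= 0]
    anchor = at_or_before[-1] if at_or_before else readings[0]
    if anchor.value == 0:
        logger.warning(
            "patient %s: biomarker at diagnosis is 0, drop ratio undefined",
            pathway.patient_id,
        )
        return None
    return drop.magnitude / anchor.value


def score_pathway(
    pathway: Pathway, config: ScoringConfig = ScoringConfig()
) -> ScoreRecord:
    """Full completeness record for one pathway."""
    pos = positioning_score(pathway, config)
    verdict = substantiation(pathway, config)
    return ScoreRecord(
        patient_id=pathway.patient_id,
        positioning=pos,
        substantiation=verdict,
        overall=overall_score(pos, verdict),
        max_drop=max_biomarker_drop(pathway, config),
        drop_ratio=drop_ratio(pathway, config),
    )


@dataclass
class CohortScores:
    """Scores for a whole cohort plus the class-level summary."""

    records: dict[str, ScoreRecord]
    #: One row per S-level: count, fraction, mean distinct codes per pathway.
    frequencies: pd.DataFrame

    def fractions(self) -> dict[str, float]:
        return dict(zip(self.frequencies["score"], self.frequencies["fraction"]))


def score_cohort(cohort: Cohort, config: ScoringConfig = ScoringConfig()) -> CohortScores:
    """Score every pathway and tabulate the S-level mixture.

    The frequency table has one row per level ``S0``–``S5`` with the pathway
    count, the fraction of the cohort, and the mean number of distinct
    activity codes among pathways at that level (``NaN`` for empty levels).
    """
    records = {pid: score_pathway(pw, config) for pid, pw in cohort.pathways.items()}
    n = len(records)
    rows = []
    for level in SCORE_LEVELS:
        members = [pid for pid, rec in records.items() if rec.overall == level]
        uniques = [len(set(cohort[pid].codes)) for pid in members]
        rows.append(
            {
                "score": level,
                "count": len(members),
                "fraction": len(members) / n if n else 0.0,
                "mean_unique_codes": (sum(uniques) / len(uniques)) if uniques else float("nan"),
            }
        )
    return CohortScores(records=records, frequencies=pd.DataFrame(rows))


def audit_surveillance(
    cohort: Cohort, config: ScoringConfig = ScoringConfig()
) -> pd.DataFrame:
    """Drop-ratio audit of surveillance-only patients.

    Restricted to patients whose first treatment activity is active
    surveillance and who have no non-surveillance treatment within
    ``surveillance_horizon_days`` after it.  For these patients a substantial
    biomarker drop cannot be explained by recorded care and may indicate an
    unrecorded treatment.  One row per patient: the drop ratio (``NaN`` when
    no drop exists) and a boolean flag per configured threshold.
    """
    all_treatments = config.positioning_treatment_codes | {config.surveillance_code}
    rows = []
    for pid, pw in cohort.pathways.items():
        treatments = [a for a in pw if a.code in all_treatments]
        if not treatments or treatments[0].code != config.surveillance_code:
            continue
        start = treatments[0].time
        left_surveillance = any(
            a.code != config.surveillance_code
            and start < a.time <= start + config.surveillance_horizon_days
            for a in treatments
        )
        if left_surveillance:
            continue
        ratio = drop_ratio(pw, config)
        row = {"patient_id": pid, "drop_ratio": float("nan") if ratio is None else ratio}
        for threshold in config.drop_ratio_thresholds:
            row[f"over_{threshold:g}"] = ratio is not None and ratio > threshold
        rows.append(row)
    columns = ["patient_id", "drop_ratio"] + [
        f"over_{t:g}" for t in config.drop_ratio_thresholds
    ]
    return pd.DataFrame(rows, columns=columns)
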