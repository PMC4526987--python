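"""Pathway data model: activities, pathways, the code dictionary and master-table I/O.

A patient *pathway* is a chronological sequence of *activities*.  Each activity
is a four-tuple ``(r, t, c, v)``: the patient identifier ``r``, the time ``t``
in whole days relative to the day of diagnosis (negative before diagnosis),
a single-letter dictionary code ``c``, and a value ``v`` that is numeric
(e.g. a PSA concentration in ng/ml) or categorical (e.g. a Gleason grade
``"4+3"``).  A *pathway dictionary* registers the meaning of every code and
partitions codes into timed *events* and *informational* elements; the latter
are pinned to ``t = 0`` so the whole pathway can be treated as a timed
sequence.

Cohorts travel on disk as a *master activity table*: a UTF-8 CSV with header
``Identifier,Time,Code,Value``, one activity per row, sorted by
``(Identifier, Time, Code)``.  Values are kept as raw text in the table (so a
left-censored laboratory result such as ``"<0.1"`` survives a round trip) and
are canonicalized when pathways are built.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence, Union

import pandas as pd

from .errors import (
    EmptyPathwayError,
    MalformedValueError,
    MasterFormatError,
    UnanchoredPatientError,
    UnknownCodeError,
)

logger = logging.getLogger(__name__)

#: Column contract of the master activity table.
MASTER_COLUMNS = ("Identifier", "Time", "Code", "Value")

Value = Union[float, str]


class CanonicalValue(NamedTuple):
    """A canonicalized activity value plus a left-censoring flag."""

    value: Value
    censored: bool


def canonicalize_value(raw: str) -> CanonicalValue:
    """Canonicalize a raw value string.

    Left-censored laboratory results of the form ``"<x"`` (value below the
    assay's reporting limit ``x``) are replaced by ``x / 2`` and flagged as
    censored — e.g. ``"<0.1"`` becomes ``0.05`` and ``"<1"`` becomes ``0.5``.
    Plain numeric strings become floats; anything else is returned trimmed, as
    a categorical value.

    Raises
    ------
    MalformedValueError
        If ``raw`` is empty, or of the form ``"<x"`` with ``x`` non-numeric or
        non-positive.
    """
    if not isinstance(raw, str):
        # Already-numeric payloads pass through unchanged.
        if isinstance(raw, (int, float)) and math.isfinite(raw):
            return CanonicalValue(float(raw), False)
        raise MalformedValueError(f"cannot canonicalize value {raw!r}")
    text = raw.strip()
    if not text:
        raise MalformedValueError("empty value string")
    if text.startswith("<"):
        body = text[1:].strip()
        try:
            limit = float(body)
        except ValueError:
            raise MalformedValueError(f"malformed censored value {raw!r}") from None
        if not math.isfinite(limit) or limit <= 0:
            raise MalformedValueError(
                f"censored value {raw!r} must have a positive finite limit"
            )
        return CanonicalValue(limit / 2.0, True)
    try:
        number = float(text)
    except ValueError:
        return CanonicalValue(text, False)
    if not math.isfinite(number):
        raise MalformedValueError(f"non-finite numeric value {raw!r}")
    return CanonicalValue(number, False)


@dataclass(frozen=True)
class Activity:
    """One timed patient event or informational fact: the tuple ``(r, t, c, v)``."""

    patient_id: str
    time: int
    code: str
    value: Value
    censored: bool = False

    def as_tuple(self) -> tuple[str, int, str, Value]:
        return (self.patient_id, self.time, self.code, self.value)


@dataclass
class DictionaryEntry:
    """One registered pathway code.

    ``clinical_class`` is one of ``demographics`` / ``diagnostics`` /
    ``treatment``; ``element_type`` is ``event`` (timed) or ``information``
    (untimed, pinned to diagnosis day).  ``support_count`` / ``support_fraction``
    record in how many cohort pathways the code occurs.
    """

    code: str
    name: str
    clinical_class: str
    element_type: str
    sources: tuple[str, ...] = ()
    support_count: int = 0
    support_fraction: float = 0.0

    CLASSES = ("demographics", "diagnostics", "treatment")
    TYPES = ("event", "information")

    def __post_init__(self) -> None:
        if not (len(self.code) == 1 and self.code.isalpha() and self.code.isupper()):
            raise ValueError(f"code must be a single uppercase letter, got {self.code!r}")
        if self.clinical_class not in self.CLASSES:
            raise ValueError(f"unknown clinical class {self.clinical_class!r}")
        if self.element_type not in self.TYPES:
            raise ValueError(f"unknown element type {self.element_type!r}")
        self.sources = tuple(self.sources)


class PathwayDictionary:
    """The code registry ``D``: every activity code a cohort may use.

    Codes are partitioned into the timed-event subset ``C_E`` and the
    informational subset ``C_I``.
    """

    def __init__(self, entries: Iterable[DictionaryEntry] = ()):
        self._entries: dict[str, DictionaryEntry] = {}
        for entry in entries:
            self.add(entry)

    # -- container protocol -------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __getitem__(self, code: str) -> DictionaryEntry:
        try:
            return self._entries[code]
        except KeyError:
            raise UnknownCodeError(code) from None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    # -- views --------------------------------------------------------------
    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self._entries)

    @property
    def event_codes(self) -> frozenset[str]:
        """C_E — codes that denote timed events."""
        return frozenset(c for c, e in self._entries.items() if e.element_type == "event")

    @property
    def info_codes(self) -> frozenset[str]:
        """C_I — informational codes, always at t = 0."""
        return frozenset(
            c for c, e in self._entries.items() if e.element_type == "information"
        )

    @property
    def treatment_codes(self) -> frozenset[str]:
        return frozenset(
            c for c, e in self._entries.items() if e.clinical_class == "treatment"
        )

    # -- mutation -----------------------------------------------------------
    def add(self, entry: DictionaryEntry) -> None:
        if entry.code in self._entries:
            raise ValueError(f"duplicate dictionary code {entry.code!r}")
        self._entries[entry.code] = entry

    def remove(self, code: str) -> DictionaryEntry:
        return self._entries.pop(code)

    def copy(self) -> "PathwayDictionary":
        return PathwayDictionary(replace(e) for e in self._entries.values())

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "code": e.code,
                "name": e.name,
                "class": e.clinical_class,
                "type": e.element_type,
                "sources": list(e.sources),
            }
            for e in self._entries.values()
        ]
        Path(path).write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayDictionary":
        records = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            DictionaryEntry(
                code=r["code"],
                name=r["name"],
                clinical_class=r["class"],
                element_type=r["type"],
                sources=tuple(r.get("sources", ())),
            )
            for r in records
        )


def default_dictionary() -> PathwayDictionary:
    """The reference prostate-cancer pathway dictionary.

    Sixteen codes in three clinical classes.  ``P`` (PSA test) is the
    biomarker that anchors completeness scoring and kinetics; treatments are
    surgery ``S``, radiotherapy ``R``, chemotherapy ``C``, orchidectomy ``O``,
    hormone therapy ``H`` and active surveillance ``W``; ``N`` records that no
    treatment was agreed.
    """
    rows = [
        ("Q", "Deprivation score", "demographics", "information", ("CR",)),
        ("A", "Age at diagnosis", "demographics", "information", ("CR",)),
        ("Z", "Death", "demographics", "event", ("CR", "ADM")),
        ("L", "Clinical trial", "demographics", "information", ("ADM",)),
        ("X", "Other cancers", "demographics", "event", ("CR",)),
        ("D", "Diagnosis and staging", "diagnostics", "event", ("CR", "HIST", "ADM")),
        ("G", "Histology grade", "diagnostics", "event", ("CR", "HIST")),
        ("I", "Imaging", "diagnostics", "event", ("RAD",)),
        ("P", "PSA test", "diagnostics", "event", ("LAB",)),
        ("S", "Surgery", "treatment", "event", ("CR", "OT")),
        ("R", "Radiotherapy", "treatment", "event", ("CR", "RT")),
        ("C", "Chemotherapy", "treatment", "event", ("CR", "ADM")),
        ("O", "Orchidectomy", "treatment", "event", ("CR", "OT")),
        ("H", "Hormone", "treatment", "event", ("CR", "ADM")),
        ("W", "Active surveillance", "treatment", "event", ("CR", "ADM")),
        ("N", "No treatment", "treatment", "information", ("CR", "ADM")),
    ]
    return PathwayDictionary(
        DictionaryEntry(code, name, cls, typ, src) for code, name, cls, typ, src in rows
    )


@dataclass(frozen=True)
class Pathway:
    """A patient's chronologically ordered activity sequence.

    Invariants: all activities share ``patient_id``; times are non-decreasing
    (equal times denote concurrent activities); informational activities sit
    at ``t = 0``.
    """

    patient_id: str
    activities: tuple[Activity, ...]

    def __len__(self) -> int:
        return len(self.activities)

    def __iter__(self):
        return iter(self.activities)

    def __getitem__(self, i):
        return self.activities[i]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(a.code for a in self.activities)

    @property
    def times(self) -> tuple[int, ...]:
        return tuple(a.time for a in self.activities)

    def readings(self, code: str) -> list[Activity]:
        """All activities with the given code, in pathway order."""
        return [a for a in self.activities if a.code == code]


RowLike = Sequence  # (patient_id, time, code, raw_value)


def build_pathway(
    rows: Iterable[RowLike],
    dictionary: PathwayDictionary,
) -> Pathway:
    """Assemble a valid :class:`Pathway` from unordered activity tuples.

    Rows are ``(patient_id, time, code, value)`` with the value either raw
    text (canonicalized here) or an already-canonical payload.  Activities are
    stable-sorted by ``(time, code)`` — the alphabetical code tie-break makes
    concurrent activities deterministic for sequence statistics.  Informational
    codes found at a nonzero time are normalized to ``t = 0`` with a logged
    warning.

    Raises
    ------
    EmptyPathwayError
        If ``rows`` is empty.
    UnknownCodeError
        If a code is absent from ``dictionary``.
    ValueError
        If rows mix patient identifiers.
    """
    materialized = list(rows)
    if not materialized:
        raise EmptyPathwayError("cannot build a pathway from zero activities")

    info_codes = dictionary.info_codes
    activities: list[Activity] = []
    patient_id: str | None = None
    for row in materialized:
        if isinstance(row, Activity):
            r, t, c, v = row.patient_id, row.time, row.code, row.value
            censored = row.censored
        else:
            r, t, c, v = row
            censored = False
        r = str(r)
        if patient_id is None:
            patient_id = r
        elif r != patient_id:
            raise ValueError(f"mixed patient identifiers {patient_id!r} and {r!r}")
        if c not in dictionary:
            raise UnknownCodeError(c)
        if isinstance(v, str):
            v, censored = canonicalize_value(v)
        elif not isinstance(row, Activity):
            v = float(v)
            if not math.isfinite(v):
                raise MalformedValueError(f"non-finite value for code {c!r}")
        t = int(t)
        if c in info_codes and t != 0:
            logger.warning(
                "informational code %s for patient %s at t=%d normalized to t=0",
                c, patient_id, t,
            )
            t = 0
        activities.append(Activity(patient_id, t, c, v, censored))

    activities.sort(key=lambda a: (a.time, a.code))
    return Pathway(patient_id=patient_id, activities=tuple(activities))


def zero_times(
    dated_rows: Iterable[Sequence],
    diagnosis_dates: Mapping[str, "date | str"],
) -> list[tuple[str, int, str, str]]:
    """Convert dated rows to diagnosis-anchored integer times.

    ``dated_rows`` are ``(patient_id, date, code, value)`` with ISO-8601
    dates; ``diagnosis_dates`` maps every patient to their diagnosis date.
    The returned time is the whole-day difference *event − diagnosis*
    (negative before diagnosis).

    Raises
    ------
    UnanchoredPatientError
        Listing every patient that has rows but no diagnosis date.
    """
    anchors = {str(k): _as_date(v) for k, v in diagnosis_dates.items()}
    rows = [(str(r), _as_date(d), c, v) for r, d, c, v in dated_rows]
    missing = {r for r, *_ in rows if r not in anchors}
    if missing:
        raise UnanchoredPatientError(missing)
    return [(r, (d - anchors[r]).days, c, v) for r, d, c, v in rows]


def _as_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value).strip())


# ---------------------------------------------------------------------------
# Master activity table I/O
# ---------------------------------------------------------------------------

def sort_master(master: pd.DataFrame) -> pd.DataFrame:
    """Return the table sorted by ``(Identifier, Time, Code)``, reindexed."""
    return master.sort_values(
        ["Identifier", "Time", "Code"], kind="stable"
    ).reset_index(drop=True)


def read_master(path: str | Path) -> pd.DataFrame:
    """Read a master activity table CSV.

    Returns a DataFrame with columns ``Identifier`` (str), ``Time`` (int),
    ``Code`` (str) and ``Value`` (raw text — canonicalized only when pathways
    are built, so censored strings like ``"<0.1"`` survive a round trip).

    Raises
    ------
    MasterFormatError
        On missing/renamed columns (a ``Date`` column means the file has not
        been time-zeroed yet — run :func:`zero_times` first) or rows with a
        non-integer time, reported with 1-based row numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    columns = tuple(frame.columns)
    if columns != MASTER_COLUMNS:
        if "Date" in columns:
            raise MasterFormatError(
                f"{path}: found a 'Date' column; master tables carry integer "
                "'Time' (days from diagnosis) — convert dates with zero_times()"
            )
        raise MasterFormatError(
            f"{path}: expected columns {','.join(MASTER_COLUMNS)}, got {','.join(columns)}"
        )
    bad_rows = []
    times = []
    for i, raw in enumerate(frame["Time"]):
        try:
            times.append(int(raw))
        except ValueError:
            bad_rows.append(i + 2)  # 1-based, +1 for the header line
            times.append(0)
    if bad_rows:
        raise MasterFormatError(
            f"{path}: non-integer Time on row(s) {', '.join(map(str, bad_rows))}"
        )
    frame["Time"] = times
    frame["Identifier"] = frame["Identifier"].astype(str)
    return frame


def write_master(master: pd.DataFrame, path: str | Path) -> None:
    """Write a master table CSV (RFC 4180 quoting, UTF-8), sorted on write."""
    missing = [c for c in MASTER_COLUMNS if c not in master.columns]
    if missing:
        raise MasterFormatError(f"cannot write master table: missing columns {missing}")
    out = sort_master(master.loc[:, list(MASTER_COLUMNS)].copy())
    out["Value"] = [format_value(v) for v in out["Value"]]
    buffer = io.StringIO()
    writer = csv.writer(buffer, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    writer.writerow(MASTER_COLUMNS)
    for row in out.itertuples(index=False):
        writer.writerow([row.Identifier, row.Time, row.Code, row.Value])
    Path(path).write_text(buffer.getvalue(), encoding="utf-8")


def format_value(value: Value) -> str:
    """Render a value for the master table: compact numerics, text verbatim."""
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    if isinstance(value, int):
        return str(value)
    return str(value)


def master_rows(master: pd.DataFrame) -> list[tuple[str, int, str, str]]:
    """The table as plain ``(patient_id, time, code, raw_value)`` tuples."""
    return [
        (str(r.Identifier), int(r.Time), str(r.Code), str(r.Value))
        for r in master.itertuples(index=False)
    ]
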