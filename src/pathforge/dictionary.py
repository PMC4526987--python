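"""The per-element lifecycle that grows the pathway dictionary and master table.

Each candidate data element (one dictionary code, e.g. the PSA test) arrives
as a flat CSV of ``Identifier,Date,Value`` rows plus a sidecar JSON naming the
code and its source system.  The lifecycle is:

1. *ingest* — restrict to the study window, drop exact duplicates,
   canonicalize values, zero times at each patient's diagnosis date, and
   produce summary statistics (support, value categories, range counts,
   extremes);
2. *decide* — a declarative keep / reject / split verdict.  Review by domain
   experts is modelled as a replayable :class:`ElementDecision` record rather
   than an interactive step, so the audit trail is data;
3. *update* — merge surviving rows into the master table, re-sort,
   de-duplicate, and refresh per-code support in the dictionary.

Ingesting elements in any order yields the same final master table.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .core import (
    MASTER_COLUMNS,
    DictionaryEntry,
    PathwayDictionary,
    canonicalize_value,
    format_value,
    sort_master,
    zero_times,
)
from .errors import ConfigError, MasterFormatError, UnknownCodeError

logger = logging.getLogger(__name__)

ELEMENT_COLUMNS = ("Identifier", "Date", "Value")


@dataclass
class ElementFile:
    """One candidate element: a code, its source tag, and raw dated rows."""

    code: str
    source_tag: str
    rows: pd.DataFrame  # columns Identifier, Date, Value (strings)

    def __post_init__(self) -> None:
        missing = [c for c in ELEMENT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise MasterFormatError(f"element file missing columns {missing}")


def read_element(csv_path: str | Path, sidecar_path: str | Path | None = None) -> ElementFile:
    """Read an element CSV and its sidecar JSON (``{"code": ..., "source": ...}``).

    The sidecar defaults to the CSV path with a ``.json`` suffix.
    """
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    rows = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    return ElementFile(code=meta["code"], source_tag=meta.get("source", ""), rows=rows)


@dataclass
class ElementSummary:
    """Descriptive statistics of an ingested element, on the retained rows."""

    code: str
    n_rows: int
    total_support: int  # distinct patients
    value_support: dict[str, int]  # categorical value -> distinct patients
    range_counts: dict[str, int]  # configured numeric range -> row count
    extremes: Optional[tuple[float, float]]  # (min, max) of numeric values
    missing_count: int
    excluded_window: int
    duplicates_dropped: int


def _parse_range(spec: str):
    """Parse a range label like ``">4.0"``, ``"<=2"`` or ``"1-10"`` into a predicate."""
    spec = spec.strip()
    for op, fn in ((">=", lambda v, x: v >= x), ("<=", lambda v, x: v <= x),
                   (">", lambda v, x: v > x), ("<", lambda v, x: v < x)):
        if spec.startswith(op):
            bound = float(spec[len(op):])
            return lambda v, fn=fn, bound=bound: fn(v, bound)
    if "-" in spec[1:]:
        split_at = spec.index("-", 1)
        lo, hi = float(spec[:split_at]), float(spec[split_at + 1:])
        return lambda v, lo=lo, hi=hi: lo <= v <= hi
    raise ConfigError(f"cannot parse range spec {spec!r}")


def ingest_element(
    element: ElementFile,
    window: tuple[date | str, date | str],
    diagnosis_dates: Mapping[str, date | str],
    ranges: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, ElementSummary]:
    """Transform an element file into master-format tuples plus a summary.

    Rows dated outside ``window`` (inclusive endpoints) are dropped and
    counted; exact ``(patient, date, value)`` duplicates are dropped and
    counted; values are canonicalized (left-censored ``"<x"`` becomes
    ``x/2``); times are zeroed at diagnosis.  ``ranges`` maps a label such as
    ``">4.0"`` to itself or another spec string and yields per-range row
    counts over the numeric values — useful for summarizing abnormal readings.

    Zero retained rows is a warning, not an error.
    """
    start, end = (_coerce(window[0]), _coerce(window[1]))
    if start > end:
        raise ConfigError(f"ill-ordered window {window!r}")
    rows = element.rows
    parsed = [(str(r), _coerce(d), str(v)) for r, d, v in
              rows[list(ELEMENT_COLUMNS)].itertuples(index=False)]

    in_window = [(r, d, v) for r, d, v in parsed if start <= d <= end]
    excluded = len(parsed) - len(in_window)

    seen, deduped = set(), []
    for row in in_window:
        if row not in seen:
            seen.add(row)
            deduped.append(row)
    duplicates = len(in_window) - len(deduped)

    missing = sum(1 for _, _, v in deduped if not v.strip())
    kept = [(r, d, v) for r, d, v in deduped if v.strip()]

    zeroed = zero_times(
        [(r, d, element.code, v) for r, d, v in kept], diagnosis_dates
    )
    canonical = [
        (r, t, c, canonicalize_value(v).value) for r, t, c, v in zeroed
    ]

    numeric = [v for *_, v in canonical if isinstance(v, float)]
    categorical_patients: dict[str, set] = {}
    for r, _, _, v in canonical:
        if isinstance(v, str):
            categorical_patients.setdefault(v, set()).add(r)
    range_counts = {}
    for label, spec in (ranges or {}).items():
        predicate = _parse_range(spec)
        range_counts[label] = sum(1 for v in numeric if predicate(v))

    summary = ElementSummary(
        code=element.code,
        n_rows=len(canonical),
        total_support=len({r for r, *_ in canonical}),
        value_support={k: len(v) for k, v in sorted(categorical_patients.items())},
        range_counts=range_counts,
        extremes=(min(numeric), max(numeric)) if numeric else None,
        missing_count=missing,
        excluded_window=excluded,
        duplicates_dropped=duplicates,
    )
    if not canonical:
        logger.warning("element %s: no rows retained after filtering", element.code)
    frame = pd.DataFrame(
        [(r, t, c, format_value(v)) for r, t, c, v in canonical],
        columns=list(MASTER_COLUMNS),
    )
    return sort_master(frame), summary


def _coerce(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value).strip())


@dataclass
class SplitSpec:
    """Rows whose value matches ``predicate`` move to ``new_code``.

    ``predicate`` is either an exact categorical value (e.g.
    ``"orchidectomy"``) or a numeric range spec (e.g. ``">4.0"``).
    """

    predicate: str
    new_code: str
    new_name: str


@dataclass
class ElementDecision:
    """The recorded review verdict for one element: keep, reject, or split."""

    code: str
    verdict: str  # keep | reject | split
    split: Optional[SplitSpec] = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in ("keep", "reject", "split"):
            raise ConfigError(f"unknown verdict {self.verdict!r}")
        if (self.verdict == "split") != (self.split is not None):
            raise ConfigError("split_spec must be present exactly when verdict='split'")


def load_decisions(path: str | Path) -> list[ElementDecision]:
    """Load a JSON list of decisions (``{code, verdict, split?, rationale?}``)."""
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    decisions = []
    for r in records:
        split = None
        if r.get("split"):
            s = r["split"]
            split = SplitSpec(
                predicate=s["predicate"], new_code=s["new_code"],
                new_name=s.get("new_name", s["new_code"]),
            )
        decisions.append(
            ElementDecision(
                code=r["code"], verdict=r["verdict"], split=split,
                rationale=r.get("rationale", ""),
            )
        )
    return decisions


def _matches(raw_value: str, predicate: str) -> bool:
    value = canonicalize_value(raw_value).value
    if isinstance(value, float):
        try:
            return _parse_range(predicate)(value)
        except ConfigError:
            return False
    return value == predicate


def apply_decision(
    tuples: pd.DataFrame,
    decision: ElementDecision,
    dictionary: PathwayDictionary,
) -> tuple[pd.DataFrame, PathwayDictionary]:
    """Apply a keep / reject / split verdict to ingested tuples.

    * keep — tuples and dictionary returned unchanged;
    * reject — the element's rows are removed and its dictionary entry (if
      any) withdrawn;
    * split — rows whose value matches the predicate are re-coded to the new
      code, which is added to the dictionary with the parent's class/type
      (e.g. splitting orchidectomy out of surgery).

    Raises
    ------
    ConfigError
        If the split's new code already exists in the dictionary.
    """
    if decision.verdict == "keep":
        return tuples, dictionary

    if decision.verdict == "reject":
        out = tuples[tuples["Code"] != decision.code].reset_index(drop=True)
        updated = dictionary.copy()
        if decision.code in updated:
            updated.remove(decision.code)
        return out, updated

    spec = decision.split
    if spec.new_code in dictionary:
        raise ConfigError(f"split target code {spec.new_code!r} already registered")
    parent = dictionary[decision.code]
    mask = (tuples["Code"] == decision.code) & tuples["Value"].map(
        lambda v: _matches(str(v), spec.predicate)
    )
    if not mask.any():
        logger.warning(
            "split of %s on %r matched zero rows", decision.code, spec.predicate
        )
    out = tuples.copy()
    out.loc[mask, "Code"] = spec.new_code
    updated = dictionary.copy()
    updated.add(
        DictionaryEntry(
            code=spec.new_code,
            name=spec.new_name,
            clinical_class=parent.clinical_class,
            element_type=parent.element_type,
            sources=parent.sources,
        )
    )
    return sort_master(out), updated


def update_master(
    master: pd.DataFrame,
    tuples: pd.DataFrame,
    dictionary: PathwayDictionary,
) -> pd.DataFrame:
    """Merge approved tuples into the master table and refresh code support.

    The merged table is re-sorted by ``(Identifier, Time, Code)`` and exact
    duplicate rows are dropped, so re-merging an element already present is a
    no-op.  Support (patients carrying each code, as count and fraction of all
    patients in the master) is recomputed in place on ``dictionary``.

    Raises
    ------
    UnknownCodeError
        If the incoming tuples carry a code absent from the dictionary.
    """
    unknown = set(tuples["Code"]) - dictionary.codes
    if unknown:
        raise UnknownCodeError(", ".join(sorted(unknown)))
    merged = pd.concat([master, tuples], ignore_index=True)
    merged = merged.drop_duplicates().pipe(sort_master)

    n_patients = merged["Identifier"].nunique()
    per_code = {
        code: group["Identifier"].nunique() for code, group in merged.groupby("Code")
    }
    for entry in dictionary:
        entry.support_count = per_code.get(entry.code, 0)
        entry.support_fraction = (
            entry.support_count / n_patients if n_patients else 0.0
        )
    return merged
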