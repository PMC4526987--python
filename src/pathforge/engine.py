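"""Cohort assembly, sequence extraction, treatment regimes, segmentation, querying.

The engine turns a master activity table into a cohort of pathways and
provides the sequence-level views that cohort statistics and audits are built
on: collapsed code strings (maximal runs of a repeated code reduced to one
symbol), treatment-regime labels (first treatment modality plus any *different*
modality started within a day window), coarse clinical segmentation, and
regular-expression retrieval over collapsed sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .core import (
    Pathway,
    PathwayDictionary,
    build_pathway,
    default_dictionary,
    master_rows,
)
from .errors import PathforgeError

#: Default day window within which a second treatment modality joins the regime.
DEFAULT_REGIME_WINDOW = 92

#: Treatment modalities eligible for regime labels ("N" is informational).
DEFAULT_REGIME_CODES = frozenset("SRCOHW")


@dataclass
class Cohort:
    """A mapping of patient identifier to :class:`Pathway`, plus its dictionary."""

    pathways: dict[str, Pathway]
    dictionary: PathwayDictionary = field(default_factory=default_dictionary)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways.values())

    def __getitem__(self, patient_id: str) -> Pathway:
        return self.pathways[str(patient_id)]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.pathways)

    @classmethod
    def from_master(
        cls, master: pd.DataFrame, dictionary: PathwayDictionary | None = None
    ) -> "Cohort":
        """Group a master table by patient and build every pathway.

        Every row of the table lands in exactly one pathway; values are
        canonicalized (censored ``"<x"`` strings become ``x/2``, flagged).
        """
        dictionary = dictionary if dictionary is not None else default_dictionary()
        groups: dict[str, list] = {}
        for row in master_rows(master):
            groups.setdefault(row[0], []).append(row)
        pathways = {
            pid: build_pathway(rows, dictionary) for pid, rows in groups.items()
        }
        return cls(pathways=pathways, dictionary=dictionary)


def collapse_repeats(codes: Iterable[str]) -> tuple[str, ...]:
    """Reduce maximal runs of consecutive identical codes to a single symbol."""
    out: list[str] = []
    for code in codes:
        if not out or out[-1] != code:
            out.append(code)
    return tuple(out)


def sequence_string(pathway: Pathway, collapse: bool = False) -> str:
    """The pathway's code sequence as a string, optionally run-length collapsed.

    ``(P,D,G,H,R,P,P,P)`` collapses to ``"PDGHRP"``.
    """
    codes = pathway.codes
    if collapse:
        codes = collapse_repeats(codes)
    return "".join(codes)


def braced_sequence(pathway: Pathway, collapse: bool = True) -> str:
    """Render a sequence in brace-comma notation, e.g. ``{P,D,G,H,P}``."""
    codes = pathway.codes
    if collapse:
        codes = collapse_repeats(codes)
    return "{" + ",".join(codes) + "}"


@dataclass(frozen=True)
class RegimeLabel:
    """A treatment-regime label: 1–2 modality letters, or ``"N"`` for none."""

    label: str
    window_days: int


def treatment_regime(
    pathway: Pathway,
    window_days: int = DEFAULT_REGIME_WINDOW,
    treatment_codes: frozenset[str] = DEFAULT_REGIME_CODES,
) -> RegimeLabel:
    """Label the pathway's treatment regime.

    The first treatment activity supplies the first letter; the earliest
    *different* treatment modality starting within ``window_days`` after it
    appends a second letter (repeats of the same modality never do).  A
    pathway with no treatment activity is labelled ``"N"``.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    treatments = [a for a in pathway if a.code in treatment_codes]
    if not treatments:
        return RegimeLabel("N", window_days)
    first = treatments[0]
    for act in treatments[1:]:
        if act.code != first.code and act.time - first.time <= window_days:
            return RegimeLabel(first.code + act.code, window_days)
    return RegimeLabel(first.code, window_days)


#: Segment labels, in chronological order.
SEGMENTS = ("pre-diagnosis", "diagnosis-to-treatment", "post-treatment")


def segment(
    pathway: Pathway,
    treatment_codes: frozenset[str] = DEFAULT_REGIME_CODES,
) -> dict[str, list]:
    """Partition activities into pre-diagnosis / diagnosis-to-treatment /
    post-treatment segments.

    Boundaries sit at ``t = 0`` (diagnosis) and at the first treatment
    activity's time; activities at the first-treatment time itself (the
    treatment and anything concurrent with it) open the post-treatment
    segment.  With no treatment present only the first two segments appear.
    Every activity lands in exactly one segment.
    """
    treatments = [a for a in pathway if a.code in treatment_codes]
    first_treatment_time = treatments[0].time if treatments else None

    segments: dict[str, list] = {"pre-diagnosis": [], "diagnosis-to-treatment": []}
    if first_treatment_time is not None:
        segments["post-treatment"] = []
    for act in pathway:
        if act.time < 0:
            segments["pre-diagnosis"].append(act)
        elif first_treatment_time is not None and act.time >= first_treatment_time:
            segments["post-treatment"].append(act)
        else:
            segments["diagnosis-to-treatment"].append(act)
    return segments


def query(cohort: Cohort, pattern: str) -> list[str]:
    """Patient identifiers whose *collapsed* code string matches ``pattern``.

    ``pattern`` is an ordinary regular expression searched against the
    collapsed sequence (use anchors for full-string matches).  Results are
    sorted for determinism.

    Raises
    ------
    PathforgeError
        If the pattern is not a valid regular expression.
    """
    try:
        compiled = re.compile(pattern)
    except re.error as exc:
        raise PathforgeError(f"invalid query pattern {pattern!r}: {exc}") from exc
    hits = [
        pid
        for pid, pw in cohort.pathways.items()
        if compiled.search(sequence_string(pw, collapse=True))
    ]
    return sorted(hits)
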