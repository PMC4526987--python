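"""Static rendering of a patient pathway as a biomarker-versus-time plot.

The plot grammar: the x-axis is time in days zeroed at diagnosis, the y-axis
the primary biomarker (PSA, ng/ml).  Biomarker readings are drawn as markers
joined in time order; other timed events appear as labelled vertical lines
whose style encodes the clinical class — diagnosis solid, treatments dashed,
death bold, everything else (further diagnostics such as biopsies or grades)
dotted.  Secondary blood series (e.g. haemoglobin) ride a twin axis, with an
optional shaded normal-range band.  Captions along the x-axis summarize the
patient at diagnosis (age, stage, grade) and at death (cause, age).

Alongside the image the renderer returns a machine-readable *manifest* — one
entry per drawn element with its kind, code and x-position — so content can
be asserted without pixel comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .core import Pathway, PathwayDictionary, default_dictionary
from .errors import EmptyPlotError


@dataclass(frozen=True)
class SecondarySeries:
    """A secondary numeric series with an optional (low, high) normal band."""

    code: str
    band: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.band is not None and not self.band[0] < self.band[1]:
            raise ValueError(f"band must satisfy low < high, got {self.band}")


@dataclass(frozen=True)
class PlotSpec:
    """Rendering parameters for :func:`plot_pathway`."""

    primary_code: str = "P"
    secondary: tuple[SecondarySeries, ...] = ()
    log_scale: bool = False
    #: Overrides of the class-derived (linestyle, linewidth) per event code.
    style_overrides: dict = field(default_factory=dict)
    figsize: tuple[float, float] = (10.0, 4.5)


def _event_style(code: str, clinical_class: str, spec: PlotSpec) -> tuple[str, float]:
    if code in spec.style_overrides:
        return spec.style_overrides[code]
    if code == "Z":
        return ("solid", 2.8)  # death, bold
    if code == "D":
        return ("solid", 1.4)
    if clinical_class == "treatment":
        return ("dashed", 1.4)
    return ("dotted", 1.0)  # further diagnostics (biopsies, grades, imaging)


def plot_pathway(
    pathway: Pathway,
    spec: PlotSpec = PlotSpec(),
    out_path: str | Path | None = None,
    dictionary: PathwayDictionary | None = None,
) -> list[dict]:
    """Render one pathway and return the element manifest.

    Every timed event in the pathway contributes exactly one manifest entry:
    biomarker/secondary readings as ``marker`` entries, all other timed events
    as ``event_line`` entries.  Overlapping event-code labels are resolved by
    horizontal offsetting.  ``out_path`` selects the format by suffix (PNG or
    SVG); pass ``None`` to build the manifest without writing a file.

    Raises
    ------
    EmptyPlotError
        If the pathway holds no drawable content (only informational
        elements).
    """
    dictionary = dictionary if dictionary is not None else default_dictionary()
    series_codes = {spec.primary_code} | {s.code for s in spec.secondary}
    event_codes = dictionary.event_codes

    drawable = [a for a in pathway if a.code in event_codes]
    if not drawable:
        raise EmptyPlotError(
            f"pathway {pathway.patient_id}: no timed events to draw"
        )

    manifest: list[dict] = []
    with plt.rc_context({"svg.hashsalt": "pathforge"}):
        fig, ax = plt.subplots(figsize=spec.figsize)
        ax.set_xlabel("time from diagnosis (days)")
        ax.set_ylabel(f"{spec.primary_code} (ng/ml)")
        if spec.log_scale:
            ax.set_yscale("log")

        # -- primary biomarker series ---------------------------------------
        primary = [
            a for a in pathway
            if a.code == spec.primary_code and isinstance(a.value, float)
        ]
        if primary:
            ax.plot(
                [a.time for a in primary],
                [a.value for a in primary],
                marker="o", color="tab:blue", lw=1.2,
            )
            for a in primary:
                manifest.append(
                    {"kind": "marker", "code": a.code, "x": a.time, "y": a.value}
                )

        # -- secondary series ------------------------------------------------
        if spec.secondary:
            twin = ax.twinx()
            twin.set_ylabel(" / ".join(s.code for s in spec.secondary))
            for series in spec.secondary:
                points = [
                    a for a in pathway
                    if a.code == series.code and isinstance(a.value, float)
                ]
                if series.band is not None:
                    low, high = series.band
                    twin.axhspan(low, high, alpha=0.15, color="tab:green")
                    manifest.append(
                        {"kind": "band", "code": series.code, "low": low, "high": high}
                    )
                if points:
                    twin.plot(
                        [a.time for a in points],
                        [a.value for a in points],
                        marker="*", lw=1.0, color="tab:orange",
                    )
                    for a in points:
                        manifest.append(
                            {"kind": "marker", "code": a.code, "x": a.time, "y": a.value}
                        )

        # -- vertical event lines with collision-resolved labels -------------
        span = max(a.time for a in drawable) - min(a.time for a in drawable)
        min_gap = max(span, 1) * 0.02
        used_label_x: list[float] = []
        for a in drawable:
            if a.code in series_codes and isinstance(a.value, float):
                continue  # already drawn as a marker
            style, width = _event_style(a.code, dictionary[a.code].clinical_class, spec)
            ax.axvline(a.time, linestyle=style, linewidth=width, color="0.25")
            label_x = float(a.time)
            while any(abs(label_x - x) < min_gap for x in used_label_x):
                label_x += min_gap
            used_label_x.append(label_x)
            ax.annotate(
                a.code, (label_x, 1.01), xycoords=("data", "axes fraction"),
                ha="center", fontsize=9,
            )
            manifest.append(
                {
                    "kind": "event_line", "code": a.code, "x": a.time,
                    "style": style, "label_x": label_x,
                }
            )

        # -- captions ---------------------------------------------------------
        for caption in _captions(pathway):
            ax.annotate(
                caption["text"], (caption["x"], -0.12),
                xycoords=("data", "axes fraction"), ha="center", fontsize=8,
                annotation_clip=False,
            )
            manifest.append(caption | {"kind": "caption"})

        if out_path is not None:
            fig.savefig(out_path, dpi=120, bbox_inches="tight", metadata=_metadata(out_path))
        plt.close(fig)
    return manifest


def _metadata(out_path) -> dict:
    suffix = Path(out_path).suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": "pathforge"}
    return {}


def _captions(pathway: Pathway) -> list[dict]:
    """Diagnosis caption (age, stage, grade) and death caption (cause, age)."""
    def first_value(code):
        for a in pathway:
            if a.code == code:
                return a
        return None

    captions = []
    age = first_value("A")
    stage = first_value("D")
    grade = first_value("G")
    parts = []
    if age is not None:
        parts.append(f"age {age.value:g}" if isinstance(age.value, float) else f"age {age.value}")
    if stage is not None and stage.value not in (None, ""):
        parts.append(f"stage {stage.value}")
    if grade is not None:
        parts.append(f"G {grade.value}")
    if parts:
        captions.append({"x": 0, "text": ", ".join(parts)})
    death = first_value("Z")
    if death is not None:
        captions.append({"x": death.time, "text": f"death: {death.value}"})
    return captions
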