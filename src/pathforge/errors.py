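"""Exception hierarchy for pathforge.

All package-specific failures derive from :class:`PathforgeError` so callers
can catch one base class at an application boundary.
"""


class PathforgeError(Exception):
    """Base class for all pathforge errors."""


class MalformedValueError(PathforgeError, ValueError):
    """A raw value string could not be canonicalized (e.g. ``"<-3"``, ``"<abc"``)."""


class UnknownCodeError(PathforgeError, KeyError):
    """An activity carries a code that is absent from the active dictionary."""


class EmptyPathwayError(PathforgeError, ValueError):
    """A pathway was requested for a patient with no activities."""


class UnanchoredPatientError(PathforgeError, ValueError):
    """Dated rows exist for patients with no diagnosis date to zero time on."""

    def __init__(self, patient_ids):
        self.patient_ids = sorted(patient_ids)
        super().__init__(
            "no diagnosis date for patient(s): " + ", ".join(map(str, self.patient_ids))
        )


class MasterFormatError(PathforgeError, ValueError):
    """A master activity table file violates the expected CSV contract."""


class InsufficientDataError(PathforgeError, ValueError):
    """Too few (or degenerate) readings for a kinetics computation."""


class ConfigError(PathforgeError, ValueError):
    """An invalid scoring or simulation configuration."""


class EmptyPlotError(PathforgeError, ValueError):
    """A pathway contains nothing drawable (no timed events, no biomarker series)."""
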