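"""Exception types shared across the package."""


class Motion4DError(Exception):
    """Base class for all package-specific errors."""


class NoCyclesError(Motion4DError):
    """No complete breathing cycle could be detected in a trace."""


class DegenerateTraceError(Motion4DError):
    """Trace has no usable amplitude excursion (e.g. constant signal)."""


class TraceParseError(Motion4DError):
    """A waveform CSV could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class OutOfFieldError(Motion4DError):
    """Requested geometry (sphere position, profile line) leaves the field of view."""


class NoEdgeError(Motion4DError):
    """A line profile has no half-maximum crossing on at least one side."""


class AmbiguousProfileError(Motion4DError):
    """A line profile has multiple disjoint plateaus above the half level."""


class DegenerateVarianceError(Motion4DError):
    """A statistical group has zero within-group variance."""


class DegenerateRoiError(Motion4DError):
    """ROI has no intensity structure to register on."""


class FormatError(Motion4DError):
    """On-disk image set is inconsistent (grid or bin-count mismatch)."""
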