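"""Exception hierarchy for acidmap.

All errors derive from :class:`AcidmapError` so callers can catch the
package's failures with a single clause while still discriminating the
stage that failed.
"""


class AcidmapError(Exception):
    """Base class for all acidmap errors."""


class SpectrumFormatError(AcidmapError, ValueError):
    """A spectrum file could not be parsed (non-numeric rows, duplicate shifts)."""


class ManifestError(AcidmapError, ValueError):
    """A dataset manifest is malformed or references a missing file."""


class PeakBoundsError(AcidmapError, ValueError):
    """Peak-1 endpoints could not be located (no trough, no left crossing)."""


class WindowError(AcidmapError, ValueError):
    """The spectrum is too short for the fixed crop window."""


class NormalizationError(AcidmapError, ValueError):
    """Internal-standard normalization impossible (nonpositive peak-1 area)."""


class RatioError(AcidmapError, ValueError):
    """Intensity ratio undefined (nonpositive reference-peak height)."""


class FitError(AcidmapError, RuntimeError):
    """A calibration fit failed (degenerate design or non-convergence)."""


class NetworkSpecError(AcidmapError, ValueError):
    """A network specification violates the fixed layer inventory."""


class TrainingError(AcidmapError, RuntimeError):
    """Training diverged (non-finite loss)."""


class GenerationError(AcidmapError, RuntimeError):
    """Chip generation could not hit the requested group within the retry budget."""


class AssignmentError(AcidmapError, ValueError):
    """Chip-group assignment impossible (no pH-6.50 acquisitions)."""


class AssemblyError(AcidmapError, ValueError):
    """pH-map assembly failed (measurement count mismatch)."""


class NumericError(AcidmapError, RuntimeError):
    """A numeric routine (root finding) failed to converge."""
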