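"""Exception hierarchy for the network-targeting pipeline.

Errors are grouped so the CLI can map them onto distinct exit codes:
configuration problems, data/geometry problems, and numerical degeneracies.
"""


class TmstargetError(Exception):
    """Base class for all package errors."""


class ConfigError(TmstargetError):
    """Invalid or inconsistent run configuration."""


class DataError(TmstargetError):
    """Invalid input data (files, tables, meshes, volumes)."""


class NumericalError(TmstargetError):
    """Degenerate numerical situation (zero variance, empty support...)."""


class IncompatibleGridError(DataError):
    """Two objects do not share the same voxel grid (shape/affine mismatch)."""


class DegenerateMapError(NumericalError):
    """A brain map has zero variance (or non-finite values) where variance is required."""


class NoStimulationError(NumericalError):
    """E-field thresholding left no suprathreshold gray-matter voxel."""


class UnclassifiedProtocolError(DataError):
    """Stimulation frequency falls in the (1, 5] Hz band the excitatory/inhibitory
    convention does not classify."""


class FrameUndefinedError(DataError):
    """The coil orientation frame is undefined at this scalp position
    (position coplanar-degenerate with the preauricular points)."""


class DegenerateCoordinateError(DataError):
    """CPC coordinate at a pole (p_nz in {0, 1}) where the coronal curve collapses."""


class NotReachableError(DataError):
    """No scalp point has an inward normal aligned with the cortical target
    within the angular cap."""


class EmptyPathologyError(DataError):
    """No focus sphere intersects the gray-matter mask."""


class DegenerateNullError(NumericalError):
    """The permutation null cannot be built (e.g. mask too small to relocate foci)."""


class DegenerateAnovaError(NumericalError):
    """Two-way ANOVA with zero error variance or otherwise undefined F statistics."""
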