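"""Local TMS effect: thresholded E-field support with signed weights.

The directly stimulated cortex is the set of gray-matter voxels whose
E-field magnitude exceeds a percentage of a robust peak. High-frequency
(> 5 Hz) protocols are excitatory and give positive weights; low-frequency
(<= 1 Hz) protocols are inhibitory and give negative weights; frequencies in
(1, 5] Hz are not classified by this convention and are rejected.

A simplified analytic E-field stand-in is provided for desk-scale work:
a Gaussian tangential footprint under the coil center with exponential
depth decay. It replaces FEM solutions where none are available; externally
computed E-field volumes (NIfTI, V/m) are consumed as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, NoStimulationError, UnclassifiedProtocolError
from .grids import BrainMap, VoxelGrid
from .scalp import CoilFrame

__all__ = [
    "StimulationProtocol",
    "LocalEffect",
    "synthetic_efield",
    "threshold_efield",
    "local_effect_vector",
]

#: quantile defining the robust peak of an E-field map
ROBUST_PEAK_QUANTILE = 0.999


@dataclass(frozen=True)
class StimulationProtocol:
    """rTMS protocol; polarity follows the frequency convention."""

    frequency_hz: float

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise DataError("frequency must be positive")
        if 1.0 < self.frequency_hz <= 5.0:
            raise UnclassifiedProtocolError(
                f"{self.frequency_hz} Hz lies in the unclassified (1, 5] Hz band"
            )

    @property
    def polarity(self) -> str:
        return "excitatory" if self.frequency_hz > 5.0 else "inhibitory"

    @property
    def sign(self) -> int:
        return +1 if self.polarity == "excitatory" else -1


@dataclass(frozen=True)
class LocalEffect:
    """Sparse signed weight vector over gray-matter voxels (the E_l vector).

    ``support`` indexes into the grid's gray-matter vector; all weights share
    the protocol's sign and are nonzero.
    """

    grid: VoxelGrid
    support: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=int)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)
        if support.size == 0:
            raise DataError("local effect support is empty")
        if support.shape != weights.shape:
            raise DataError("support and weights length mismatch")
        if np.any(weights == 0) or not np.all(np.isfinite(weights)):
            raise DataError("weights must be nonzero and finite")
        if not (np.all(weights > 0) or np.all(weights < 0)):
            raise DataError("all weights must share one sign")
        if support.min() < 0 or support.max() >= self.grid.n_voxels:
            raise DataError("support indices outside the gray-matter vector")

    def to_map(self) -> BrainMap:
        v = np.zeros(self.grid.n_voxels)
        v[self.support] = self.weights
        return BrainMap(self.grid, v)


def synthetic_efield(
    frame: CoilFrame,
    grid: VoxelGrid,
    sigma_tangential: float = 10.0,
    depth_decay: float = 20.0,
    peak: float = 100.0,
    sigma_across: float | None = None,
) -> BrainMap:
    """Analytic E-field magnitude stand-in on the gray-matter voxels.

    magnitude = peak * exp(-r^2 / 2) * exp(-d / depth_decay), where the
    squared tangential distance r^2 = (t_h / sigma_tangential)^2 +
    (t_c / sigma_across)^2 splits along the handle direction (t_h) and
    across it (t_c), and d is the depth below the coil plane along the
    inward normal (clipped at 0 above the scalp). The default is an
    isotropic footprint (``sigma_across = sigma_tangential``); a smaller
    ``sigma_across`` emulates the elongated focus of a figure-8 coil and
    makes coil orientation matter.

    Units: mm for distances, V/m for ``peak`` (never rescaled downstream).
    """
    if sigma_tangential <= 0 or depth_decay <= 0 or peak < 0:
        raise DataError("sigma_tangential and depth_decay must be positive, peak >= 0")
    if sigma_across is None:
        sigma_across = sigma_tangential
    if sigma_across <= 0:
        raise DataError("sigma_across must be positive")
    coords = grid.mask_coords_mm
    v = coords - frame.center
    depth = np.maximum(0.0, -(v @ frame.normal))
    tangential = v + depth[:, None] * frame.normal  # remove the inward component
    tangential -= (tangential @ frame.normal)[:, None] * frame.normal
    t_h = tangential @ frame.handle_dir
    cross_dir = np.cross(frame.normal, frame.handle_dir)
    t_c = tangential @ cross_dir
    r2 = (t_h / sigma_tangential) ** 2 + (t_c / sigma_across) ** 2
    mag = peak * np.exp(-0.5 * r2) * np.exp(-depth / depth_decay)
    return BrainMap(grid, mag)


def robust_peak(efield: BrainMap) -> float:
    """Robust E-field peak: 99.9th percentile of suprazero gray-matter magnitudes.

    The upper quantile (taken with the 'higher' rule) is stable against
    single-voxel FEM spikes while equalling the maximum on small supports.
    """
    vals = efield.values[efield.values > 0]
    if vals.size == 0:
        raise NoStimulationError("E-field is zero everywhere in gray matter")
    return float(np.quantile(vals, ROBUST_PEAK_QUANTILE, method="higher"))


def threshold_efield(efield: BrainMap, percent: float) -> np.ndarray:
    """Indices (into the gray-matter vector) of suprathreshold voxels.

    A voxel survives if its magnitude is >= (percent/100) x robust peak and
    is strictly positive (so percent = 0 keeps exactly the suprazero set).
    """
    if not (0.0 <= percent < 100.0):
        raise DataError(f"percent must lie in [0, 100), got {percent}")
    if np.any(efield.values < 0):
        raise DataError("E-field magnitudes must be nonnegative")
    cutoff = (percent / 100.0) * robust_peak(efield)
    support = np.nonzero((efield.values >= cutoff) & (efield.values > 0))[0]
    if support.size == 0:
        raise NoStimulationError(f"no voxel reaches {percent}% of the robust peak")
    return support


def local_effect_vector(
    efield: BrainMap,
    percent: float,
    protocol: StimulationProtocol,
    uniform_weights: bool = False,
) -> LocalEffect:
    """Signed local-effect vector E_l from a thresholded E-field.

    Weights default to the E-field magnitude at each suprathreshold voxel
    (the "E-field weighted" profile); ``uniform_weights=True`` switches to a
    constant +/-1 per voxel. Excitatory protocols give positive weights,
    inhibitory ones negative.
    """
    support = threshold_efield(efield, percent)
    if uniform_weights:
        w = np.ones(support.size)
    else:
        w = efield.values[support].copy()
    return LocalEffect(efield.grid, support, protocol.sign * w)
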