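"""Pathological-network maps: state differences and meta-analysis foci spheres.

The pathological network P of a disease is the patient-minus-control
difference of brain states, P = I_pt - I_hc. Where voxel-wise state maps are
unavailable, P is built from a coordinate-based meta-analysis (CBMA) foci
table: each focus contributes a hard sphere of its sign and weight
(hyperactive +, hypoactive -), spheres combining additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, EmptyPathologyError
from .grids import BrainMap, VoxelGrid, map_correlation

__all__ = [
    "FociTable",
    "difference_map",
    "foci_to_map",
    "radius_sensitivity",
    "DEFAULT_FOCUS_RADIUS_MM",
]

#: default foci sphere radius (midpoint of the 4-16 mm sensitivity range)
DEFAULT_FOCUS_RADIUS_MM = 10.0


@dataclass(frozen=True)
class FociTable:
    """CBMA foci: world-mm coordinates with direction (+1 hyper / -1 hypo) and weight."""

    coords: np.ndarray
    directions: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        directions = np.asarray(self.directions, dtype=int).ravel()
        weights = (
            np.ones(len(coords))
            if self.weights is None
            else np.asarray(self.weights, dtype=float).ravel()
        )
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "weights", weights)
        if coords.shape[0] == 0:
            raise DataError("foci table is empty")
        if coords.shape[1] != 3 or not np.all(np.isfinite(coords)):
            raise DataError("foci coordinates must be finite (x, y, z) mm")
        if directions.shape != (len(coords),) or not np.all(np.isin(directions, (-1, 1))):
            raise DataError("directions must be +1 or -1, one per focus")
        if weights.shape != (len(coords),) or np.any(weights <= 0):
            raise DataError("weights must be positive, one per focus")

    def __len__(self) -> int:
        return len(self.coords)

    # ------------------------------------------------------------------- I/O
    @classmethod
    def read_tsv(cls, path: str | Path) -> "FociTable":
        df = pd.read_csv(path, sep="\t")
        required = {"x", "y", "z", "direction"}
        if not required.issubset(df.columns):
            raise DataError(f"foci TSV must have columns {sorted(required)}")
        weights = df["weight"].to_numpy() if "weight" in df.columns else None
        return cls(df[["x", "y", "z"]].to_numpy(), df["direction"].to_numpy(), weights)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "direction": self.directions,
                "weight": self.weights,
            }
        ).to_csv(path, sep="\t", index=False)

    def relocated(self, new_coords: np.ndarray) -> "FociTable":
        """Same foci (directions, weights) at new coordinates."""
        return FociTable(new_coords, self.directions, self.weights)


def difference_map(i_pt: BrainMap, i_hc: BrainMap) -> BrainMap:
    """Pathological network P = I_pt - I_hc (entrywise, same grid)."""
    return i_pt - i_hc


def foci_to_map(
    foci: FociTable, grid: VoxelGrid, radius_mm: float = DEFAULT_FOCUS_RADIUS_MM
) -> BrainMap:
    """Signed sphere map: P(v) = sum_f direction_f * weight_f * 1[|v - f| <= r].

    Evaluated at gray-matter voxel centers in world mm; overlapping spheres
    add with sign. Foci outside gray matter are kept — only the in-mask
    portion of their spheres contributes.
    """
    if radius_mm <= 0:
        raise DataError("radius must be positive")
    coords = grid.mask_coords_mm
    values = np.zeros(grid.n_voxels)
    touched = False
    for f, d, w in zip(foci.coords, foci.directions, foci.weights):
        inside = np.linalg.norm(coords - f, axis=1) <= radius_mm
        if inside.any():
            touched = True
            values[inside] += d * w
    if not touched:
        raise EmptyPathologyError(
            f"no focus sphere of radius {radius_mm} mm intersects the gray-matter mask"
        )
    return BrainMap(grid, values)


def radius_sensitivity(
    foci: FociTable,
    grid: VoxelGrid,
    radii: list[float],
    score=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep the foci sphere radius; report scores and map similarity.

    Returns a (radius, score) table — score omitted when no scoring function
    is given — and the pairwise Pearson correlations between the P maps at
    the different radii.
    """
    if len(radii) < 2:
        raise DataError("radius sweep needs at least 2 radii")
    maps = {r: foci_to_map(foci, grid, r) for r in radii}
    rows = []
    for r in radii:
        row = {"radius_mm": r}
        if score is not None:
            row["score"] = float(score(maps[r]))
        rows.append(row)
    pairs = []
    for i, r1 in enumerate(radii):
        for r2 in radii[i + 1 :]:
            pairs.append(
                {
                    "radius_a": r1,
                    "radius_b": r2,
                    "correlation": map_correlation(maps[r1], maps[r2]),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(pairs)
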