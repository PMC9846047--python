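"""Voxel-wise signed functional connectome and the stimulation-network operator.

The connectome ``C`` is the N x N matrix of signed resting-state
functional-connectivity (Pearson) values between gray-matter voxels. The
stimulation network seeded by a local effect E_l is

    E_n = C . E_l / ||E_l||_1

i.e. the absolute-weight-normalized signed combination of seed connectivity
columns, so that the E-field weights of suprathreshold voxels sum to one.
With positive (excitatory) weights E_n is a convex combination of
correlation columns and stays in [-1, 1]; inhibitory stimulation yields the
exactly negated network.

Two interchangeable backends represent the same operator: a materialized
dense matrix, and a "lazy" column-standardized time-series table X for which
C . v is computed as X'(Xv)/(T-1) without ever forming C.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError
from .grids import BrainMap, VoxelGrid
from .efield import LocalEffect

__all__ = [
    "Connectome",
    "DenseConnectome",
    "TimeseriesConnectome",
    "connectome_from_timeseries",
    "stimulation_network",
    "seed_map",
]


@dataclass(frozen=True)
class Connectome:
    """Abstract voxel-wise connectome bound to a :class:`VoxelGrid`."""

    grid: VoxelGrid

    def matvec(self, v: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def column(self, i: int) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass(frozen=True)
class DenseConnectome(Connectome):
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = self.grid.n_voxels
        if m.shape != (n, n):
            raise DataError(f"connectome shape {m.shape} != ({n}, {n})")
        if not np.allclose(m, m.T, atol=1e-9):
            raise DataError("dense connectome must be symmetric within 1e-9")
        if not np.allclose(np.diag(m), 1.0, atol=1e-9):
            raise DataError("dense connectome must have unit diagonal")

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ v

    def column(self, i: int) -> np.ndarray:
        return self.matrix[:, i].copy()

    def columns(self, idx: np.ndarray) -> np.ndarray:
        return self.matrix[:, idx]

    def save(self, array_path: str | Path) -> None:
        np.save(str(array_path), self.matrix)

    @classmethod
    def load(cls, array_path: str | Path, grid: VoxelGrid) -> "DenseConnectome":
        return cls(grid, np.load(str(array_path)))


@dataclass(frozen=True)
class TimeseriesConnectome(Connectome):
    """Lazy backend holding the column-standardized T x N time-series table."""

    timeseries: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.timeseries, dtype=float)
        object.__setattr__(self, "timeseries", x)
        t, n = x.shape
        if n != self.grid.n_voxels:
            raise DataError(f"timeseries has {n} columns for N={self.grid.n_voxels}")
        if t < 3:
            raise DataError("timeseries needs T >= 3 timepoints")
        if not np.allclose(x.mean(axis=0), 0.0, atol=1e-9):
            raise DataError("timeseries columns must have zero mean")
        if not np.allclose(x.std(axis=0, ddof=1), 1.0, atol=1e-9):
            raise DataError("timeseries columns must have unit (ddof=1) sd")

    @property
    def n_timepoints(self) -> int:
        return self.timeseries.shape[0]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        x = self.timeseries
        return x.T @ (x @ v) / (x.shape[0] - 1)

    def column(self, i: int) -> np.ndarray:
        x = self.timeseries
        return x.T @ x[:, i] / (x.shape[0] - 1)

    def to_dense(self) -> DenseConnectome:
        x = self.timeseries
        c = x.T @ x / (x.shape[0] - 1)
        # exact unit diagonal / symmetry despite float round-off
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 1.0)
        return DenseConnectome(self.grid, c)


def standardize_columns(x: np.ndarray) -> np.ndarray:
    """Center and scale columns to zero mean and unit (ddof=1) sd."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DataError("constant column in the time-series table")
    return (x - x.mean(axis=0)) / sd


def connectome_from_timeseries(
    x: np.ndarray, grid: VoxelGrid, mode: str = "dense"
) -> Connectome:
    """Build a connectome from a T x N time-series table.

    ``mode='dense'`` materializes C = corr(X); ``mode='lazy'`` stores the
    standardized table and computes products on demand. Both represent the
    same operator.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise DataError("time-series table must be 2D (T x N)")
    if x.shape[0] < 3:
        raise DataError("timeseries needs T >= 3 timepoints")
    z = standardize_columns(x)
    lazy = TimeseriesConnectome(grid, z)
    if mode == "lazy":
        return lazy
    if mode == "dense":
        return lazy.to_dense()
    raise DataError(f"unknown connectome mode {mode!r}")


def stimulation_network(c: Connectome, el: LocalEffect) -> BrainMap:
    """Stimulation network E_n = C . E_l / ||E_l||_1.

    Normalization uses the sum of absolute weights, so scaling all weights
    by any alpha > 0 leaves E_n unchanged and flipping the protocol sign
    exactly negates it.
    """
    c.grid.require_same_grid(el.grid)
    norm = float(np.abs(el.weights).sum())
    v = np.zeros(c.grid.n_voxels)
    v[el.support] = el.weights / norm
    if isinstance(c, DenseConnectome):
        # seed-column combination avoids the full N x N product
        values = c.columns(el.support) @ (el.weights / norm)
    else:
        values = c.matvec(v)
    return BrainMap(c.grid, values)


def seed_map(c: Connectome, voxel: int) -> BrainMap:
    """Whole-brain connectivity profile seeded at one gray-matter voxel."""
    if not (0 <= voxel < c.grid.n_voxels):
        raise DataError(f"voxel {voxel} outside the gray-matter vector")
    return BrainMap(c.grid, c.column(int(voxel)))
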