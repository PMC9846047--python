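"""NTA scoring, placement grid search, and the position x orientation ANOVA.

Network targeting accuracy is the spatial anti-correlation between the
stimulation network and the pathological network,

    NTA(s, theta) = -corr(E_n(s, theta), P),

hypothesized to predict treatment outcome. The per-subject optimizer
exhaustively evaluates a (position x orientation) search space and takes the
maximum; cohort-level structure is assessed with a balanced two-way
fixed-effects ANOVA (position and orientation crossed, subjects as
replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import Connectome, stimulation_network
from .efield import StimulationProtocol, local_effect_vector, synthetic_efield
from .errors import DataError, DegenerateAnovaError, TmstargetError
from .grids import BrainMap, VoxelGrid, map_correlation
from .scalp import CoilFrame, CPCCoordinate, ScalpMesh, coil_frames

__all__ = [
    "DEFAULT_THRESHOLD_PERCENT",
    "SyntheticEfieldSource",
    "Subject",
    "SearchSpace",
    "NTAGrid",
    "nta",
    "nta_for_placement",
    "grid_search",
    "grid_anova",
    "threshold_sensitivity",
]

#: default E-field threshold (% of robust peak); the stability range is 75-99
DEFAULT_THRESHOLD_PERCENT = 75.0


@dataclass(frozen=True)
class SyntheticEfieldSource:
    """E-field source backed by the analytic stand-in (see :mod:`tmstarget.efield`)."""

    sigma_tangential: float = 10.0
    depth_decay: float = 20.0
    peak: float = 100.0
    sigma_across: float | None = None

    def __call__(self, frame: CoilFrame, grid: VoxelGrid) -> BrainMap:
        return synthetic_efield(
            frame,
            grid,
            sigma_tangential=self.sigma_tangential,
            depth_decay=self.depth_decay,
            peak=self.peak,
            sigma_across=self.sigma_across,
        )


@dataclass(frozen=True)
class FixedEfieldSource:
    """Placement-independent E-field (e.g. a precomputed FEM volume)."""

    efield: BrainMap

    def __call__(self, frame: CoilFrame, grid: VoxelGrid) -> BrainMap:
        grid.require_same_grid(self.efield.grid)
        return self.efield


@dataclass
class Subject:
    """All per-subject inputs of the model chain, on one shared grid."""

    subject_id: str
    scalp: ScalpMesh
    grid: VoxelGrid
    connectome: Connectome
    pathology: BrainMap
    protocol: StimulationProtocol
    efield_source: Callable[[CoilFrame, VoxelGrid], BrainMap]
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT

    def __post_init__(self) -> None:
        self.grid.require_same_grid(self.connectome.grid)
        self.grid.require_same_grid(self.pathology.grid)


@dataclass(frozen=True)
class SearchSpace:
    """Product placement space, position-major ((p0,t0), (p0,t1), ..., (p1,t0), ...)."""

    positions: tuple[CPCCoordinate, ...]
    orientations: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "orientations", tuple(float(t) for t in self.orientations))
        if not self.positions or not self.orientations:
            raise DataError("search space must have >= 1 position and orientation")
        for t in self.orientations:
            if not (-180.0 < t <= 180.0):
                raise DataError(f"orientation {t} outside (-180, 180]")
        if len(set(self.positions)) != len(self.positions):
            raise DataError("duplicate positions in search space")
        if len(set(self.orientations)) != len(self.orientations):
            raise DataError("duplicate orientations in search space")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.positions), len(self.orientations))

    @classmethod
    def from_ranges(
        cls,
        p_nz: Sequence[float],
        p_al: Sequence[float],
        orientations: "Sequence[float] | str" = "0:-165:15",
    ) -> "SearchSpace":
        """Grid product of CPC coordinates; orientations accept 'start:stop:step'
        shorthand (e.g. '0:-165:15' for the 12 orientations 0, -15, ..., -165)."""
        positions = tuple(
            CPCCoordinate(float(a), float(b)) for a in p_nz for b in p_al
        )
        if isinstance(orientations, str):
            start, stop, step = (float(x) for x in orientations.split(":"))
            n = int(round(abs(stop - start) / abs(step))) + 1
            sign = 1.0 if stop >= start else -1.0
            orient = tuple(start + sign * abs(step) * k for k in range(n))
        else:
            orient = tuple(float(t) for t in orientations)
        return cls(positions, orient)


@dataclass(frozen=True)
class NTAGrid:
    """NTA values of one subject over a search space; NaN marks failed placements."""

    subject_id: str
    space: SearchSpace
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.space.shape:
            raise DataError(f"grid shape {v.shape} != space shape {self.space.shape}")
        if not np.any(np.isfinite(v)):
            raise DataError("all placements failed: empty NTA grid")

    @property
    def argmax(self) -> tuple[int, int]:
        """Indices of the maximum NTA; ties break lexicographically
        (lowest position index, then lowest orientation index)."""
        masked = np.where(np.isfinite(self.values), self.values, -np.inf)
        flat = int(np.argmax(masked))  # C order == lexicographic tie-break
        return np.unravel_index(flat, masked.shape)  # type: ignore[return-value]

    @property
    def optimum(self) -> tuple[CPCCoordinate, float]:
        i, j = self.argmax
        return self.space.positions[i], self.space.orientations[j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pos in enumerate(self.space.positions):
            for j, theta in enumerate(self.space.orientations):
                rows.append(
                    {
                        "subject": self.subject_id,
                        "p_nz": pos.p_nz,
                        "p_al": pos.p_al,
                        "theta_deg": theta,
                        "nta": self.values[i, j],
                    }
                )
        return pd.DataFrame(rows)


def nta(en: BrainMap, p: BrainMap) -> float:
    """Network targeting accuracy: -corr(E_n, P), in [-1, 1]."""
    return -map_correlation(en, p)


def nta_for_frame(subject: Subject, frame: CoilFrame) -> float:
    """NTA of a prepared coil frame (E-field -> E_l -> E_n -> NTA chain)."""
    efield = subject.efield_source(frame, subject.grid)
    el = local_effect_vector(efield, subject.threshold_percent, subject.protocol)
    en = stimulation_network(subject.connectome, el)
    return nta(en, subject.pathology)


def nta_for_placement(
    subject: Subject, placement: tuple[CPCCoordinate, float]
) -> float:
    """NTA of one (position, orientation) placement; deterministic for fixed inputs."""
    position, theta = placement
    (frame,) = coil_frames(subject.scalp, position, [theta])
    return nta_for_frame(subject, frame)


def grid_search(subject: Subject, space: SearchSpace) -> NTAGrid:
    """Exhaustive NTA evaluation over the search space (no early stopping).

    Failed placements (no suprathreshold voxel, undefined frame...) are
    recorded as NaN and excluded from the argmax; an all-failed grid is an
    error.
    """
    n_pos, n_ori = space.shape
    values = np.full((n_pos, n_ori), np.nan)
    for i, position in enumerate(space.positions):
        try:
            frames = coil_frames(subject.scalp, position, space.orientations)
        except TmstargetError:
            continue
        for j, frame in enumerate(frames):
            try:
                values[i, j] = nta_for_frame(subject, frame)
            except TmstargetError:
                continue
    return NTAGrid(subject.subject_id, space, values)


def grid_anova(grids: Sequence[NTAGrid]) -> dict:
    """Two-way fixed-effects ANOVA of NTA over position x orientation.

    Subjects are replicates; the design must be complete (no NaN cells) and
    all grids must share one search space. Sums of squares follow the
    standard balanced decomposition; F tests use the balanced-design
    degrees of freedom.
    """
    if len(grids) < 2:
        raise DataError("ANOVA needs >= 2 subjects")
    space = grids[0].space
    for g in grids[1:]:
        if g.space != space:
            raise DataError("all NTA grids must share one search space")
    y = np.stack([g.values for g in grids])  # (subjects, positions, orientations)
    if not np.all(np.isfinite(y)):
        raise DataError("ANOVA requires complete grids (missing cells present)")
    n, a, b = y.shape
    grand = y.mean()
    cell = y.mean(axis=0)          # (a, b)
    pos_mean = y.mean(axis=(0, 2))  # (a,)
    ori_mean = y.mean(axis=(0, 1))  # (b,)
    ss_pos = n * b * float(((pos_mean - grand) ** 2).sum())
    ss_ori = n * a * float(((ori_mean - grand) ** 2).sum())
    ss_int = n * float(
        ((cell - pos_mean[:, None] - ori_mean[None, :] + grand) ** 2).sum()
    )
    ss_err = float(((y - cell[None]) ** 2).sum())
    df_pos, df_ori = a - 1, b - 1
    df_int, df_err = df_pos * df_ori, a * b * (n - 1)
    if df_err <= 0 or ss_err <= 1e-30:
        raise DegenerateAnovaError("zero error variance: F statistics undefined")
    ms_err = ss_err / df_err
    out: dict = {"df_error": df_err, "n_subjects": n}
    for name, ss, df in (
        ("position", ss_pos, df_pos),
        ("orientation", ss_ori, df_ori),
        ("interaction", ss_int, df_int),
    ):
        f_val = (ss / df) / ms_err if df > 0 else np.nan
        out[f"F_{name}"] = float(f_val)
        out[f"df_{name}"] = df
        out[f"p_{name}"] = float(sps.f.sf(f_val, df, df_err)) if df > 0 else np.nan
    return out


def threshold_sensitivity(
    subject: Subject,
    placements: Sequence[tuple[CPCCoordinate, float]],
    percents: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NTA across placements at several E-field thresholds.

    Returns the long table (placement, percent, nta) and the pairwise
    Pearson and Spearman correlations between the NTA vectors of each
    threshold, mirroring the 75-99% stability analysis.
    """
    if len(percents) < 2:
        raise DataError("threshold sweep needs >= 2 percents")
    rows = []
    columns: dict[float, list[float]] = {float(p): [] for p in percents}
    for k, (position, theta) in enumerate(placements):
        (frame,) = coil_frames(subject.scalp, position, [theta])
        efield = subject.efield_source(frame, subject.grid)
        for percent in percents:
            el = local_effect_vector(efield, float(percent), subject.protocol)
            en = stimulation_network(subject.connectome, el)
            value = nta(en, subject.pathology)
            columns[float(percent)].append(value)
            rows.append(
                {
                    "placement": k,
                    "p_nz": position.p_nz,
                    "p_al": position.p_al,
                    "theta_deg": theta,
                    "percent": percent,
                    "nta": value,
                }
            )
    vectors = {p: np.array(v) for p, v in columns.items()}
    pairs = []
    plist = list(percents)
    for i, p1 in enumerate(plist):
        for p2 in plist[i + 1 :]:
            va, vb = vectors[float(p1)], vectors[float(p2)]
            pearson = float(np.corrcoef(va, vb)[0, 1])
            spearman = float(sps.spearmanr(va, vb).statistic)
            pairs.append(
                {
                    "percent_a": p1,
                    "percent_b": p2,
                    "pearson": pearson,
                    "spearman": spearman,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(pairs)
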