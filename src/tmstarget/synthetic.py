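"""Synthetic study generator: heads, shell grids, connectomes, planted cohorts.

Everything the pipeline consumes can be generated here, deterministically
from a seed: an analytic (icosphere/ellipsoid) head with the four fiducials
at their anatomical positions, a gray-matter shell grid under the scalp, a
modular voxel-wise connectome with anti-correlated networks, a pathological
map planted on one network, and cohorts whose outcomes are a noisy linear
function of true NTA.

The connectome model is a block factor model: voxels are partitioned into K
spatially contiguous angular sectors; each voxel's time series mixes its
network factor (factors correlated across networks by a signed K x K
matrix) with idiosyncratic noise, so empirical within/between correlations
converge to the specified block values as T grows.

For planted-target recovery an optional *mirror-circuit* component adds
smooth spatial bumps whose loadings in the anterior network are negated at
the front-back mirrored position of the posterior network. This emulates
specific long-range antagonistic circuits (DLPFC-SGC-like pairing) and
gives the NTA landscape a unique peak at the mirrored partner of the
planted pathology; with a purely block-constant connectome the landscape
is flat across the whole anti-correlated network. Only supported for K=2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .connectome import Connectome, connectome_from_timeseries
from .efield import StimulationProtocol
from .errors import DataError
from .grids import BrainMap, VoxelGrid
from .optimize import (
    DEFAULT_THRESHOLD_PERCENT,
    Subject,
    SearchSpace,
    SyntheticEfieldSource,
    nta_for_placement,
)
from .pathology import FociTable, foci_to_map
from .scalp import CPCCoordinate, ScalpMesh, restore_placement_from_cortical_target
from .stats import CohortTable

__all__ = [
    "HeadSpec",
    "GridSpec",
    "ConnectomeSpec",
    "PathologySpec",
    "CohortSpec",
    "StudySpec",
    "make_head",
    "make_shell_grid",
    "make_connectome",
    "make_planted_cohort",
    "PlantedStudy",
]


@dataclass(frozen=True)
class HeadSpec:
    """Analytic head: icosphere scaled to an ellipsoid, landmarks on the equator."""

    radius_mm: float = 85.0
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subdivisions: int = 4

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or any(r <= 0 for r in self.axis_ratios):
            raise DataError("head radius and axis ratios must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Gray-matter shell under the scalp: voxels with
    radius - gap - thickness <= (scaled) radial distance <= radius - gap."""

    voxel_size_mm: float = 6.0
    shell_thickness_mm: float = 14.0
    scalp_gap_mm: float = 2.0
    min_up_frac: float = -1.0  # keep voxels with z/radius above this fraction

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise DataError("voxel size must be positive")
        if self.shell_thickness_mm <= 0:
            raise DataError("shell thickness must be positive")
        if self.scalp_gap_mm < 0:
            raise DataError("scalp gap must be nonnegative")


@dataclass(frozen=True)
class ConnectomeSpec:
    """Block-correlated networks plus optional mirror-circuit component."""

    n_networks: int = 2
    within_corr: float = 0.45
    between_corr: float | np.ndarray = -0.30
    t_timepoints: int = 600
    noise_sd: float = 0.0
    mirror_coupling: float = 0.5
    bump_scale_mm: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.within_corr < 1.0):
            raise DataError("within-network correlation must lie in (0, 1)")
        if self.t_timepoints < 3:
            raise DataError("need T >= 3 timepoints")
        if self.noise_sd < 0 or self.bump_scale_mm <= 0:
            raise DataError("noise sd must be >= 0 and bump scale > 0")
        if self.mirror_coupling != 0.0 and self.n_networks != 2:
            raise DataError("mirror coupling is only defined for K = 2 networks")

    def factor_corr(self) -> np.ndarray:
        """K x K factor correlation matrix implied by the block targets."""
        k = self.n_networks
        if np.isscalar(self.between_corr):
            b = np.full((k, k), float(self.between_corr))
        else:
            b = np.asarray(self.between_corr, dtype=float)
            if b.shape != (k, k):
                raise DataError(f"between-corr matrix must be {k}x{k}")
        corr = b / self.within_corr
        np.fill_diagonal(corr, 1.0)
        eig = np.linalg.eigvalsh(0.5 * (corr + corr.T))
        if eig.min() < -1e-10:
            raise DataError("implied factor correlation matrix is not PSD")
        return corr


@dataclass(frozen=True)
class PathologySpec:
    """Pathology planted on the target network: foci spheres around one direction."""

    target_network: int = 0
    target_direction: tuple[float, float, float] = (0.0, 0.7071, 0.7071)
    n_foci: int = 4
    focus_radius_mm: float = 10.0
    direction_sign: int = +1  # hyperactive foci by default


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size and NTA-outcome coupling: outcome = beta * NTA + eps."""

    n_subjects: int = 15
    beta: float = 1.0
    noise_sd: float = 0.05
    target_r: float | None = None  # if set, noise sd is derived from sd(NTA)
    frequency_hz: float = 10.0
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT
    placement_jitter: float = 0.12  # CPC sd of placements around the optimum


@dataclass(frozen=True)
class StudySpec:
    head: HeadSpec = field(default_factory=HeadSpec)
    grid: GridSpec = field(default_factory=lambda: GridSpec(min_up_frac=0.05))
    connectome: ConnectomeSpec = field(default_factory=ConnectomeSpec)
    pathology: PathologySpec = field(default_factory=PathologySpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    efield: SyntheticEfieldSource = field(default_factory=SyntheticEfieldSource)
    placement_box: tuple[float, float] = (0.2, 0.8)  # CPC range for placements


# ----------------------------------------------------------------- generators
def make_head(spec: HeadSpec = HeadSpec()) -> ScalpMesh:
    """Deterministic analytic head with landmarks NZ/IZ (anterior/posterior
    midline) and AL/AR (lateral) on the equator."""
    sphere = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    scales = spec.radius_mm * np.asarray(spec.axis_ratios)
    mesh = trimesh.Trimesh(
        vertices=sphere.vertices * scales, faces=sphere.faces, process=False
    )
    rx, ry, _ = scales
    landmarks = {
        "NZ": np.array([0.0, ry, 0.0]),
        "IZ": np.array([0.0, -ry, 0.0]),
        "AL": np.array([-rx, 0.0, 0.0]),
        "AR": np.array([rx, 0.0, 0.0]),
    }
    return ScalpMesh(mesh, landmarks)


def make_shell_grid(head: HeadSpec, spec: GridSpec = GridSpec()) -> VoxelGrid:
    """Voxel grid whose gray-matter mask is a cortical shell under the scalp."""
    scales = head.radius_mm * np.asarray(head.axis_ratios)
    half = float(scales.max()) + spec.voxel_size_mm
    n = int(np.ceil(2 * half / spec.voxel_size_mm)) | 1  # odd => a voxel at origin
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -spec.voxel_size_mm * (n - 1) / 2.0
    idx = np.indices((n, n, n)).reshape(3, -1).T
    xyz = idx * spec.voxel_size_mm + affine[:3, 3]
    # normalized radial coordinate: 1.0 on the scalp surface
    u = np.linalg.norm(xyz / scales, axis=1)
    lo = 1.0 - (spec.scalp_gap_mm + spec.shell_thickness_mm) / head.radius_mm
    hi = 1.0 - spec.scalp_gap_mm / head.radius_mm
    if lo >= hi or lo < 0:
        raise DataError("shell thickness/gap incompatible with the head radius")
    inside = (u >= lo) & (u <= hi)
    if spec.min_up_frac > -1.0:
        inside &= (xyz[:, 2] / head.radius_mm) > spec.min_up_frac
    mask = inside.reshape(n, n, n)
    if not mask.any():
        raise DataError("empty gray-matter shell (check thickness/voxel size)")
    return VoxelGrid((n, n, n), affine, mask)


def network_labels(grid: VoxelGrid, k: int) -> np.ndarray:
    """Partition gray-matter voxels into K contiguous azimuthal sectors.

    Sector 0 is centered on the anterior (+y) direction; for K=2 this is the
    anterior/posterior split.
    """
    xyz = grid.mask_coords_mm
    az = np.arctan2(xyz[:, 0], xyz[:, 1])  # 0 at +y (anterior)
    sector = np.floor((az + np.pi / k) / (2 * np.pi / k)).astype(int) % k
    return sector


def _mirror_bumps(grid: VoxelGrid, labels: np.ndarray, scale_mm: float) -> np.ndarray:
    """N x P loading matrix of smooth spatial bumps with mirrored, negated
    loadings in network 1 (the front-back mirror of network 0)."""
    dirs = trimesh.creation.icosphere(subdivisions=2, radius=1.0).vertices
    dirs = dirs[dirs[:, 2] >= -0.2]  # bumps live on the upper head
    xyz = grid.mask_coords_mm.copy()
    mirrored = labels == 1
    xyz[mirrored, 1] *= -1.0  # evaluate posterior voxels at their anterior partner
    r = np.linalg.norm(xyz, axis=1, keepdims=True)
    u = xyz / np.maximum(r, 1e-9)
    ang = np.arccos(np.clip(u @ dirs.T, -1, 1))
    radius = float(np.median(r))
    phi = np.exp(-0.5 * (ang * radius / scale_mm) ** 2)
    phi /= np.sqrt(np.mean(np.sum(phi**2, axis=1)))  # unit average bump variance
    phi[mirrored] *= -1.0
    return phi


def make_connectome(
    grid: VoxelGrid, spec: ConnectomeSpec = ConnectomeSpec(), seed: int = 0, mode: str = "lazy"
) -> tuple[Connectome, np.ndarray]:
    """Sample a connectome (time-series backend by default) and voxel labels."""
    rng = np.random.default_rng(seed)
    labels = network_labels(grid, spec.n_networks)
    t, n = spec.t_timepoints, grid.n_voxels
    corr = spec.factor_corr()
    # factor series with the required K x K correlation
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.maximum(w, 0))) @ v.T
    factors = rng.standard_normal((t, spec.n_networks)) @ root.T
    a = np.sqrt(spec.within_corr)
    x = a * factors[:, labels] + np.sqrt(1 - spec.within_corr) * rng.standard_normal((t, n))
    if spec.mirror_coupling != 0.0:
        phi = _mirror_bumps(grid, labels, spec.bump_scale_mm)
        h = rng.standard_normal((t, phi.shape[1]))
        x = x + spec.mirror_coupling * (h @ phi.T)
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal((t, n))
    return connectome_from_timeseries(x, grid, mode=mode), labels


def planted_foci(
    grid: VoxelGrid, labels: np.ndarray, spec: PathologySpec, head: HeadSpec
) -> FociTable:
    """Foci at the gray-matter voxel centers of the target network closest to
    the planted direction."""
    xyz = grid.mask_coords_mm
    in_net = labels == spec.target_network
    if not in_net.any():
        raise DataError("target network has no voxels")
    d = np.asarray(spec.target_direction, dtype=float)
    d = d / np.linalg.norm(d)
    u = xyz / np.maximum(np.linalg.norm(xyz, axis=1, keepdims=True), 1e-9)
    score = u @ d
    score[~in_net] = -np.inf
    order = np.argsort(-score)[: spec.n_foci]
    return FociTable(
        xyz[order],
        np.full(len(order), spec.direction_sign, dtype=int),
        np.ones(len(order)),
    )


@dataclass
class PlantedStudy:
    """A complete synthetic study with known ground truth."""

    spec: StudySpec
    seed: int
    head: ScalpMesh
    grid: VoxelGrid
    labels: np.ndarray
    foci: FociTable
    pathology: BrainMap
    subjects: list[Subject]
    placements: list[tuple[CPCCoordinate, float]]
    nta_true: np.ndarray
    cohort: CohortTable
    truth: dict

    def stimulation_networks(self) -> list[BrainMap]:
        """Each subject's E_n at their assigned placement (the fixed maps the
        network-relocation null correlates against)."""
        from .connectome import stimulation_network
        from .efield import local_effect_vector
        from .scalp import coil_frames

        maps = []
        for subject, (position, theta) in zip(self.subjects, self.placements):
            (frame,) = coil_frames(subject.scalp, position, [theta])
            efield = subject.efield_source(frame, subject.grid)
            el = local_effect_vector(efield, subject.threshold_percent, subject.protocol)
            maps.append(stimulation_network(subject.connectome, el))
        return maps

    def sample_outcomes(self, beta: float, noise_sd: float, rng: np.random.Generator,
                        target_r: float | None = None) -> CohortTable:
        """Fresh outcome draw: outcome = beta * NTA + N(0, noise_sd^2).

        ``target_r`` overrides ``noise_sd`` so that the population
        NTA-outcome correlation equals the target (given the realized
        across-subject NTA spread).
        """
        sd_nta = float(np.std(self.nta_true))
        if target_r is not None:
            if not (0 < target_r < 1):
                raise DataError("target_r must lie in (0, 1)")
            noise_sd = abs(beta) * sd_nta * np.sqrt(1.0 / target_r**2 - 1.0)
            if beta == 0:
                raise DataError("target_r requires beta != 0")
        outcome = beta * self.nta_true + noise_sd * rng.standard_normal(len(self.nta_true))
        return CohortTable(self.cohort.subjects, self.nta_true, outcome,
                           sex=self.cohort.sex, age=self.cohort.age)


def make_planted_cohort(spec: StudySpec = StudySpec(), seed: int = 0) -> PlantedStudy:
    """Build the full planted study: head, shell grid, per-subject connectomes,
    planted pathology, jittered placements, and outcomes coupled to true NTA.

    Per-subject variation comes from independent finite-T connectome draws
    (all from the same population model) and from the assigned placements,
    scattered over the placement box. All randomness derives from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_conn, s_place, s_out = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    head = make_head(spec.head)
    grid = make_shell_grid(spec.head, spec.grid)
    labels = network_labels(grid, spec.connectome.n_networks)
    foci = planted_foci(grid, labels, spec.pathology, spec.head)
    pathology = foci_to_map(foci, grid, spec.pathology.focus_radius_mm)

    # ground truth: the best cortical site is the front-back mirror of the
    # planted direction, at mid-shell depth; its scalp projection is the
    # planted optimal placement
    d = np.asarray(spec.pathology.target_direction, dtype=float)
    d = d / np.linalg.norm(d)
    partner = d * np.array([1.0, -1.0, 1.0])
    depth = spec.grid.scalp_gap_mm + 0.5 * spec.grid.shell_thickness_mm
    partner_point = partner * (spec.head.radius_mm - depth) * np.asarray(spec.head.axis_ratios)
    truth_cpc = restore_placement_from_cortical_target(head, partner_point)

    protocol = StimulationProtocol(spec.cohort.frequency_hz)
    lo, hi = spec.placement_box
    orientations = tuple(-15.0 * k for k in range(12))
    subjects: list[Subject] = []
    placements: list[tuple[CPCCoordinate, float]] = []
    nta_vals = []
    conn_seeds = ss.spawn(spec.cohort.n_subjects + 3)[3:]
    jitter = spec.cohort.placement_jitter
    for i in range(spec.cohort.n_subjects):
        conn, _ = make_connectome(
            grid, spec.connectome, seed=conn_seeds[i], mode="lazy"
        )
        subject = Subject(
            subject_id=f"sub-{i:03d}",
            scalp=head,
            grid=grid,
            connectome=conn,
            pathology=pathology,
            protocol=protocol,
            efield_source=spec.efield,
            threshold_percent=spec.cohort.threshold_percent,
        )
        # placements jittered around (and away from) the planted optimum,
        # like a cohort all treated over one broad region
        position = CPCCoordinate(
            float(np.clip(truth_cpc.p_nz + jitter * s_place.standard_normal(), lo, hi)),
            float(np.clip(truth_cpc.p_al + jitter * s_place.standard_normal(), lo, hi)),
        )
        theta = float(orientations[int(s_place.integers(0, len(orientations)))])
        placements.append((position, theta))
        subjects.append(subject)
        nta_vals.append(nta_for_placement(subject, (position, theta)))
    nta_true = np.array(nta_vals)

    sd_nta = float(np.std(nta_true))
    noise_sd = spec.cohort.noise_sd
    if spec.cohort.target_r is not None and spec.cohort.beta != 0:
        noise_sd = abs(spec.cohort.beta) * sd_nta * np.sqrt(
            1.0 / spec.cohort.target_r**2 - 1.0
        )
    outcome = spec.cohort.beta * nta_true + noise_sd * s_out.standard_normal(len(nta_true))
    sex = s_out.integers(0, 2, size=len(nta_true)).astype(float)
    age = s_out.uniform(20, 60, size=len(nta_true))
    cohort = CohortTable(
        tuple(s.subject_id for s in subjects), nta_true, outcome, sex=sex, age=age
    )
    return PlantedStudy(
        spec=spec,
        seed=seed,
        head=head,
        grid=grid,
        labels=labels,
        foci=foci,
        pathology=pathology,
        subjects=subjects,
        placements=placements,
        nta_true=nta_true,
        cohort=cohort,
        truth={
            "target_direction": d,
            "partner_point_mm": partner_point,
            "optimal_cpc": truth_cpc,
            "focus_radius_mm": spec.pathology.focus_radius_mm,
        },
    )
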