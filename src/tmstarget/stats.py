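"""Cohort-level validation statistics for the network-targeting model.

The model's hypothesis is directional: higher NTA predicts larger clinical
improvement, so all p-values are one-tailed for a positive correlation.
Two permutation nulls accompany the parametric test:

* outcome permutation — clinical outcomes randomly reassigned across
  patients, the correlation recomputed each time;
* network permutation — the pathological network rebuilt from foci
  relocated uniformly within gray matter (count, directions and weights
  preserved), per-subject NTA and the cohort correlation recomputed.

Permutation p-values use the add-one correction
p = (1 + #{r* >= r_obs}) / (1 + n_perm), which keeps them valid and
strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DegenerateNullError, NumericalError
from .grids import BrainMap, VoxelGrid
from .pathology import FociTable, foci_to_map

__all__ = [
    "CohortTable",
    "efficacy_correlation",
    "permute_outcomes",
    "permute_networks",
    "partial_correlation",
    "DEFAULT_N_PERMUTATIONS",
]

#: default number of permutation runs
DEFAULT_N_PERMUTATIONS = 100_000


@dataclass(frozen=True)
class CohortTable:
    """Per-subject NTA, outcome (improvement score) and optional covariates."""

    subjects: tuple[str, ...]
    nta: np.ndarray
    outcome: np.ndarray
    sex: np.ndarray | None = None
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        nta = np.asarray(self.nta, dtype=float).ravel()
        outcome = np.asarray(self.outcome, dtype=float).ravel()
        object.__setattr__(self, "subjects", tuple(str(s) for s in self.subjects))
        object.__setattr__(self, "nta", nta)
        object.__setattr__(self, "outcome", outcome)
        n = len(self.subjects)
        if nta.shape != (n,) or outcome.shape != (n,):
            raise DataError("nta/outcome length must match the subject list")
        if not (np.all(np.isfinite(nta)) and np.all(np.isfinite(outcome))):
            raise DataError("nta/outcome must be finite (no missing analyzed rows)")
        for name in ("sex", "age"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float).ravel()
                object.__setattr__(self, name, v)
                if v.shape != (n,):
                    raise DataError(f"{name} length must match the subject list")

    def __len__(self) -> int:
        return len(self.subjects)

    @classmethod
    def read_tsv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, sep="\t")
        if not {"subject", "nta", "outcome"}.issubset(df.columns):
            raise DataError("cohort TSV needs columns subject, nta, outcome")
        return cls(
            tuple(df["subject"].astype(str)),
            df["nta"].to_numpy(),
            df["outcome"].to_numpy(),
            sex=df["sex"].to_numpy() if "sex" in df.columns else None,
            age=df["age"].to_numpy() if "age" in df.columns else None,
        )

    def write_tsv(self, path) -> None:
        data = {"subject": self.subjects, "nta": self.nta, "outcome": self.outcome}
        if self.sex is not None:
            data["sex"] = self.sex
        if self.age is not None:
            data["age"] = self.age
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def _require_variance(x: np.ndarray, name: str) -> None:
    if np.ptp(x) == 0:
        raise NumericalError(f"{name} has zero variance")


def efficacy_correlation(cohort: CohortTable) -> dict:
    """Pearson NTA-outcome correlation with a one-tailed (r > 0) p-value."""
    if len(cohort) < 3:
        raise DataError("correlation needs n >= 3")
    _require_variance(cohort.nta, "nta")
    _require_variance(cohort.outcome, "outcome")
    res = sps.pearsonr(cohort.nta, cohort.outcome, alternative="greater")
    return {"r": float(res.statistic), "p_one_tailed": float(res.pvalue), "n": len(cohort)}


def _pearson_many(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Correlation of one vector x with each row of ys (vectorized)."""
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc @ xc) * np.einsum("ij,ij->i", yc, yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def permute_outcomes(
    cohort: CohortTable, n_perm: int = DEFAULT_N_PERMUTATIONS, seed: int = 0
) -> dict:
    """Permutation p-value from random reassignment of clinical outcomes."""
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    obs = efficacy_correlation(cohort)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    # permuted outcome rows, correlated with the fixed NTA vector in blocks
    count = 0
    block = 10_000
    for start in range(0, n_perm, block):
        m = min(block, n_perm - start)
        perms = np.empty((m, n))
        for k in range(m):
            perms[k] = cohort.outcome[rng.permutation(n)]
        r_star = _pearson_many(cohort.nta, perms)
        count += int(np.sum(r_star >= obs["r"] - 1e-12))
    p = (1 + count) / (1 + n_perm)
    return {
        "r": obs["r"],
        "p_perm": float(p),
        "n": n,
        "n_perm": n_perm,
        "seed": seed,
        "null": "outcome-permutation",
    }


def permute_networks(
    stimulation_networks: "list[BrainMap]",
    outcomes: np.ndarray,
    foci: FociTable,
    grid: VoxelGrid,
    radius_mm: float,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    relocator=None,
) -> dict:
    """Permutation p-value from randomly relocated pathological networks.

    Each permutation relocates every focus to a uniformly sampled
    gray-matter voxel center (foci count, directions and weights preserved),
    rebuilds P, recomputes each subject's NTA against it from the subject's
    (fixed) stimulation network, and recomputes the cohort correlation.
    ``relocator(rng, foci, grid) -> FociTable`` may be injected for testing;
    the default is the uniform gray-matter relocation.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    outcomes = np.asarray(outcomes, dtype=float).ravel()
    n = len(stimulation_networks)
    if outcomes.shape != (n,):
        raise DataError("one outcome per stimulation network required")
    if n < 3:
        raise DataError("correlation needs n >= 3")
    _require_variance(outcomes, "outcome")
    for en in stimulation_networks:
        grid.require_same_grid(en.grid)
    if grid.n_voxels < 2 * len(foci):
        raise DegenerateNullError("gray-matter mask too small to relocate foci")

    coords = grid.mask_coords_mm
    p_obs = foci_to_map(foci, grid, radius_mm)
    nta_obs = np.array([-_corr(en.values, p_obs.values) for en in stimulation_networks])
    _require_variance(nta_obs, "nta")
    r_obs = float(np.corrcoef(nta_obs, outcomes)[0, 1])

    # standardized E_n matrix for vectorized map correlations
    z = np.stack([en.values for en in stimulation_networks])
    z = z - z.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    count = 0
    block = 512
    signed_w = foci.directions * foci.weights
    for start in range(0, n_perm, block):
        m = min(block, n_perm - start)
        p_star = np.zeros((m, grid.n_voxels))
        for k in range(m):
            if relocator is not None:
                fstar = relocator(rng, foci, grid)
                p_star[k] = foci_to_map(fstar, grid, radius_mm).values
            else:
                centers = coords[rng.integers(0, grid.n_voxels, size=len(foci))]
                for c, w in zip(centers, signed_w):
                    inside = np.linalg.norm(coords - c, axis=1) <= radius_mm
                    p_star[k, inside] += w
        pc = p_star - p_star.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(pc, axis=1)
        good = norms > 0
        nta_star = np.full((m, n), np.nan)
        nta_star[good] = -(pc[good] / norms[good, None]) @ z.T
        r_star = _pearson_many(outcomes, nta_star)
        count += int(np.sum(r_star >= r_obs - 1e-12))
    p = (1 + count) / (1 + n_perm)
    return {
        "r": r_obs,
        "p_perm": float(p),
        "n": n,
        "n_perm": n_perm,
        "seed": seed,
        "null": "network-relocation",
    }


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def partial_correlation(cohort: CohortTable, covariate: str) -> dict:
    """NTA-outcome Pearson correlation after partialing one covariate.

    Both variables are residualized on [1, covariate] by least squares; the
    residual correlation is tested one-tailed (r > 0) with n - 3 df.
    """
    if covariate not in ("sex", "age"):
        raise DataError("covariate must be 'sex' or 'age'")
    z = getattr(cohort, covariate)
    if z is None:
        raise DataError(f"cohort has no {covariate} column")
    if np.ptp(z) == 0:
        raise NumericalError(f"covariate {covariate} is constant")
    n = len(cohort)
    if n < 4:
        raise DataError("partial correlation needs n >= 4")
    design = np.column_stack([np.ones(n), z])

    def residual(y: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return y - design @ beta

    rx = residual(cohort.nta)
    ry = residual(cohort.outcome)
    _require_variance(np.round(rx, 12), "residual nta")
    _require_variance(np.round(ry, 12), "residual outcome")
    r = _corr(rx, ry)
    df = n - 3
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(sps.t.sf(t, df))
    return {"r_partial": float(r), "p_one_tailed": p, "n": n, "covariate": covariate}
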