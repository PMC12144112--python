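"""Plan-comparison dosimetry: MAE/MSE, the gamma index, cumulative DVH
curves, and isodose-volume overlap (Dice, Hausdorff).

The gamma index follows the standard Low-type formulation: for each
evaluated voxel, gamma is the minimum over reference voxels within the
search radius of sqrt((dose difference / dose tolerance)^2 +
(distance / distance tolerance)^2); a voxel passes when gamma <= 1.
Normalization is global (percent of the reference maximum) by default,
optionally local; voxels below the low-dose cutoff are excluded from the
pass rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .transport import DoseGrid

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "DVHCurve",
    "OverlapMetrics",
    "error_metrics",
    "gamma_index",
    "compute_dvh",
    "dice_isodose",
    "hausdorff_isodose",
]

ArrayLike = Union[np.ndarray, DoseGrid]


def _dose_and_spacing(x: ArrayLike, spacing=None) -> tuple[np.ndarray, tuple[float, float, float]]:
    if isinstance(x, DoseGrid):
        return x.dose, x.spacing
    return np.asarray(x, dtype=float), tuple(spacing) if spacing is not None else (1.0, 1.0, 1.0)


def _check_grids(a: ArrayLike, b: ArrayLike, spacing=None):
    da, sa = _dose_and_spacing(a, spacing)
    db, sb = _dose_and_spacing(b, spacing)
    if da.shape != db.shape:
        raise ValueError(f"grid shape mismatch: {da.shape} vs {db.shape}")
    if not np.allclose(sa, sb):
        raise ValueError(f"grid spacing mismatch: {sa} vs {sb}")
    return da, db, sa


@dataclass
class GammaCriteria:
    """Gamma criteria: percent dose tolerance / mm distance-to-agreement."""

    dose_tolerance_percent: float = 3.0
    distance_tolerance_mm: float = 3.0
    normalization: str = "global"       # global | local
    dose_cutoff_percent: float = 10.0   # exclude voxels below this % of ref max
    search_radius_factor: float = 3.0   # search radius = factor x distance tol

    def __post_init__(self) -> None:
        if self.dose_tolerance_percent <= 0 or self.distance_tolerance_mm <= 0:
            raise ValueError("tolerances must be > 0")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")


@dataclass
class GammaResult:
    gamma_map: np.ndarray
    pass_rate: float  # percent of evaluated voxels with gamma <= 1
    n_evaluated: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pass_rate <= 100.0):
            raise ValueError("pass_rate must lie in [0, 100]")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: percent of the structure receiving
    at least each bin dose. Starts at 100% at 0 Gy, monotone non-increasing."""

    dose_bins: np.ndarray
    relative_volume: np.ndarray
    structure_voxels: int

    def to_csv(self, path: str) -> None:
        np.savetxt(
            str(path),
            np.column_stack([self.dose_bins, self.relative_volume]),
            delimiter=",",
            header="dose_gy,volume_percent",
            comments="",
        )


@dataclass
class OverlapMetrics:
    dice: float
    hausdorff_mm: float
    isodose_threshold: float


def error_metrics(pred: ArrayLike, ref: ArrayLike, mask: Optional[np.ndarray] = None) -> tuple[float, float]:
    """(MAE in Gy, MSE in Gy^2) over the evaluation mask (whole grid default)."""
    dp, dr, _ = _check_grids(pred, ref)
    if mask is not None:
        dp, dr = dp[mask], dr[mask]
    diff = dp - dr
    return float(np.mean(np.abs(diff))), float(np.mean(diff**2))


def gamma_index(
    pred: ArrayLike,
    ref: ArrayLike,
    criteria: Optional[GammaCriteria] = None,
    spacing=None,
) -> GammaResult:
    """Per-voxel gamma map and pass rate for pred evaluated against ref."""
    criteria = criteria or GammaCriteria()
    dp, dr, sp = _check_grids(pred, ref, spacing)
    ref_max = dr.max()
    if ref_max <= 0:
        raise ValueError("reference dose maximum must be > 0")
    dta = criteria.distance_tolerance_mm
    if criteria.normalization == "global":
        dose_tol = criteria.dose_tolerance_percent / 100.0 * ref_max
    radius = criteria.search_radius_factor * dta

    # neighbor offsets (voxel steps) within the search radius
    max_steps = [int(np.floor(radius / s)) for s in sp]
    oz, oy, ox = np.meshgrid(
        *[np.arange(-m, m + 1) for m in max_steps], indexing="ij"
    )
    dist = np.sqrt((oz * sp[0]) ** 2 + (oy * sp[1]) ** 2 + (ox * sp[2]) ** 2)
    keep = dist <= radius + 1e-12
    offsets = np.column_stack([oz[keep], oy[keep], ox[keep]])
    dists = dist[keep]
    order = np.argsort(dists)
    offsets, dists = offsets[order], dists[order]

    gamma_sq = np.full(dp.shape, np.inf)
    shape = dp.shape
    for (dz, dy, dx), r_mm in zip(offsets, dists):
        dist_term = (r_mm / dta) ** 2
        if dist_term >= gamma_sq.max():
            # every voxel already has a candidate at least this good
            break
        # reference shifted by the offset, aligned to evaluated voxels
        if any(abs(o) >= n for o, n in zip((dz, dy, dx), shape)):
            continue
        src = tuple(
            slice(max(0, o), min(n, n + o)) for o, n in zip((dz, dy, dx), shape)
        )
        dst = tuple(
            slice(max(0, -o), min(n, n - o)) for o, n in zip((dz, dy, dx), shape)
        )
        ref_sh = dr[src]
        pred_part = dp[dst]
        if criteria.normalization == "global":
            dd = (pred_part - ref_sh) / dose_tol
        else:
            local_tol = criteria.dose_tolerance_percent / 100.0 * np.maximum(ref_sh, 1e-12)
            dd = (pred_part - ref_sh) / local_tol
        cand = dd**2 + dist_term
        view = gamma_sq[dst]
        np.minimum(view, cand, out=view)

    gamma_map = np.sqrt(gamma_sq)
    eval_mask = dr >= criteria.dose_cutoff_percent / 100.0 * ref_max
    n_eval = int(eval_mask.sum())
    if n_eval == 0:
        pass_rate = 100.0
    else:
        pass_rate = 100.0 * float(np.mean(gamma_map[eval_mask] <= 1.0 + 1e-9))
    return GammaResult(gamma_map=gamma_map, pass_rate=pass_rate, n_evaluated=n_eval)


def compute_dvh(
    dose: ArrayLike,
    mask: Optional[np.ndarray] = None,
    bin_width_gy: float = 0.1,
) -> DVHCurve:
    """Cumulative DVH for the voxels in ``mask`` (whole grid by default)."""
    d, _ = _dose_and_spacing(dose)
    if mask is None:
        mask = np.ones(d.shape, dtype=bool)
    vals = d[mask]
    if vals.size == 0:
        raise ValueError("structure mask is empty")
    top = max(float(vals.max()), bin_width_gy)
    bins = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    # percent of structure receiving at least each bin dose
    volume = 100.0 * np.array([(vals >= b).mean() if b > 0 else 1.0 for b in bins])
    return DVHCurve(dose_bins=bins, relative_volume=volume, structure_voxels=int(vals.size))


def dice_isodose(doseA: ArrayLike, doseB: ArrayLike, threshold: float) -> float:
    """Dice overlap of the two supra-threshold isodose volumes.

    Both-empty convention: 1.0 (perfect agreement on 'nothing above dose').
    """
    da, db, _ = _check_grids(doseA, doseB)
    a = da >= threshold
    b = db >= threshold
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _boundary_points_mm(mask: np.ndarray, spacing) -> np.ndarray:
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    return pts * np.asarray(spacing)[None, :]


def hausdorff_isodose(
    doseA: ArrayLike, doseB: ArrayLike, threshold: float, spacing=None
) -> float:
    """Classical (max-min) symmetric Hausdorff distance, in mm, between the
    boundary voxel centers of the two supra-threshold isodose volumes."""
    da, db, sp = _check_grids(doseA, doseB, spacing)
    a = da >= threshold
    b = db >= threshold
    if not a.any() or not b.any():
        raise ValueError("both isodose volumes must be nonempty for a Hausdorff distance")
    pa = _boundary_points_mm(a, sp)
    pb = _boundary_points_mm(b, sp)
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab = tb.query(pa)[0].max()
    d_ba = ta.query(pb)[0].max()
    return float(max(d_ab, d_ba))
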