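"""Classical radiation transport: Monte Carlo photon histories and a
discrete-ordinates discretization of the steady-state, single-group
Boltzmann transport equation assembled as a sparse linear system ``A f = b``.

The deterministic solve is the ground-truth oracle for the quantum linear
solver; the analog Monte Carlo keeps exact energy bookkeeping
(emitted = absorbed + escaped) and is the stochastic cross-check.

Physics model
-------------
Steady-state, mono-energetic photon transport in a heterogeneous voxel
medium. Streaming is discretized with first-order upwind differences on the
voxel grid, angle with a discrete-ordinates set whose quadrature weights sum
to 4*pi, and scattering with a Henyey-Greenstein phase function of
anisotropy ``g`` (g = 0 is isotropic). Boundaries are vacuum unless an
inflow is prescribed (external beams enter as boundary inflow on the entry
face).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantoms import Phantom, SourceModel

__all__ = [
    "MediumProperties",
    "TransportSystem",
    "FluxField",
    "DoseGrid",
    "DEFAULT_MATERIALS",
    "build_media",
    "make_ordinates",
    "build_transport_system",
    "solve_classical",
    "run_monte_carlo",
    "flux_to_dose",
    "estimate_condition_number",
]

#: label -> (mu_t [1/mm], mu_s [1/mm], g) at unit relative electron density.
#: Magnitudes are in the range of megavoltage photon attenuation in tissue.
DEFAULT_MATERIALS: dict[int, tuple[float, float, float]] = {
    0: (0.005, 0.0025, 0.0),   # water-like soft tissue
    1: (0.007, 0.0035, 0.0),   # denser tissue / bone surrogate
    2: (0.0015, 0.00075, 0.0),  # lung-like low density
}


@dataclass
class MediumProperties:
    """Voxelwise interaction coefficients (1/mm) and scattering anisotropy."""

    mu_t: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.mu_t = np.asarray(self.mu_t, dtype=np.float64)
        self.mu_s = np.asarray(self.mu_s, dtype=np.float64)
        self.g = np.asarray(self.g, dtype=np.float64)
        if np.any(self.mu_s < 0) or np.any(self.mu_s > self.mu_t + 1e-15):
            raise ValueError("require 0 <= mu_s <= mu_t voxelwise")
        if np.any(np.abs(self.g) > 1):
            raise ValueError("anisotropy |g| must be <= 1")

    @property
    def mu_a(self) -> np.ndarray:
        """Absorption coefficient mu_t - mu_s (1/mm)."""
        return self.mu_t - self.mu_s


@dataclass
class TransportSystem:
    """Sparse linear system over voxel x ordinate unknowns.

    Unknown ordering: index = m * n_voxels + (z * ny + y) * nx + x for
    ordinate m. ``s`` is the true max number of nonzeros in any row of A;
    ``kappa`` a 2-norm condition number estimate.
    """

    A: sp.csr_matrix
    b: np.ndarray
    ordinates: np.ndarray          # (M, 3) unit direction vectors (z, y, x)
    weights: np.ndarray            # (M,) quadrature weights summing to 4*pi
    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    s: int = 0
    kappa: float = float("nan")

    def __post_init__(self) -> None:
        n = self.A.shape[0]
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if self.b.shape[0] != n:
            raise ValueError("b length must equal A dimension")
        if abs(self.weights.sum() - 4 * np.pi) > 1e-9:
            raise ValueError("quadrature weights must sum to 4*pi")

    @property
    def dimension(self) -> int:
        return self.A.shape[0]

    def to_matrix_market(self, path: str) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.A)


@dataclass
class FluxField:
    """Angular flux per ordinate and voxel, plus the scalar (weighted) flux."""

    values: np.ndarray       # (M, nz, ny, nx)
    scalar_flux: np.ndarray  # (nz, ny, nx)
    residual: float = 0.0


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose in Gy with optional MC uncertainty."""

    dose: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stat_uncertainty: Optional[np.ndarray] = None
    normalization: float = float("nan")
    energy_emitted: float = float("nan")
    energy_absorbed: float = float("nan")
    energy_escaped: float = float("nan")

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if np.any(self.dose < -1e-12):
            raise ValueError("dose must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dose.shape  # type: ignore[return-value]

    def write_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag(list(self.spacing[::-1]) + [1.0])
        img = nib.Nifti1Image(self.dose.transpose(2, 1, 0).astype(np.float32), affine)
        nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def build_media(
    phantom: Phantom,
    material_table: Mapping[int, tuple[float, float, float]] = DEFAULT_MATERIALS,
) -> MediumProperties:
    """Map tissue labels to interaction coefficients, scaled by density.

    The table gives (mu_t, mu_s, g) per label at unit relative electron
    density; mu_t and mu_s scale linearly with the voxel's density (Compton
    dominance at megavoltage energies), g does not.
    """
    labels = phantom.labels
    present = np.unique(labels)
    for lab in present:
        if int(lab) not in material_table:
            raise KeyError(f"material table has no entry for label {int(lab)}")
        mu_t, mu_s, g = material_table[int(lab)]
        if not (0 <= mu_s <= mu_t):
            raise ValueError(f"label {int(lab)}: require 0 <= mu_s <= mu_t")
        if abs(g) > 1:
            raise ValueError(f"label {int(lab)}: |g| must be <= 1")
    mu_t = np.zeros(phantom.shape)
    mu_s = np.zeros(phantom.shape)
    g = np.zeros(phantom.shape)
    for lab in present:
        m = labels == lab
        t, s_, gg = material_table[int(lab)]
        mu_t[m] = t
        mu_s[m] = s_
        g[m] = gg
    mu_t = mu_t * phantom.density
    mu_s = mu_s * phantom.density
    return MediumProperties(mu_t=mu_t, mu_s=mu_s, g=g)


# ---------------------------------------------------------------------------
# Ordinates
# ---------------------------------------------------------------------------

def make_ordinates(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-weight direction set; weights sum to 4*pi.

    n = 1 gives +z (useful for collimated slab problems); n <= 6 gives the
    +/- coordinate axes; larger n a Fibonacci-sphere design.
    """
    if n < 1:
        raise ValueError("n_ordinates must be >= 1")
    if n == 1:
        dirs = np.array([[1.0, 0.0, 0.0]])
    elif n <= 6:
        axes = np.array(
            [
                [1.0, 0, 0], [-1.0, 0, 0],
                [0, 1.0, 0], [0, -1.0, 0],
                [0, 0, 1.0], [0, 0, -1.0],
            ]
        )
        dirs = axes[:n]
    else:
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        golden = np.pi * (1 + 5 ** 0.5)
        theta = golden * i
        dirs = np.stack(
            [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)],
            axis=1,
        )
    weights = np.full(len(dirs), 4 * np.pi / len(dirs))
    return dirs, weights


def henyey_greenstein_pdf(cos_theta: np.ndarray, g: float) -> np.ndarray:
    """HG phase function p(cos) normalized over solid angle (integrates to 1)."""
    if abs(g) < 1e-12:
        return np.full_like(np.asarray(cos_theta, dtype=float), 1.0 / (4 * np.pi))
    return (1 - g**2) / (4 * np.pi * (1 + g**2 - 2 * g * cos_theta) ** 1.5)


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

def build_transport_system(
    phantom: Phantom,
    media: MediumProperties,
    source: Optional[SourceModel] = None,
    n_ordinates: int = 6,
    dim_cap: int = 40000,
    angular_source: Optional[np.ndarray] = None,
    inflow: Optional[np.ndarray] = None,
    estimate_kappa: bool = True,
) -> TransportSystem:
    """Assemble the upwind discrete-ordinates system ``A f = b``.

    Streaming uses first-order upwind differences with vacuum boundaries;
    collision adds ``mu_t`` on the diagonal; in-scatter couples ordinates via
    the HG phase matrix and the quadrature weights. ``angular_source`` (per
    voxel) or ``inflow`` (per ordinate and voxel, applied at upwind
    boundaries) may override/augment the :class:`SourceModel`.

    The reported sparsity ``s`` is the exact max nonzeros per row; ``kappa``
    is estimated by power iteration on ``A^T A`` and its inverse action
    (exact dense SVD for dimensions <= 64).
    """
    if media.mu_t.shape != phantom.shape:
        raise ValueError("media and phantom shapes must match")
    dirs, weights = make_ordinates(n_ordinates)
    M = len(dirs)
    nz, ny, nx = phantom.shape
    nvox = nz * ny * nx
    dim = M * nvox
    if dim > dim_cap:
        raise ValueError(
            f"system dimension {dim} exceeds the desk-scale cap {dim_cap}; "
            "reduce grid size or ordinate count, or raise dim_cap"
        )
    spacing = phantom.spacing

    mu_t_flat = media.mu_t.ravel()
    mu_s_flat = media.mu_s.ravel()
    g_scalar = float(np.mean(media.g))  # single anisotropy for the phase matrix

    # phase matrix: row m' (incoming) -> column m (outgoing), renormalized so
    # each incoming ordinate redistributes exactly unit probability
    cosmat = dirs @ dirs.T
    P = henyey_greenstein_pdf(cosmat, g_scalar)
    row_sums = (P * weights[None, :]).sum(axis=1)
    P = P / row_sums[:, None]  # now sum_m w_m P[m', m] = 1

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = np.zeros(dim)

    idx3 = np.arange(nvox).reshape(nz, ny, nx)

    if angular_source is not None:
        q_ang = np.broadcast_to(np.asarray(angular_source, dtype=float), phantom.shape)
        for m in range(M):
            b[m * nvox:(m + 1) * nvox] += q_ang.ravel()

    if inflow is None:
        inflow_arr = None
    else:
        inflow_arr = np.asarray(inflow, dtype=float).reshape(M, nz, ny, nx)

    if source is not None:
        if source.modality == "brachy_seed":
            pos = np.asarray(source.geometry["position_mm"], dtype=float)
            vox = np.round((pos - np.asarray(phantom.origin)) / np.asarray(spacing)).astype(int)
            vox = np.clip(vox, 0, np.asarray(phantom.shape) - 1)
            v = idx3[tuple(vox)]
            q = source.emission_strength / (4 * np.pi * phantom.voxel_volume_mm3)
            for m in range(M):
                b[m * nvox + v] += q
        else:  # external beam -> boundary inflow on the ordinate nearest the beam
            beam_dir = np.asarray(source.geometry["direction"], dtype=float)
            m_beam = int(np.argmax(dirs @ beam_dir))
            beam_inflow = np.zeros((M, nz, ny, nx))
            _fill_beam_inflow(beam_inflow[m_beam], dirs[m_beam], phantom, source)
            inflow_arr = beam_inflow if inflow_arr is None else inflow_arr + beam_inflow

    for m in range(M):
        off = m * nvox
        diag = mu_t_flat.copy()
        for axis in range(3):
            mu = dirs[m, axis]
            if abs(mu) < 1e-14:
                continue
            h = spacing[axis]
            diag += abs(mu) / h
            # upwind neighbor coupling
            sl_to = [slice(None)] * 3
            sl_from = [slice(None)] * 3
            if mu > 0:
                sl_to[axis] = slice(1, None)
                sl_from[axis] = slice(0, -1)
            else:
                sl_to[axis] = slice(0, -1)
                sl_from[axis] = slice(1, None)
            r = idx3[tuple(sl_to)].ravel()
            c = idx3[tuple(sl_from)].ravel()
            rows.append(off + r)
            cols.append(off + c)
            vals.append(np.full(r.size, -abs(mu) / h))
            # inflow through the upwind boundary face
            if inflow_arr is not None:
                sl_b = [slice(None)] * 3
                sl_b[axis] = 0 if mu > 0 else -1
                vb = idx3[tuple(sl_b)].ravel()
                fin = inflow_arr[m][tuple(sl_b)].ravel()
                b[off + vb] += (abs(mu) / h) * fin
        rows.append(off + np.arange(nvox))
        cols.append(off + np.arange(nvox))
        vals.append(diag)
        # in-scatter coupling from every ordinate m'
        for mp in range(M):
            coef = -mu_s_flat * weights[mp] * P[mp, m]
            nzmask = np.abs(coef) > 0
            if not nzmask.any():
                continue
            v = np.arange(nvox)[nzmask]
            rows.append(off + v)
            cols.append(mp * nvox + v)
            vals.append(coef[nzmask])

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(dim, dim),
    )
    A.sum_duplicates()
    A.eliminate_zeros()
    s = int(np.diff(A.indptr).max())
    kappa = estimate_condition_number(A) if estimate_kappa else float("nan")
    return TransportSystem(
        A=A, b=b, ordinates=dirs, weights=weights,
        grid_shape=phantom.shape, spacing=spacing, s=s, kappa=kappa,
    )


def _fill_beam_inflow(target: np.ndarray, direction: np.ndarray, phantom: Phantom, source: SourceModel) -> None:
    """Set unit angular-flux inflow within the field on the beam entry face."""
    axis = int(np.argmax(np.abs(direction)))
    half = source.geometry["field_size_mm"] / 2.0
    centers = phantom.voxel_centers_mm()
    mid = phantom.center_mm()
    other = [a for a in range(3) if a != axis]
    c0 = centers[other[0]] - mid[other[0]]
    c1 = centers[other[1]] - mid[other[1]]
    mask2 = (np.abs(c0)[:, None] <= half) & (np.abs(c1)[None, :] <= half)
    sl = [slice(None)] * 3
    sl[axis] = 0 if direction[axis] > 0 else -1
    # the sliced face keeps the two non-beam axes in original order
    target[tuple(sl)][mask2] = source.emission_strength


# ---------------------------------------------------------------------------
# Condition number
# ---------------------------------------------------------------------------

def estimate_condition_number(
    A: sp.spmatrix, n_iter: int = 200, tol: float = 1e-9, seed: int = 0
) -> float:
    """2-norm condition number via power iteration on ``A^T A`` and its
    inverse action (LU-solves). Exact dense SVD for dimension <= 64."""
    n = A.shape[0]
    if n <= 64:
        sv = np.linalg.svd(A.toarray(), compute_uv=False)
        if sv[-1] <= 0:
            return float("inf")
        return float(sv[0] / sv[-1])
    rng = np.random.default_rng(seed)
    Acsc = A.tocsc()
    At = Acsc.T

    def power(matvec) -> float:
        x = rng.standard_normal(n)
        x /= np.linalg.norm(x)
        lam = 0.0
        for _ in range(n_iter):
            y = matvec(x)
            ny = np.linalg.norm(y)
            if ny == 0:
                return 0.0
            x_new = y / ny
            if abs(ny - lam) <= tol * max(ny, 1.0):
                lam = ny
                break
            lam, x = ny, x_new
        return lam

    sig_max_sq = power(lambda v: At @ (Acsc @ v))
    try:
        lu = spla.splu(Acsc)
    except RuntimeError as exc:
        raise np.linalg.LinAlgError(f"singular transport matrix: {exc}") from exc
    inv_sq = power(lambda v: lu.solve(lu.solve(v), trans="T"))
    if inv_sq == 0:
        return float("inf")
    return float(np.sqrt(sig_max_sq * inv_sq))


# ---------------------------------------------------------------------------
# Deterministic solve
# ---------------------------------------------------------------------------

def solve_classical(system: TransportSystem, residual_tol: float = 1e-8) -> FluxField:
    """Direct sparse solve of ``A f = b`` (ground-truth oracle).

    Raises on a singular matrix; the relative residual is checked against
    ``residual_tol``.
    """
    try:
        f = spla.spsolve(system.A.tocsc(), system.b)
    except RuntimeError as exc:
        raise np.linalg.LinAlgError(
            f"singular transport matrix (kappa estimate {system.kappa:.3g}): {exc}"
        ) from exc
    if not np.all(np.isfinite(f)):
        raise np.linalg.LinAlgError(
            f"non-finite solution; system is singular (kappa estimate {system.kappa:.3g})"
        )
    bnorm = np.linalg.norm(system.b)
    resid = float(np.linalg.norm(system.A @ f - system.b) / (bnorm if bnorm > 0 else 1.0))
    if resid > residual_tol:
        raise np.linalg.LinAlgError(f"solver residual {resid:.3g} exceeds {residual_tol:.3g}")
    M = len(system.weights)
    values = f.reshape(M, *system.grid_shape)
    scalar = np.tensordot(system.weights, values, axes=(0, 0))
    return FluxField(values=values, scalar_flux=scalar, residual=resid)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

def run_monte_carlo(
    phantom: Phantom,
    media: MediumProperties,
    source: SourceModel,
    n_particles: int = 10_000,
    seed: int = 0,
    n_batches: int = 10,
    reference_mask: Optional[np.ndarray] = None,
) -> DoseGrid:
    """Analog Monte Carlo photon transport with Woodcock (delta) tracking.

    Free paths are sampled from the exponential with the grid-maximum
    attenuation; at candidate sites a real interaction occurs with
    probability ``mu_t/mu_max``, resolving to absorption (full local energy
    deposit) with probability ``mu_a/mu_t`` or a Henyey-Greenstein scatter.
    Energy bookkeeping is exact: emitted = absorbed + escaped. Per-voxel
    1-sigma statistical uncertainty comes from batch statistics. The dose is
    normalized so the reference receives the prescription dose — the
    maximum-dose voxel by default, or the mean over ``reference_mask``
    (a mask average is the robust choice for noisy tallies).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    mu_max = float(media.mu_t.max())
    if mu_max <= 0:
        raise ValueError("mu_t is zero everywhere: infinite free path for an internal source")
    rng = np.random.default_rng(seed)
    nz, ny, nx = phantom.shape
    spacing = np.asarray(phantom.spacing)
    origin = np.asarray(phantom.origin)
    lo = origin - 0.5 * spacing
    hi = origin + (np.asarray(phantom.shape) - 0.5) * spacing

    n_batches = min(n_batches, n_particles)
    counts = np.full(n_batches, n_particles // n_batches)
    counts[: n_particles % n_batches] += 1

    e_dep_batches = np.zeros((n_batches, nz, ny, nx))
    e_escaped = 0.0
    e_emitted = 0.0
    e_particle = source.emission_strength / n_particles

    for bi, nb in enumerate(counts):
        nb = int(nb)
        if nb == 0:
            continue
        pos, dirn = _sample_source(phantom, source, nb, rng)
        energy = np.full(nb, e_particle)
        e_emitted += energy.sum()
        alive = np.ones(nb, dtype=bool)
        dep = e_dep_batches[bi]
        g_arr = media.g
        while alive.any():
            ia = np.flatnonzero(alive)
            step = -np.log(rng.random(ia.size)) / mu_max
            pos[ia] += dirn[ia] * step[:, None]
            out = np.any((pos[ia] < lo) | (pos[ia] >= hi), axis=1)
            esc = ia[out]
            e_escaped += energy[esc].sum()
            alive[esc] = False
            ia = ia[~out]
            if ia.size == 0:
                break
            vox = np.floor((pos[ia] - lo) / spacing).astype(int)
            vz, vy, vx = vox[:, 0], vox[:, 1], vox[:, 2]
            mu_t_here = media.mu_t[vz, vy, vx]
            real = rng.random(ia.size) < mu_t_here / mu_max
            ir = ia[real]
            if ir.size == 0:
                continue
            vzr, vyr, vxr = vz[real], vy[real], vx[real]
            mu_t_r = mu_t_here[real]
            mu_s_r = media.mu_s[vzr, vyr, vxr]
            absorb = rng.random(ir.size) >= mu_s_r / np.maximum(mu_t_r, 1e-300)
            iabs = ir[absorb]
            np.add.at(dep, (vzr[absorb], vyr[absorb], vxr[absorb]), energy[iabs])
            alive[iabs] = False
            isc = ir[~absorb]
            if isc.size:
                g_here = g_arr[vzr[~absorb], vyr[~absorb], vxr[~absorb]]
                dirn[isc] = _hg_scatter(dirn[isc], g_here, rng)

    e_absorbed = float(e_dep_batches.sum())
    # per-voxel dose in energy per unit mass (relative density as mass proxy)
    mass = np.maximum(phantom.density, 1e-12) * phantom.voxel_volume_mm3
    dose_batches = e_dep_batches / mass[None]
    dose_raw = dose_batches.sum(axis=0)
    # batch estimate of the standard error of the total
    batch_means = dose_batches * n_batches  # scale each batch to full-run estimate
    sigma_raw = batch_means.std(axis=0, ddof=1) / np.sqrt(n_batches) if n_batches > 1 else np.zeros_like(dose_raw)

    scale = _normalization_scale(dose_raw, source.prescription_dose, reference_mask)
    return DoseGrid(
        dose=dose_raw * scale,
        spacing=phantom.spacing,
        stat_uncertainty=sigma_raw * scale,
        normalization=source.prescription_dose,
        energy_emitted=float(e_emitted),
        energy_absorbed=e_absorbed,
        energy_escaped=float(e_escaped),
    )


def _sample_source(
    phantom: Phantom, source: SourceModel, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.asarray(phantom.spacing)
    origin = np.asarray(phantom.origin)
    lo = origin - 0.5 * spacing
    if source.modality == "brachy_seed":
        pos = np.tile(np.asarray(source.geometry["position_mm"], dtype=float), (n, 1))
        # isotropic directions
        u = 1 - 2 * rng.random(n)
        phi = 2 * np.pi * rng.random(n)
        st = np.sqrt(1 - u**2)
        dirn = np.stack([u, st * np.sin(phi), st * np.cos(phi)], axis=1)
        return pos, dirn
    beam_dir = np.asarray(source.geometry["direction"], dtype=float)
    axis = int(np.argmax(np.abs(beam_dir)))
    half = source.geometry["field_size_mm"] / 2.0
    mid = np.asarray(phantom.center_mm())
    pos = np.empty((n, 3))
    for a in range(3):
        if a == axis:
            ext = lo[a] if beam_dir[axis] > 0 else lo[a] + phantom.shape[a] * spacing[a]
            pos[:, a] = ext + (1e-9 if beam_dir[axis] > 0 else -1e-9)
        else:
            pos[:, a] = mid[a] + (rng.random(n) * 2 - 1) * half
    dirn = np.tile(beam_dir / np.linalg.norm(beam_dir), (n, 1))
    return pos, dirn


def _hg_scatter(dirn: np.ndarray, g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample new directions from the HG phase function about ``dirn``."""
    n = dirn.shape[0]
    u = rng.random(n)
    g = np.asarray(g, dtype=float)
    iso = np.abs(g) < 1e-12
    cos_t = np.empty(n)
    cos_t[iso] = 1 - 2 * u[iso]
    ga = g[~iso]
    if ga.size:
        frac = (1 - ga**2) / (1 - ga + 2 * ga * u[~iso])
        cos_t[~iso] = (1 + ga**2 - frac**2) / (2 * ga)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.sqrt(1 - cos_t**2)
    phi = 2 * np.pi * rng.random(n)
    # local frame around the current direction
    w = dirn
    a = np.where(np.abs(w[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]])
    uvec = np.cross(a, w)
    uvec /= np.linalg.norm(uvec, axis=1, keepdims=True)
    vvec = np.cross(w, uvec)
    return (
        cos_t[:, None] * w
        + (sin_t * np.cos(phi))[:, None] * uvec
        + (sin_t * np.sin(phi))[:, None] * vvec
    )


# ---------------------------------------------------------------------------
# Flux -> dose
# ---------------------------------------------------------------------------

def _normalization_scale(dose_raw: np.ndarray, prescription: float, mask: Optional[np.ndarray] = None) -> float:
    ref = dose_raw[mask].mean() if mask is not None else dose_raw.max()
    if ref <= 0:
        raise ValueError("zero dose at the normalization reference with nonzero prescription")
    return prescription / ref


def flux_to_dose(
    flux: FluxField,
    media: MediumProperties,
    normalization: float = 2.0,
    density: Optional[np.ndarray] = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    reference_mask: Optional[np.ndarray] = None,
) -> DoseGrid:
    """Convert scalar flux to absorbed dose.

    Unnormalized dose is ``mu_a * scalar_flux`` (energy deposited per unit
    volume), divided by the relative density when given (per unit mass); the
    result is rescaled so the reference (max-dose voxel by default, or the
    mean over ``reference_mask``) receives the prescription dose.
    """
    if flux.scalar_flux.shape != media.mu_t.shape:
        raise ValueError("flux and media shapes must match")
    raw = media.mu_a * flux.scalar_flux
    if density is not None:
        raw = raw / np.maximum(density, 1e-12)
    scale = _normalization_scale(raw, normalization, reference_mask)
    return DoseGrid(
        dose=np.clip(raw * scale, 0, None),
        spacing=spacing,
        normalization=normalization,
    )
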