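"""Synthetic voxel phantoms, HU-to-electron-density conversion and source models.

Grid convention: axis order (z, y, x), 0-based voxel indices, physical
position of a voxel center = ``origin + index * spacing``; all distances in
millimetres, doses in gray. Relative electron density is unitless with
water = 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Phantom",
    "PhantomSpec",
    "SourceModel",
    "DEFAULT_HU_TABLE",
    "generate_phantom",
    "hu_to_density",
    "make_source",
    "read_volume",
    "write_volume",
]

#: Piecewise-linear HU -> relative electron density calibration.
#: Anchored at the air (-1000 HU) and water (0 HU) conventions of CT
#: calibration; the two supra-water points give soft-tissue/bone slopes.
DEFAULT_HU_TABLE: tuple[tuple[float, float], ...] = (
    (-1000.0, 0.001),
    (0.0, 1.0),
    (1000.0, 1.1),
    (2000.0, 1.5),
)


@dataclass
class Phantom:
    """A voxelized patient model.

    Attributes
    ----------
    density
        3D grid of relative electron density (water = 1.0), axis order (z, y, x).
    labels
        3D integer grid of tissue-class labels, same shape as ``density``.
    spacing
        Per-axis voxel size in mm, ordered (z, y, x).
    origin
        Physical coordinate (mm) of the center of voxel (0, 0, 0).
    """

    density: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.density.ndim != 3:
            raise ValueError("density grid must be 3D (z, y, x)")
        if self.labels.shape != self.density.shape:
            raise ValueError("labels and density grids must share one shape")
        if np.any(self.density < 0):
            raise ValueError("density must be >= 0 everywhere")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0 on each axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def center_mm(self) -> tuple[float, float, float]:
        """Physical coordinate of the grid center (mm)."""
        return tuple(
            self.origin[a] + (self.shape[a] - 1) / 2.0 * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class PhantomSpec:
    """Recipe for a seeded synthetic phantom.

    ``pattern`` is one of ``uniform`` (single tissue), ``slab`` (stacked
    layers along z) or ``concentric`` (nested shells around the grid center,
    emulating concentric tissue-density variations). ``tissue_densities`` is
    an ordered list of ``(label, density)`` pairs, innermost/bottom first.
    """

    shape: tuple[int, int, int]
    pattern: str = "uniform"
    tissue_densities: Sequence[tuple[int, float]] = ((0, 1.0),)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        for axis, n in zip("zyx", self.shape):
            if n < 1:
                raise ValueError(f"shape must be >= 1 on axis {axis!r}, got {n}")
        if self.pattern not in ("uniform", "slab", "concentric"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not self.tissue_densities:
            raise ValueError("tissue_densities must be non-empty")
        for label, dens in self.tissue_densities:
            if dens < 0:
                raise ValueError(f"density for label {label} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SourceModel:
    """A radiation source: external beam or brachytherapy seed.

    For ``external_beam`` the geometry is a unit beam direction plus a square
    field size (mm); for ``brachy_seed`` it is the seed position (mm).
    The spectrum is mono-group: ``nominal_energy`` is a label ("6 MV",
    "Ir-192") kept as an extension point for polyenergetic physics.
    """

    modality: str
    nominal_energy: str
    geometry: dict
    emission_strength: float = 1.0
    prescription_dose: float = 2.0

    def __post_init__(self) -> None:
        if self.modality not in ("external_beam", "brachy_seed"):
            raise ValueError(
                f"unknown modality {self.modality!r}; supported: "
                "external_beam, brachy_seed"
            )
        if self.emission_strength <= 0:
            raise ValueError("emission_strength must be > 0")
        if self.modality == "external_beam":
            d = np.asarray(self.geometry["direction"], dtype=float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ValueError("beam direction must be nonzero")
            self.geometry["direction"] = tuple(d / n)
            if self.geometry.get("field_size_mm", 1.0) <= 0:
                raise ValueError("field size must be > 0")


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a seeded synthetic phantom from a :class:`PhantomSpec`.

    Deterministic: the same spec (including seed) yields bit-identical grids.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int32)
    density = np.zeros(spec.shape, dtype=np.float64)
    pairs = list(spec.tissue_densities)

    if spec.pattern == "uniform":
        label0, dens0 = pairs[0]
        labels[...] = label0
        density[...] = dens0
    elif spec.pattern == "slab":
        # stacked layers along z, equal thickness
        edges = np.linspace(0, nz, len(pairs) + 1).round().astype(int)
        for (label, dens), lo, hi in zip(pairs, edges[:-1], edges[1:]):
            labels[lo:hi] = label
            density[lo:hi] = dens
    else:  # concentric shells around the grid center
        zz, yy, xx = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        c = [(n - 1) / 2.0 for n in spec.shape]
        # normalized radius so shells scale with the grid
        r = np.sqrt(
            ((zz - c[0]) / max(nz / 2.0, 1)) ** 2
            + ((yy - c[1]) / max(ny / 2.0, 1)) ** 2
            + ((xx - c[2]) / max(nx / 2.0, 1)) ** 2
        )
        edges = np.linspace(0, 1.0, len(pairs) + 1)[1:]
        labels[...] = pairs[-1][0]
        density[...] = pairs[-1][1]
        for (label, dens), hi in zip(pairs[::-1], edges[::-1]):
            inside = r <= hi
            labels[inside] = label
            density[inside] = dens

    if spec.noise_sd > 0:
        density = np.clip(density + rng.normal(0, spec.noise_sd, spec.shape), 0, None)

    return Phantom(density=density, labels=labels, spacing=spec.spacing, origin=spec.origin)


# ---------------------------------------------------------------------------
# HU calibration
# ---------------------------------------------------------------------------

def hu_to_density(
    hu_volume: np.ndarray,
    table: Sequence[tuple[float, float]] = DEFAULT_HU_TABLE,
) -> np.ndarray:
    """Convert a Hounsfield-unit volume to relative electron density.

    Piecewise-linear interpolation of ``table`` (monotone HU breakpoints),
    flat extrapolation beyond the table ends, clipped at zero.
    """
    table = list(table)
    if len(table) < 2:
        raise ValueError("calibration table needs >= 2 breakpoints")
    hu_pts = np.asarray([p[0] for p in table], dtype=float)
    rho_pts = np.asarray([p[1] for p in table], dtype=float)
    if np.any(np.diff(hu_pts) <= 0):
        raise ValueError("calibration table HU breakpoints must be strictly increasing")
    out = np.interp(np.asarray(hu_volume, dtype=float), hu_pts, rho_pts)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Source construction
# ---------------------------------------------------------------------------

_SOURCE_DEFAULTS = {
    "external_beam": {
        "nominal_energy": "6 MV",
        "direction": (1.0, 0.0, 0.0),  # +z in (z, y, x) order
        "field_size_mm": 50.0,
    },
    "brachy_seed": {
        "nominal_energy": "Ir-192",
        "position_mm": (0.0, 0.0, 0.0),
    },
}


def make_source(config: Mapping) -> SourceModel:
    """Build a :class:`SourceModel` from a mapping, filling defaults.

    All effective values (including defaults) are echoed in the returned
    model so a run manifest can replay it.
    """
    cfg = dict(config)
    modality = cfg.pop("modality", None)
    if modality not in _SOURCE_DEFAULTS:
        raise ValueError(
            f"unknown modality {modality!r}; supported modalities: "
            + ", ".join(sorted(_SOURCE_DEFAULTS))
        )
    defaults = dict(_SOURCE_DEFAULTS[modality])
    nominal_energy = cfg.pop("nominal_energy", defaults["nominal_energy"])
    emission_strength = float(cfg.pop("emission_strength", 1.0))
    prescription_dose = float(cfg.pop("prescription_dose", 2.0))
    if modality == "external_beam":
        geometry = {
            "direction": tuple(cfg.pop("direction", defaults["direction"])),
            "field_size_mm": float(cfg.pop("field_size_mm", defaults["field_size_mm"])),
        }
    else:
        geometry = {"position_mm": tuple(cfg.pop("position_mm", defaults["position_mm"]))}
    if cfg:
        raise ValueError(f"unrecognized source config keys: {sorted(cfg)}")
    return SourceModel(
        modality=modality,
        nominal_energy=nominal_energy,
        geometry=geometry,
        emission_strength=emission_strength,
        prescription_dose=prescription_dose,
    )


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def write_volume(phantom: Phantom, path: str) -> None:
    """Write a phantom to disk.

    ``.nii``/``.nii.gz`` stores the density grid as NIfTI (spacing/origin in
    the affine; labels not preserved). ``.npz`` stores the full phantom
    (density, labels, spacing, origin) in the native container.
    """
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        # NIfTI is (x, y, z); our grids are (z, y, x)
        affine = np.diag(list(phantom.spacing[::-1]) + [1.0])
        affine[:3, 3] = phantom.origin[::-1]
        img = nib.Nifti1Image(
            np.asarray(phantom.density.transpose(2, 1, 0), dtype=np.float32), affine
        )
        nib.save(img, path)
    elif path.endswith(".npz"):
        np.savez_compressed(
            path,
            density=phantom.density,
            labels=phantom.labels,
            spacing=np.asarray(phantom.spacing, dtype=np.float64),
            origin=np.asarray(phantom.origin, dtype=np.float64),
        )
    else:
        raise ValueError(f"unsupported volume format for {path!r} (use .nii/.nii.gz/.npz)")


def read_volume(path: str) -> Phantom:
    """Read a phantom written by :func:`write_volume`."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValueError(f"malformed NIfTI header: non-positive pixdim {zooms}")
        data = np.asanyarray(img.dataobj).astype(np.float64)
        origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
        density = data.transpose(2, 1, 0)
        return Phantom(
            density=density,
            labels=np.zeros(density.shape, dtype=np.int32),
            spacing=tuple(float(z) for z in zooms[::-1]),
            origin=origin,
        )
    if path.endswith(".npz"):
        with np.load(path) as z:
            for key in ("density", "labels", "spacing", "origin"):
                if key not in z:
                    raise ValueError(f"malformed phantom container: missing field {key!r}")
            spacing = tuple(float(s) for s in z["spacing"])
            if any(s <= 0 for s in spacing):
                raise ValueError(f"malformed phantom container: non-positive spacing {spacing}")
            return Phantom(
                density=z["density"].astype(np.float64),
                labels=z["labels"],
                spacing=spacing,
                origin=tuple(float(o) for o in z["origin"]),
            )
    raise ValueError(f"unsupported volume format for {path!r} (use .nii/.nii.gz/.npz)")
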