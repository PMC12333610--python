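"""Voxelized synthetic thoracic anatomy and auxiliary optimization structures.

The phantom is the geometry every downstream stage consumes: a regular
voxel grid carrying a relative-electron-density volume and a set of named
boolean structure masks (body, lungs, heart, spinal cord, CTV, PTV).  From
these, :func:`derive_auxiliary` builds the non-anatomical helper structures
used by the optimization template:

* ``ring``  — shell between a 0.3 cm and a 1.3 cm isotropic expansion of
  the PTV, used to enforce target conformity;
* ``nt``    — normal tissue: body minus the PTV expanded by 1.3 cm;
* ``sp0.3`` — spinal cord expanded by 0.3 cm (planning organ-at-risk
  volume for the cord);
* ``lung-ptv`` — lung tissue outside the PTV.

All masks are boolean on the dose grid; partial-volume effects are
ignored.  Coordinates are patient-like axes in mm: x = left, y =
posterior, z = superior, voxel centers, 0-based indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "GeometryError",
    "GridSpec",
    "Structure",
    "Phantom",
    "PhantomConfig",
    "volume_cc",
    "expand_mask",
    "build_phantom",
    "derive_auxiliary",
    "save_structures_nifti",
    "load_structure_nifti",
]

#: derived structure names produced by :func:`derive_auxiliary`
AUXILIARY_NAMES = ("ring", "nt", "sp0.3", "lung-ptv")

LUNG_DENSITY = 0.26  # relative electron density of inflated lung
SOFT_TISSUE_DENSITY = 1.0


class GeometryError(ValueError):
    """A structure does not fit the grid or violates a containment rule."""


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: counts per axis, mm spacing, mm origin of voxel (0,0,0) center."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape entries must be >= 1, got {self.shape}")
        if any(sp <= 0 for sp in self.spacing):
            raise ValueError(f"grid spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) center-coordinate arrays in mm."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij", sparse=True)

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (diagonal, for NIfTI export)."""
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class Structure:
    name: str
    mask: np.ndarray
    derived: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class Phantom:
    """Voxel grid + density + named structure masks."""

    grid: GridSpec
    density: np.ndarray
    structures: dict[str, Structure] = field(default_factory=dict)
    _cache: dict = field(default_factory=dict, repr=False)

    def mask(self, name: str) -> np.ndarray:
        if name not in self.structures:
            raise KeyError(f"phantom has no structure named {name!r}")
        return self.structures[name].mask

    def add_structure(self, name: str, mask: np.ndarray, derived: bool = False) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise GeometryError(
                f"structure {name!r} mask shape {mask.shape} does not match grid {self.grid.shape}"
            )
        self.structures[name] = Structure(name, mask, derived)
        self._cache.clear()

    def volume_cc(self, name: str) -> float:
        return volume_cc(self.mask(name), self.grid)

    def structure_doses(self, dose: np.ndarray, name: str) -> np.ndarray:
        """Doses of the voxels inside a structure, as a flat array."""
        return np.asarray(dose).reshape(self.grid.shape)[self.mask(name)]

    def distance_outside_mm(self, name: str) -> np.ndarray:
        """Euclidean distance (mm) from each voxel to the surface of a structure.

        Zero inside the structure; cached (used by dose-falloff objectives).
        """
        key = ("dist_out", name)
        if key not in self._cache:
            self._cache[key] = ndimage.distance_transform_edt(
                ~self.mask(name), sampling=self.grid.spacing
            )
        return self._cache[key]

    def centroid_mm(self, name: str) -> np.ndarray:
        idx = np.argwhere(self.mask(name))
        if idx.size == 0:
            raise GeometryError(f"structure {name!r} is empty")
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * np.asarray(self.grid.spacing)


def volume_cc(mask: np.ndarray, grid: GridSpec) -> float:
    """Volume of a boolean mask in cm^3 (voxel count times voxel volume, exactly)."""
    return int(np.count_nonzero(mask)) * grid.voxel_volume_cc


def expand_mask(mask: np.ndarray, margin_cm: float, grid: GridSpec) -> np.ndarray:
    """Isotropic Euclidean-distance expansion of a boolean mask by ``margin_cm``.

    A voxel belongs to the result iff its center lies within ``margin_cm``
    of some voxel of the input (distance-transform based, anisotropy-aware).
    ``margin_cm = 0`` returns the mask unchanged; negative margins are
    rejected (contraction is a different operation).
    """
    if margin_cm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_cm}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise GeometryError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    if margin_cm == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    return dist <= margin_cm * 10.0


# ---------------------------------------------------------------------------
# Phantom construction


@dataclass
class PhantomConfig:
    """Parameters of the synthetic thorax.

    Defaults target the cohort scale of conventionally fractionated NSCLC
    planning: a spherical tumor in the right lung sized so the digitized
    PTV (CTV + 5 mm) lands near 285 cm^3, combined lungs around 3.2 L of
    inflated tissue (the lungs OAR mask excludes the gross tumor, the usual
    protocol convention for lung DVH reporting), a roughly 690 cm^3 heart, and a
    5 mm-radius spinal cord.  The grid default is 4 mm isotropic so that a
    full optimization stays desk-scale; it is a knob, not a claim.
    """

    grid_shape: tuple[int, int, int] = (72, 56, 48)
    grid_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_semiaxes_mm: tuple[float, float] = (138.0, 98.0)
    lung_center_x_mm: float = 70.0
    lung_semiaxes_mm: tuple[float, float, float] = (58.0, 76.0, 95.0)
    heart_center_mm: tuple[float, float, float] = (-10.0, -20.0, -40.0)
    heart_semiaxes_mm: tuple[float, float, float] = (56.0, 46.0, 64.0)
    cord_center_y_mm: float = 75.0
    cord_radius_mm: float = 5.0
    tumor_center_mm: tuple[float, float, float] = (70.0, -10.0, 10.0)
    tumor_radius_mm: float = 37.5
    tumor_jitter_mm: float = 5.0
    ctv_to_ptv_margin_cm: float = 0.5
    lung_density: float = LUNG_DENSITY
    seed: int = 7

    def grid(self) -> GridSpec:
        shape = tuple(int(s) for s in self.grid_shape)
        spacing = tuple(float(s) for s in self.grid_spacing_mm)
        origin = tuple(-(n - 1) / 2.0 * sp for n, sp in zip(shape, spacing))
        return GridSpec(shape, spacing, origin)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        }
        return cls(**kwargs)


def _ellipsoid(grid: GridSpec, center, semiaxes) -> np.ndarray:
    x, y, z = grid.coordinate_grids()
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _elliptic_cylinder(grid: GridSpec, semiaxes_xy) -> np.ndarray:
    x, y, _ = grid.coordinate_grids()
    ax, ay = semiaxes_xy
    return np.broadcast_to((x / ax) ** 2 + (y / ay) ** 2 <= 1.0, grid.shape).copy()


def build_phantom(config: PhantomConfig | None = None, *, seed: int | None = None) -> Phantom:
    """Build the synthetic thorax phantom, including auxiliary structures.

    Deterministic for a fixed seed: the only randomness is a small uniform
    jitter of the tumor center (±``tumor_jitter_mm`` per axis), standing in
    for patient-to-patient variation in tumor position.

    Raises
    ------
    GeometryError
        If the tumor radius is non-positive, a structure exceeds the body
        or grid bounds, or the tumor centroid is not inside a lung.
    """
    config = config or PhantomConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    if config.tumor_radius_mm <= 0:
        raise GeometryError(f"tumor radius must be > 0, got {config.tumor_radius_mm}")

    grid = config.grid()
    rng = np.random.default_rng(config.seed)
    jitter = rng.uniform(-config.tumor_jitter_mm, config.tumor_jitter_mm, size=3)
    tumor_center = np.asarray(config.tumor_center_mm, dtype=float) + jitter

    body = _elliptic_cylinder(grid, config.body_semiaxes_mm)
    lung_r = _ellipsoid(grid, (config.lung_center_x_mm, 0.0, 0.0), config.lung_semiaxes_mm)
    lung_l = _ellipsoid(grid, (-config.lung_center_x_mm, 0.0, 0.0), config.lung_semiaxes_mm)
    heart = _ellipsoid(grid, config.heart_center_mm, config.heart_semiaxes_mm)
    x, y, _ = grid.coordinate_grids()
    cord = np.broadcast_to(
        x**2 + (y - config.cord_center_y_mm) ** 2 <= config.cord_radius_mm**2, grid.shape
    ).copy()
    ctv = _ellipsoid(grid, tumor_center, (config.tumor_radius_mm,) * 3)
    if not ctv.any():
        raise GeometryError("CTV rasterized to an empty mask; tumor outside the grid?")

    lung_tissue = (lung_r | lung_l) & ~heart
    ctv_centroid_idx = tuple(np.round((tumor_center - grid.origin) / grid.spacing).astype(int))
    if not (0 <= ctv_centroid_idx[0] < grid.shape[0] and lung_tissue[ctv_centroid_idx]):
        raise GeometryError("tumor centroid is not inside a lung")
    # lungs OAR per protocol convention: both lungs minus the gross tumor
    lungs = lung_tissue & ~ctv

    ptv = expand_mask(ctv, config.ctv_to_ptv_margin_cm, grid) & body

    phantom = Phantom(grid=grid, density=np.empty(grid.shape))
    phantom.add_structure("body", body)
    for name, mask in (
        ("lungs", lungs),
        ("heart", heart),
        ("spinal_cord", cord & body),
        ("ctv", ctv),
        ("ptv", ptv),
    ):
        clipped = mask & body
        if name != "ptv" and np.count_nonzero(mask & ~body):
            raise GeometryError(f"structure {name!r} exceeds the body outline")
        phantom.add_structure(name, clipped)

    density = np.zeros(grid.shape)  # air outside the body
    density[body] = SOFT_TISSUE_DENSITY
    density[phantom.mask("lungs")] = config.lung_density
    density[ctv] = SOFT_TISSUE_DENSITY  # solid tumor inside lung
    phantom.density = density

    return derive_auxiliary(phantom)


def derive_auxiliary(phantom: Phantom) -> Phantom:
    """Derive ring, nt, sp0.3 and lung-ptv from the anatomical structures.

    Idempotent: derived structures are recomputed from the anatomical ones,
    so calling this twice yields identical masks.  Emits a warning if the
    normal-tissue structure comes out empty (degenerate phantom).
    """
    for required in ("body", "ptv", "lungs", "spinal_cord"):
        if required not in phantom.structures:
            raise GeometryError(f"cannot derive auxiliary structures: missing {required!r}")

    grid = phantom.grid
    body = phantom.mask("body")
    ptv = phantom.mask("ptv")
    ptv_13 = expand_mask(ptv, 1.3, grid)
    ptv_03 = expand_mask(ptv, 0.3, grid)

    ring = ptv_13 & ~ptv_03 & body
    nt = body & ~ptv_13
    if not nt.any():
        warnings.warn("normal-tissue structure 'nt' is empty (PTV + 1.3 cm covers the body)")
    sp03 = expand_mask(phantom.mask("spinal_cord"), 0.3, grid) & body
    lung_minus_ptv = phantom.mask("lungs") & ~ptv

    phantom.add_structure("ring", ring, derived=True)
    phantom.add_structure("nt", nt, derived=True)
    phantom.add_structure("sp0.3", sp03, derived=True)
    phantom.add_structure("lung-ptv", lung_minus_ptv, derived=True)
    return phantom


# ---------------------------------------------------------------------------
# NIfTI import/export (one file per structure, affine from the grid)


def save_structures_nifti(phantom: Phantom, directory) -> None:
    import pathlib

    import nibabel as nib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = phantom.grid.affine()
    nib.save(
        nib.Nifti1Image(phantom.density.astype(np.float32), aff),
        directory / "density.nii",
    )
    for name, struct in phantom.structures.items():
        safe = name.replace(".", "p").replace("-", "_")
        nib.save(
            nib.Nifti1Image(struct.mask.astype(np.uint8), aff),
            directory / f"{safe}.nii",
        )


def load_structure_nifti(path) -> tuple[np.ndarray, GridSpec]:
    """Read one structure (or density) volume and recover its grid."""
    import nibabel as nib

    img = nib.load(path)
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    data = np.asarray(img.dataobj)
    grid = GridSpec(tuple(int(s) for s in data.shape), spacing, origin)
    return data, grid
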