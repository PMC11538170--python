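"""Geometric and intensity primitives for 3D SPECT volumes.

Conventions used throughout the package:

* World coordinates are RAS millimetres (``+x`` right, ``+y`` anterior,
  ``+z`` superior).
* Voxel indices are 0-based; the 4x4 ``affine`` maps homogeneous voxel
  indices to world millimetres.
* Out-of-field values are 0, matching the dark background of SPECT.
* Two grids are considered compatible when shapes match exactly and
  affines agree entrywise within ``GRID_TOL`` (round-tripped files are
  not bit-identical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

GRID_TOL = 1e-6

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full-width-at-half-maximum to a Gaussian sigma (same units)."""
    return float(fwhm) / FWHM_PER_SIGMA


@dataclass(frozen=True)
class Grid:
    """A 3D sampling lattice: shape plus voxel-index -> world-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray  # (4, 4), float

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"degenerate grid shape {self.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("non-invertible affine")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to (..., 3) world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_coordinates(self) -> np.ndarray:
        """World mm of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack([idx[0], idx[1], idx[2]], axis=-1)
        return self.voxel_to_world(ijk)


def centered_grid(shape: tuple[int, int, int], spacing) -> Grid:
    """Axis-aligned grid whose world origin is the volume centre.

    Placing world ``x = 0`` at the centre puts the mid-sagittal plane
    through the middle of the field of view, which is the convention the
    template space and hemisphere split rely on.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -spacing * (np.asarray(shape) - 1) / 2.0
    return Grid(shape, affine)


def grids_compatible(a: Grid, b: Grid, tol: float = GRID_TOL) -> bool:
    return a.shape == b.shape and bool(np.allclose(a.affine, b.affine, atol=tol))


def _check_compatible(a: Grid, b: Grid, what: str) -> None:
    if not grids_compatible(a, b):
        raise ValueError(f"grid mismatch between {what}")


@dataclass
class Volume:
    """A 3D scalar image with its sampling grid.

    ``data`` holds counts or normalized uptake; non-finite voxels are
    rejected at construction so nothing downstream needs to guard
    against NaN propagation.
    """

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.grid.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    @property
    def spacing(self) -> np.ndarray:
        return self.grid.spacing

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data, dtype=np.float64), self.grid)


@dataclass
class BinaryVOI:
    """Boolean volume-of-interest mask on a grid."""

    mask: np.ndarray
    grid: Grid
    name: str = field(default="voi")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.grid.spacing))


def resample(
    vol: Volume,
    target_grid: Grid,
    transform=None,
    interpolation: str = "linear",
) -> Volume:
    """Pull ``vol`` onto ``target_grid`` through a world->world transform.

    ``transform`` maps target-grid world coordinates into source world
    coordinates (pull-back convention); ``None`` means identity.  Values
    outside the source support are 0.  ``nearest`` is for label/mask
    volumes, ``linear`` for intensity volumes.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0

    xyz = target_grid.world_coordinates().reshape(-1, 3)
    if transform is not None:
        xyz = transform(xyz)
    ijk = vol.grid.world_to_voxel(xyz)
    out = ndimage.map_coordinates(
        vol.data, ijk.T, order=order, mode="constant", cval=0.0, prefilter=False
    )
    return Volume(out.reshape(target_grid.shape), target_grid)


def sample_at_world(vol: Volume, xyz: np.ndarray, order: int = 1) -> np.ndarray:
    """Interpolate ``vol`` at world coordinates ``xyz`` (N, 3); 0 outside."""
    ijk = vol.grid.world_to_voxel(np.asarray(xyz, dtype=float))
    return ndimage.map_coordinates(
        vol.data, ijk.T, order=order, mode="constant", cval=0.0, prefilter=False
    )


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable 3D Gaussian smoothing at a given FWHM in mm.

    Per-axis sigma in voxels is ``fwhm / 2.3548 / spacing_axis`` so
    anisotropic grids blur isotropically in world space.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vol.spacing
    if np.all(fwhm_mm < 0.1 * vol.spacing):
        warnings.warn(
            f"FWHM {fwhm_mm} mm is below a tenth of a voxel; smoothing skipped",
            stacklevel=2,
        )
        return vol.copy_with(vol.data.copy())
    out = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="constant", cval=0.0)
    return vol.copy_with(out)


def masked_mean(vol: Volume, voi: BinaryVOI) -> float:
    """Arithmetic mean of the voxels under a nonempty mask."""
    _check_compatible(vol.grid, voi.grid, "volume and VOI")
    if voi.n_voxels == 0:
        raise ValueError(f"empty mask {voi.name!r}: mean undefined")
    return float(vol.data[voi.mask].mean())
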