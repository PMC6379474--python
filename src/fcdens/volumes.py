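"""Volumetric containers and NIfTI-1 I/O.

The package works on a regular 3-D voxel lattice in a common (MNI-like)
space.  Only *scaled-translation* affines are supported: the world
coordinate of voxel index ``i`` along each axis is ``origin + i * voxel_size``.
General rotations/shears are rejected at load time so that all neighborhood
distances stay exact center-to-center Euclidean distances in millimetres.

Voxel indices are 0-based; the voxel center defines its world position.
Mask extraction order is lexicographic in voxel index (C order), which every
routine in the package relies on for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "BoldSeries",
    "GrayMatterMask",
    "GeometryError",
    "UnsupportedOrientationError",
    "load_volume",
    "load_bold",
    "load_mask",
    "save_volume",
    "save_bold",
]


class GeometryError(ValueError):
    """Grid/mask/volume dimensions are inconsistent."""


class UnsupportedOrientationError(ValueError):
    """The NIfTI affine is not a positive scaled translation."""


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D voxel lattice.

    Parameters
    ----------
    dims : tuple of 3 int
        Number of voxels along x, y, z.
    voxel_size_mm : tuple of 3 float
        Isotropic or anisotropic voxel edge lengths, strictly positive.
    origin_mm : tuple of 3 float
        World coordinate of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise GeometryError(f"dims must be 3 positive integers, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise GeometryError(
                f"voxel sizes must be positive, got {self.voxel_size_mm}"
            )
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm)
        )
        object.__setattr__(
            self, "origin_mm", tuple(float(o) for o in self.origin_mm)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_to_world(self, index) -> np.ndarray:
        """World (mm) coordinate of a voxel center; `index` may be (..., 3)."""
        idx = np.asarray(index)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)):
            raise IndexError(f"voxel index {index} outside grid dims {self.dims}")
        return np.asarray(self.origin_mm) + idx * np.asarray(self.voxel_size_mm)

    def world_to_voxel(self, point) -> np.ndarray:
        """Nearest lattice index of a world point; inverse of voxel_to_world."""
        pt = np.asarray(point, dtype=float)
        idx = np.rint(
            (pt - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)
        ).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)):
            raise IndexError(f"world point {point} outside grid")
        return idx

    @classmethod
    def from_affine(cls, affine: np.ndarray, dims) -> "VolumeGrid":
        aff = np.asarray(affine, dtype=float)
        lin = aff[:3, :3]
        diag = np.diag(lin)
        if not np.allclose(lin, np.diag(diag), atol=1e-6):
            raise UnsupportedOrientationError(
                "only axis-aligned (scaled translation) affines are supported; "
                f"got linear part\n{lin}"
            )
        if np.any(diag <= 0):
            raise UnsupportedOrientationError(
                "negative/zero affine scales are not supported; reorient first "
                f"(diagonal {diag})"
            )
        return cls(tuple(dims[:3]), tuple(diag), tuple(aff[:3, 3]))


@dataclass
class BoldSeries:
    """One subject's 4-D BOLD run: data indexed (x, y, z, time)."""

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float = 3.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise GeometryError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[:3] != self.grid.dims:
            raise GeometryError(
                f"data shape {self.data.shape[:3]} != grid dims {self.grid.dims}"
            )
        if self.data.shape[3] < 1:
            raise GeometryError("time dimension must be >= 1")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class GrayMatterMask:
    """Boolean gray-matter membership on a grid."""

    grid: VolumeGrid
    membership: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != self.grid.dims:
            raise GeometryError(
                f"mask shape {self.membership.shape} != grid dims {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) int array of member voxel indices, lexicographic order."""
        return np.argwhere(self.membership)

    def world_coords(self) -> np.ndarray:
        """(n, 3) world-mm centers of member voxels, same order."""
        return self.grid.voxel_to_world(self.voxel_indices())

    def extract(self, bold: BoldSeries) -> np.ndarray:
        """Masked time series as a (time, n_voxels) matrix.

        Column order matches :meth:`voxel_indices`.
        """
        if bold.grid.dims != self.grid.dims:
            raise GeometryError("BOLD grid does not match mask grid")
        return bold.data[self.membership].T.copy()


def _grid_from_img(img) -> VolumeGrid:
    return VolumeGrid.from_affine(img.affine, img.shape[:3])


def load_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    """Load a 3-D or 4-D NIfTI volume; returns (data, grid)."""
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    return np.asarray(img.get_fdata(), dtype=np.float64), grid


def load_bold(path, tr_s: float | None = None, subject_id: str = "") -> BoldSeries:
    img = nib.load(str(path))
    grid = _grid_from_img(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 3.0
    return BoldSeries(grid=grid, data=data, tr_s=tr_s, subject_id=subject_id)


def load_mask(path) -> GrayMatterMask:
    data, grid = load_volume(path)
    return GrayMatterMask(grid=grid, membership=data > 0.5)


def save_volume(path, data: np.ndarray, grid: VolumeGrid, tr_s: float | None = None):
    """Write a 3-D/4-D array as NIfTI-1 with the grid's scaled-translation affine."""
    data = np.asarray(data)
    if data.shape[:3] != grid.dims:
        raise GeometryError(f"data shape {data.shape[:3]} != grid dims {grid.dims}")
    img = nib.Nifti1Image(data.astype(np.float64), grid.affine)
    zooms = list(grid.voxel_size_mm)
    if data.ndim == 4:
        zooms.append(tr_s if tr_s else 1.0)
    img.header.set_zooms(tuple(zooms[: data.ndim]))
    nib.save(img, str(path))


def save_bold(path, bold: BoldSeries):
    save_volume(path, bold.data, bold.grid, tr_s=bold.tr_s)


def save_mask(path, mask: GrayMatterMask):
    save_volume(path, mask.membership.astype(np.uint8), mask.grid)
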