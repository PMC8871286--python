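"""Axis-aligned 3D scalar lattices and the containers built on them.

All images, masks and parameter maps in this package are carried on a
:class:`VolumeGrid`: a 3D array of scalars with a per-axis voxel spacing in
millimetres and a world-space origin at the centre of voxel (0, 0, 0).
Lattices are axis-aligned (RAS+); oblique affines are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "PDFFMap", "VOISpec", "GeometryError"]


class GeometryError(ValueError):
    """Raised when two lattices that must be congruent are not, or a
    region/VOI does not intersect the lattice or mask."""


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with voxel spacing (mm) and world origin (mm).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar field. Must be finite.
    voxel_size : tuple of float
        Per-axis spacing in mm, all strictly positive.
    origin : tuple of float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (0.98, 0.98, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3D lattice, got ndim={self.values.ndim}")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.voxel_size) != 3 or len(self.origin) != 3:
            raise GeometryError("voxel_size and origin must have 3 components")
        if any(s <= 0 for s in self.voxel_size):
            raise GeometryError(f"voxel spacings must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("lattice values must be finite")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def congruent(self, other: "VolumeGrid") -> bool:
        """Same shape, spacing and origin (to 1e-6 mm)."""
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=1e-6)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def require_congruent(self, other: "VolumeGrid", what: str = "grids") -> None:
        if not self.congruent(other):
            raise GeometryError(
                f"{what} are not on the same lattice: "
                f"{self.shape}/{self.voxel_size}/{self.origin} vs "
                f"{other.shape}/{other.voxel_size}/{other.origin}"
            )

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)

    def like(self, values: np.ndarray) -> "VolumeGrid":
        """A new grid on this lattice carrying ``values``."""
        return VolumeGrid(values, self.voxel_size, self.origin)

    # -- NIfTI I/O --------------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        img.header.set_zooms(self.voxel_size)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        aff = img.affine
        off = np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))).max()
        if off > 1e-4:
            raise GeometryError(f"{path}: oblique affines are not supported")
        return cls(
            np.asarray(img.dataobj, dtype=np.float64),
            tuple(np.diag(aff[:3, :3])),
            tuple(aff[:3, 3]),
        )


@dataclass
class PDFFMap:
    """A voxel-wise fat-fraction map (percent) with its liver mask.

    ``map`` carries PDFF in percent units (0–100); ``mask`` is a binary grid
    on the same lattice. Values are only guaranteed in range inside the mask.
    """

    map: VolumeGrid
    mask: VolumeGrid

    def __post_init__(self) -> None:
        self.map.require_congruent(self.mask, "PDFF map and mask")
        m = self.mask_bool
        if not m.any():
            raise GeometryError("liver mask is empty")
        inside = self.map.values[m]
        if inside.min() < -1e-9 or inside.max() > 100 + 1e-9:
            raise ValueError(
                f"PDFF values inside the mask must lie in [0, 100] percent; "
                f"range is [{inside.min():.3g}, {inside.max():.3g}]"
            )

    @property
    def mask_bool(self) -> np.ndarray:
        return self.mask.values > 0.5

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask_bool.sum())

    @property
    def liver_volume_ml(self) -> float:
        return self.n_mask_voxels * self.map.voxel_volume_ml


@dataclass
class VOISpec:
    """Axis-aligned cubic volume of interest in world coordinates.

    The default 20 mm side matches a single-voxel spectroscopy VOI placed in
    the right hepatic lobe; the same cube is re-used on the fat-fraction map
    so the two methods sample the same tissue.
    """

    center: tuple[float, float, float]
    side: float = 20.0

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)
        if len(self.center) != 3:
            raise GeometryError("VOI center must have 3 components")
        self.side = float(self.side)
        if self.side <= 0:
            raise GeometryError(f"VOI side must be > 0 mm, got {self.side}")
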