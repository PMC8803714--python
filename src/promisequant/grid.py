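"""Voxel-grid data model and NIfTI I/O.

A :class:`VoxelGrid` carries a 3D scalar (SUV) or integer (label) volume
together with its physical geometry: voxel spacing in mm and the 4x4
voxel-to-world affine. All masks and label maps in this package live on the
PET grid; co-registration is expressed by sharing a ``frame`` identifier and
identical geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "voxel_volume_ml",
]


def voxel_volume_ml(spacing: tuple[float, float, float]) -> float:
    """Volume of one voxel in mL for a spacing triple in mm."""
    sx, sy, sz = spacing
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return sx * sy * sz / 1000.0


@dataclass
class VoxelGrid:
    """A 3D volume with anisotropic spacing (mm) and a voxel-to-world affine.

    Parameters
    ----------
    data
        3D array; floating dtype for SUV volumes, integer dtype for label maps.
    spacing
        Voxel edge lengths (sx, sy, sz) in mm along array axes 0, 1, 2.
    affine
        4x4 voxel-index -> world-mm map (NIfTI convention). Defaults to a
        diagonal affine built from ``spacing``.
    frame
        Identifier tying co-registered grids together.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]
    frame: str = "unnamed"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self.spacing)

    @property
    def is_integer(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer)

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of one voxel index or an (n, 3) array of them."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        homog = np.c_[idx, np.ones(len(idx))]
        world = homog @ self.affine.T
        out = world[:, :3]
        return out[0] if np.asarray(index).ndim == 1 else out

    def world_to_index(self, world) -> np.ndarray:
        """Continuous voxel indices of one world point or an (n, 3) array."""
        pts = np.atleast_2d(np.asarray(world, dtype=float))
        homog = np.c_[pts, np.ones(len(pts))]
        idx = homog @ np.linalg.inv(self.affine).T
        out = idx[:, :3]
        return out[0] if np.asarray(world).ndim == 1 else out

    def same_frame(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return replace(self, data=data)


@dataclass
class BinaryMask:
    """Organ or lesion membership on a voxel grid."""

    grid: VoxelGrid
    label_name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.grid.data)
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.all(np.isin(uniq, [0, 1])):
                raise ValueError("mask values must be in {0, 1}")
            self.grid = self.grid.with_data(data.astype(bool))

    @classmethod
    def from_array(
        cls, data: np.ndarray, like: VoxelGrid, label_name: str = ""
    ) -> "BinaryMask":
        if data.shape != like.shape:
            raise ValueError(f"mask shape {data.shape} != grid shape {like.shape}")
        grid = VoxelGrid(
            data=np.asarray(data, dtype=bool),
            spacing=like.spacing,
            affine=like.affine,
            frame=like.frame,
        )
        return cls(grid=grid, label_name=label_name)

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_ml


def read_volume(path: str | Path, frame: str | None = None) -> VoxelGrid:
    """Read a NIfTI volume into a :class:`VoxelGrid`.

    SUV (floating-point) volumes are clamped at zero — negative voxels can
    occur after scanner reconstruction but carry no uptake meaning — with the
    clamped count logged. Integer label maps are preserved exactly.
    Non-finite voxels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got {len(img.shape)}D: {path}")
    on_disk = img.get_data_dtype()
    if np.issubdtype(on_disk, np.integer):
        data = np.asarray(img.dataobj).astype(on_disk)
    else:
        data = np.asarray(img.dataobj, dtype=np.float64)
        n_bad = int(np.size(data) - np.isfinite(data).sum())
        if n_bad:
            raise ValueError(f"{n_bad} non-finite voxel(s) in {path}")
        n_neg = int((data < 0).sum())
        if n_neg:
            logger.warning("clamped %d negative SUV voxel(s) to 0 in %s", n_neg, path)
            data = np.clip(data, 0.0, None)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(
        data=data, spacing=spacing, affine=img.affine, frame=frame or path.stem
    )


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a :class:`VoxelGrid` to NIfTI; lossless for labels, float64 for SUV."""
    path = Path(path)
    if grid.is_integer:
        data = grid.data
    else:
        data = np.asarray(grid.data, dtype=np.float64)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, path)
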