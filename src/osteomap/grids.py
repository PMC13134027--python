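"""Sampling grids, binary masks, and NIfTI input/output.

All masks of a case live on one :class:`VolumeGrid` — a 3D lattice with a
shape, a per-axis spacing in millimetres, and a 4x4 voxel-to-world affine.
Masks are combined strictly in voxel space after grid compatibility has been
checked; orientation mismatches are hard errors, never silently reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "GridMismatchError",
    "VolumeGrid",
    "BinaryMask",
    "CaseInputs",
    "read_mask",
    "write_mask",
    "resample_nearest",
]

#: relative tolerance for comparing spacings / affines; absorbs header round-off
GRID_RTOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """The 3D sampling lattice shared by all masks of a case.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis; every entry must be >= 1.
    spacing : tuple of float
        Millimetres per voxel along each axis; strictly positive.
    affine : (4, 4) ndarray
        Voxel-index to world-coordinate (mm) mapping. Defaults to a
        diagonal affine built from ``spacing`` with origin at zero.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive reals, got {spacing}")
        affine = self.affine
        if affine is None:
            affine = np.diag([*spacing, 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)
        self.affine.setflags(write=False)

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (product of spacings)."""
        return float(np.prod(self.spacing))

    def compatible(self, other: "VolumeGrid", rtol: float = GRID_RTOL) -> bool:
        """Same shape, and spacing/affine equal within relative tolerance."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=rtol, atol=0.0)
            and np.allclose(self.affine, other.affine, rtol=rtol, atol=rtol)
        )

    def require_compatible(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                f"{what} are on incompatible grids: "
                f"shape {self.shape} spacing {self.spacing} vs "
                f"shape {other.shape} spacing {other.spacing}"
            )


@dataclass(frozen=True)
class BinaryMask:
    """A 3D {0,1} array aligned to a :class:`VolumeGrid`."""

    grid: VolumeGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={vox.ndim}")
        if tuple(vox.shape) != self.grid.shape:
            raise GridMismatchError(
                f"mask shape {vox.shape} does not match grid shape {self.grid.shape}"
            )
        vox = (vox != 0).astype(np.uint8)
        object.__setattr__(self, "voxels", vox)
        self.voxels.setflags(write=False)

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return self.count() * self.grid.voxel_volume_mm3

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)


@dataclass(frozen=True)
class CaseInputs:
    """One case: a tumor mask and a skull mask on a common grid, plus covariates."""

    case_id: str
    tumor: BinaryMask
    skull: BinaryMask
    covariates: Optional[dict] = None

    def __post_init__(self) -> None:
        self.tumor.grid.require_compatible(
            self.skull.grid, what=f"tumor and skull masks of case {self.case_id!r}"
        )


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 3D NIfTI volume as a binary mask.

    Any nonzero voxel becomes 1. Grid metadata (shape, zooms, affine) is
    taken from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read NIfTI header of {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise IOError(f"{path} is not a 3D volume (ndim={data.ndim})")
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(shape=data.shape, spacing=tuple(float(z) for z in zooms),
                      affine=np.asarray(img.affine, dtype=float))
    return BinaryMask(grid=grid, voxels=data)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI; re-reading reproduces it bit-exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine=mask.grid.affine)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def resample_nearest(
    mask: BinaryMask, target: VolumeGrid, transform: np.ndarray | None = None
) -> BinaryMask:
    """Resample a binary mask onto ``target`` by nearest-neighbor lookup.

    ``transform`` is a 4x4 world-to-world affine mapping *source* world
    coordinates to *target* world coordinates (the forward mapping a
    registration produces); it is inverted here to pull values. Voxels whose
    nearest source location falls outside the source field of view are 0
    (masks are absence-default). Output is always binary and on ``target``.
    """
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    det = np.linalg.det(transform)
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("transform is singular and cannot be inverted")

    # target voxel -> target world -> (inverse transform) source world -> source voxel
    full = np.linalg.inv(mask.grid.affine) @ np.linalg.inv(transform) @ target.affine
    ii, jj, kk = np.meshgrid(
        np.arange(target.shape[0]),
        np.arange(target.shape[1]),
        np.arange(target.shape[2]),
        indexing="ij",
    )
    ones = np.ones_like(ii)
    idx = np.stack([ii, jj, kk, ones], axis=0).reshape(4, -1)
    src = full @ idx
    src_idx = np.rint(src[:3]).astype(np.int64)
    inside = np.ones(src_idx.shape[1], dtype=bool)
    for ax in range(3):
        inside &= (src_idx[ax] >= 0) & (src_idx[ax] < mask.grid.shape[ax])
    out = np.zeros(np.prod(target.shape), dtype=np.uint8)
    s = src_idx[:, inside]
    out[inside] = mask.voxels[s[0], s[1], s[2]]
    return BinaryMask(grid=target, voxels=out.reshape(target.shape))
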