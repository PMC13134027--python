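"""Compartment construction: osseous shell, juxta-osseous band, intradural space.

The skull mask partitions the head into an osseous compartment (the mask
itself), a juxta-osseous/dural-proximity layer — the band of intracranial
voxels within a fixed Euclidean distance (default 5 mm) of the inner table —
and the remaining intradural space. The layer is a radiological proximity
compartment, not an anatomical dura segmentation.

Distances are metric: voxel-center to voxel-center in millimetres, honoring
anisotropic spacing, boundary-inclusive (distance <= thickness). Residual
overlaps are resolved by the fixed priority osseous > juxta-osseous >
intradural, so the labels always form a partition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import BinaryMask, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "LayerSpec",
    "CompartmentMap",
    "NoCavityError",
    "LABEL_BACKGROUND",
    "LABEL_OSSEOUS",
    "LABEL_JUXTAOSSEOUS",
    "LABEL_INTRADURAL",
    "extract_intracranial_cavity",
    "make_juxtaosseous_layer",
    "build_compartment_map",
    "compartment_map_for_skull",
]

LABEL_BACKGROUND = 0
LABEL_OSSEOUS = 1
LABEL_JUXTAOSSEOUS = 2
LABEL_INTRADURAL = 3

#: tolerance (mm) added to the thickness so exactly-attained distances
#: (e.g. 5.0 on a 1-mm grid) survive floating-point sqrt
_DIST_TOL = 1e-7


class NoCavityError(ValueError):
    """The skull mask encloses no bounded interior."""


@dataclass(frozen=True)
class LayerSpec:
    """Geometry parameters of the compartment construction.

    thickness_mm:
        Inward extent of the juxta-osseous band from the inner table.
        Default 5.0 mm; the sensitivity analysis uses {2, 3, 5} mm.
    connectivity:
        Voxel neighborhood (6, 18 or 26) used for the cavity fill and
        connected components. 6 is conservative and avoids diagonal leaks.
    closing_radius_mm:
        Radius of the morphological closing applied to the skull before the
        cavity fill, sealing foramina and other openings. 0 disables sealing.
    """

    thickness_mm: float = 5.0
    connectivity: int = 6
    closing_radius_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.thickness_mm < 0:
            raise ValueError("thickness_mm must be >= 0")
        if self.closing_radius_mm < 0:
            raise ValueError("closing_radius_mm must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def ndimage_structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass(frozen=True)
class CompartmentMap:
    """Mutually exclusive per-voxel labels (0 background, 1 osseous,
    2 juxta-osseous/dural, 3 intradural)."""

    grid: VolumeGrid
    labels: np.ndarray
    layer: LayerSpec = field(default_factory=LayerSpec)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if tuple(labels.shape) != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        if not np.isin(labels, [0, 1, 2, 3]).all():
            raise ValueError("labels must be in {0,1,2,3}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))
        self.labels.setflags(write=False)

    def mask(self, label: int) -> BinaryMask:
        return BinaryMask(grid=self.grid, voxels=(self.labels == label))

    def label_counts(self) -> dict[int, int]:
        return {lab: int((self.labels == lab).sum()) for lab in (0, 1, 2, 3)}

    def save(self, path: str | Path) -> None:
        """Write the integer-coded map as NIfTI plus a JSON sidecar with the LayerSpec."""
        path = Path(path)
        img = nib.Nifti1Image(self.labels.astype(np.uint8), affine=self.grid.affine)
        img.header.set_zooms(self.grid.spacing)
        nib.save(img, str(path))
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
        sidecar = sidecar.parent / (sidecar.name + ".json")
        sidecar.write_text(json.dumps({
            "thickness_mm": self.layer.thickness_mm,
            "connectivity": self.layer.connectivity,
            "closing_radius_mm": self.layer.closing_radius_mm,
            "labels": {"0": "background", "1": "osseous",
                       "2": "juxta-osseous/dural", "3": "intradural"},
        }, indent=2))


def _ball_structure(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Metric ball structuring element honoring anisotropic spacing."""
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    zz, yy, xx = np.meshgrid(
        *(np.arange(-h, h + 1) * s for h, s in zip(half, spacing)), indexing="ij"
    )
    return (zz**2 + yy**2 + xx**2) <= radius_mm**2 + _DIST_TOL


def extract_intracranial_cavity(skull: BinaryMask, spec: LayerSpec) -> BinaryMask:
    """Recover the bounded space enclosed by the skull shell.

    The skull is first closed with a metric ball of ``closing_radius_mm`` to
    seal foramina, then the connected components of the complement are
    examined: components touching the array border are extracranial, and the
    largest enclosed component is the cavity. Skull voxels are subtracted, so
    the result is always disjoint from the skull. Voxels swallowed by the
    closing (inside sealed openings) belong to neither compartment.
    """
    if skull.count() == 0:
        raise ValueError("skull mask is empty")
    bone = skull.as_bool()
    if spec.closing_radius_mm > 0:
        selem = _ball_structure(spec.closing_radius_mm, skull.grid.spacing)
        # pad so the closing is not truncated at the array border
        pad = [s // 2 for s in selem.shape]
        padded = np.pad(bone, [(p, p) for p in pad])
        closed = ndimage.binary_closing(padded, structure=selem)
        closed = closed[tuple(slice(p, c + p) for p, c in zip(pad, bone.shape))]
    else:
        closed = bone
    complement = ~closed
    lab, n = ndimage.label(complement, structure=spec.ndimage_structure())
    if n == 0:
        raise NoCavityError("skull fills the whole volume; no cavity")
    border_labels = set(np.unique(lab[0, :, :])) | set(np.unique(lab[-1, :, :])) \
        | set(np.unique(lab[:, 0, :])) | set(np.unique(lab[:, -1, :])) \
        | set(np.unique(lab[:, :, 0])) | set(np.unique(lab[:, :, -1]))
    border_labels.discard(0)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    enclosed = [i + 1 for i in range(n) if (i + 1) not in border_labels]
    if not enclosed:
        raise NoCavityError(
            "no bounded interior found: the skull shell is open; "
            "consider a larger closing_radius_mm"
        )
    best = max(enclosed, key=lambda i: sizes[i - 1])
    cavity = (lab == best) & ~bone
    return BinaryMask(grid=skull.grid, voxels=cavity)


def make_juxtaosseous_layer(
    skull: BinaryMask, cavity: BinaryMask, spec: LayerSpec
) -> BinaryMask:
    """Band of cavity voxels within ``thickness_mm`` of the nearest skull voxel.

    Distance is the Euclidean voxel-center distance in mm using the grid
    spacing (exact distance transform); the boundary is inclusive. Always a
    subset of the cavity.
    """
    skull.grid.require_compatible(cavity.grid, "skull and cavity")
    if cavity.count() == 0:
        return BinaryMask(grid=cavity.grid, voxels=np.zeros(cavity.grid.shape))
    if spec.thickness_mm == 0:
        return BinaryMask(grid=cavity.grid, voxels=np.zeros(cavity.grid.shape))
    dist = ndimage.distance_transform_edt(
        ~skull.as_bool(), sampling=skull.grid.spacing
    )
    band = cavity.as_bool() & (dist <= spec.thickness_mm + _DIST_TOL)
    return BinaryMask(grid=cavity.grid, voxels=band)


def build_compartment_map(
    skull: BinaryMask,
    layer: BinaryMask,
    cavity: BinaryMask,
    spec: LayerSpec,
) -> CompartmentMap:
    """Resolve overlaps by fixed priority and emit the exclusive label map.

    Priority: osseous, then juxta-osseous/dural, then intradural; everything
    else is background. The output is a partition by construction.
    """
    skull.grid.require_compatible(layer.grid, "skull and layer")
    skull.grid.require_compatible(cavity.grid, "skull and cavity")
    labels = np.zeros(skull.grid.shape, dtype=np.uint8)
    labels[cavity.as_bool()] = LABEL_INTRADURAL
    labels[layer.as_bool()] = LABEL_JUXTAOSSEOUS
    labels[skull.as_bool()] = LABEL_OSSEOUS
    return CompartmentMap(grid=skull.grid, labels=labels, layer=spec)


def compartment_map_for_skull(skull: BinaryMask, spec: LayerSpec) -> CompartmentMap:
    """Full construction from a skull mask alone: cavity, band, label map."""
    cavity = extract_intracranial_cavity(skull, spec)
    layer = make_juxtaosseous_layer(skull, cavity, spec)
    return build_compartment_map(skull, layer, cavity, spec)
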