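"""Bone segmentation, isodose reconstruction and voxel volumetrics.

The quantities of interest are all volumes and intersections of voxel
regions: the mandible Vm, the whole-grid isodose volume at a threshold
(e.g. V56 for 56 Gy), the planning target volume V-PTV, and the mandibular
portions Vm56 and Vm-PTV. A voxel belongs to a region iff its *center* is
inside; volumes are voxel counts times the voxel volume, reported in mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .core import BinaryVolume, DoseGrid, FrameMismatchError, ImageFrame, _require_same_frame

__all__ = [
    "IsodoseVolume",
    "segment_bone",
    "isodose_region",
    "volume_ml",
    "intersect",
    "mesh_from_mask",
]


@dataclass
class IsodoseVolume:
    """The 3D region receiving at least ``threshold`` Gy."""

    threshold: float
    region: BinaryVolume
    source: Literal["dose_threshold", "contour"] = "dose_threshold"


def segment_bone(
    hu_volume: np.ndarray,
    frame: ImageFrame,
    hu_threshold: float = 300.0,
    roi_mask: BinaryVolume | None = None,
) -> BinaryVolume:
    """Threshold-segment bone from a CT volume.

    The mask is ``HU >= hu_threshold``, optionally intersected with a region
    of interest, then restricted to the largest 26-connected component so that
    disconnected high-density structures (teeth fillings, hyoid, artefacts)
    are dropped.
    """
    if not np.isfinite(hu_threshold):
        raise ValueError("hu_threshold must be finite")
    hu_volume = np.asarray(hu_volume)
    if hu_volume.shape != frame.shape:
        raise ValueError("HU volume shape does not match frame")
    mask = hu_volume >= hu_threshold
    if roi_mask is not None:
        if not roi_mask.frame.approx_equal(frame):
            raise FrameMismatchError("roi_mask must be in the same frame")
        mask &= roi_mask.mask
    if not mask.any():
        raise ValueError(f"no bone above threshold {hu_threshold} HU")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    return BinaryVolume(frame=frame, mask=mask)


def isodose_region(dose: DoseGrid, threshold: float) -> IsodoseVolume:
    """Region of the dose grid receiving at least ``threshold`` Gy (inclusive)."""
    if threshold <= 0:
        raise ValueError("isodose threshold must be positive")
    region = BinaryVolume(frame=dose.frame, mask=dose.values >= threshold)
    return IsodoseVolume(threshold=float(threshold), region=region)


def volume_ml(v: BinaryVolume) -> float:
    """Volume of a mask in millilitres (1 mL = 1000 mm^3)."""
    return v.voxel_count * v.frame.voxel_volume_mm3 / 1000.0


def intersect(a: BinaryVolume, b: BinaryVolume) -> BinaryVolume:
    """Voxelwise AND of two masks sharing one frame."""
    _require_same_frame(a.frame, b.frame, "intersect")
    return BinaryVolume(frame=a.frame, mask=a.mask & b.mask)


def mesh_from_mask(
    v: BinaryVolume,
    iso_level: float = 0.5,
    smooth_sigma_vox: float = 0.0,
) -> trimesh.Trimesh:
    """Triangulated iso-surface of a binary mask, vertices in patient mm.

    Marching cubes is run at the 0/1 midpoint of the (optionally
    Gaussian-smoothed) indicator function. The indicator is padded by one
    voxel of background first, so masks touching the array border still
    produce a closed, watertight surface.
    """
    if not v.mask.any():
        raise ValueError("cannot mesh an empty mask")
    indicator = np.pad(v.mask.astype(float), 1)
    if smooth_sigma_vox > 0:
        indicator = ndimage.gaussian_filter(indicator, smooth_sigma_vox)
        if indicator.max() <= iso_level:
            raise ValueError("smoothing erased the mask; lower smooth_sigma_vox")
    verts, faces, _, _ = measure.marching_cubes(indicator, level=iso_level)
    verts -= 1.0  # undo padding offset, back to voxel-index coordinates
    verts_mm = v.frame.index_to_physical(verts)
    mesh = trimesh.Trimesh(vertices=verts_mm, faces=faces, process=True)
    return mesh
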