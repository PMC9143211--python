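"""Readers and writers for the radiotherapy imaging formats.

Everything read here is expressed in one common patient-space frame (DICOM
LPS, millimetres) so that downstream geometry — isodose reconstruction,
virtual resection, volumetrics — never has to reason about storage order or
vendor conventions again.

Supported formats: DICOM CT series, DICOM RTDOSE and DICOM RTSTRUCT (read);
NIfTI for binary masks (read/write); STL/PLY for surface meshes (write).
"""

from __future__ import annotations

import difflib
from pathlib import Path

import numpy as np
import pydicom
from scipy import ndimage

from .core import BinaryVolume, ContourSet, DoseGrid, ImageFrame

__all__ = [
    "read_ct_series",
    "read_rtdose",
    "read_rtstruct",
    "resample_dose_to_frame",
    "rasterize_contours",
    "save_mask",
    "load_mask",
    "save_mesh",
]


def _slice_frame(ds: pydicom.Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (row_dir, col_dir, normal) unit vectors from a DICOM dataset."""
    try:
        iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
        ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
    except AttributeError as exc:
        raise ValueError(f"missing geometry tags in {getattr(ds, 'filename', '?')}: {exc}")
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    return row_dir, col_dir, normal, ipp


def read_ct_series(directory_path: str | Path) -> tuple[ImageFrame, np.ndarray]:
    """Read one CT series from a directory into a HU volume.

    Slices are sorted by their patient-space position along the slice normal
    regardless of file order on disk, and the rescale slope/intercept is
    applied so the returned array is in Hounsfield units, indexed
    ``[ix, iy, iz]``.

    Raises
    ------
    ValueError
        If the directory mixes several series, if in-plane spacing differs
        between slices, or if slice positions are not uniformly spaced.
    """
    directory_path = Path(directory_path)
    files = sorted(p for p in directory_path.iterdir() if p.suffix.lower() == ".dcm")
    datasets = []
    for p in files:
        ds = pydicom.dcmread(p)
        if getattr(ds, "Modality", "CT") == "CT" or hasattr(ds, "ImagePositionPatient"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no CT slices found in {directory_path}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"directory mixes multiple series: {sorted(uids)}")

    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) > 1:
        raise ValueError(f"inconsistent PixelSpacing across slices: {sorted(spacings)}")

    row_dir, col_dir, normal, _ = _slice_frame(datasets[0])
    datasets.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))

    positions = np.array([np.dot(ds.ImagePositionPatient, normal) for ds in datasets])
    if len(positions) > 1:
        steps = np.diff(positions)
        if np.any(steps <= 0):
            raise ValueError("duplicate or non-monotone slice positions")
        if not np.allclose(steps, steps[0], atol=1e-4):
            raise ValueError(f"non-uniform slice spacing: {np.unique(steps.round(4))}")
        slice_spacing = float(steps[0])
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # DICOM stores (rows, cols); our convention is [ix=col, iy=row, iz=slice]
    hu = np.stack([s.T for s in slices], axis=2)

    ps = [float(v) for v in datasets[0].PixelSpacing]  # (row spacing, col spacing)
    frame = ImageFrame(
        origin=tuple(float(v) for v in datasets[0].ImagePositionPatient),
        spacing=(ps[1], ps[0], slice_spacing),
        direction=tuple(
            map(tuple, np.column_stack([row_dir, col_dir, normal]))
        ),
        shape=hu.shape,
    )
    return frame, hu


def read_rtdose(file_path: str | Path) -> DoseGrid:
    """Read a DICOM RTDOSE grid into physical dose (Gy).

    Stored integer values are multiplied by the file's DoseGridScaling
    factor; an absent scaling factor is an error, as are non-uniform
    GridFrameOffsetVector steps.
    """
    ds = pydicom.dcmread(file_path)
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{file_path}: RTDOSE without DoseGridScaling factor")
    scaling = float(ds.DoseGridScaling)

    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        steps = np.diff(offsets)
        if not np.allclose(steps, steps[0], atol=1e-4):
            raise ValueError(f"{file_path}: non-uniform GridFrameOffsetVector")
        slice_spacing = float(steps[0])
    else:
        slice_spacing = 1.0

    row_dir, col_dir, normal, ipp = _slice_frame(ds)
    values = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols)
    values = np.transpose(values, (2, 1, 0))  # -> [ix, iy, iz]

    ps = [float(v) for v in ds.PixelSpacing]
    frame = ImageFrame(
        origin=tuple(ipp),
        spacing=(ps[1], ps[0], slice_spacing),
        direction=tuple(map(tuple, np.column_stack([row_dir, col_dir, normal]))),
        shape=values.shape,
    )
    return DoseGrid(frame=frame, values=values)


def read_rtstruct(file_path: str | Path, roi_names: list[str]) -> list[ContourSet]:
    """Read the requested ROIs from a DICOM RTSTRUCT file.

    Names are matched case-insensitively. A missing ROI raises an error that
    lists the names actually present (with close matches first).
    """
    ds = pydicom.dcmread(file_path)
    roi_numbers: dict[str, int] = {}
    for item in ds.StructureSetROISequence:
        roi_numbers[str(item.ROIName)] = int(item.ROINumber)
    contours_by_number: dict[int, list] = {}
    for item in getattr(ds, "ROIContourSequence", []):
        contours_by_number[int(item.ReferencedROINumber)] = list(
            getattr(item, "ContourSequence", [])
        )

    lowered = {name.lower(): name for name in roi_numbers}
    out: list[ContourSet] = []
    for requested in roi_names:
        key = requested.lower()
        if key not in lowered:
            near = difflib.get_close_matches(requested, list(roi_numbers), n=3)
            available = near + [n for n in sorted(roi_numbers) if n not in near]
            raise ValueError(
                f"ROI {requested!r} not found in {file_path}; available: {available}"
            )
        stored = lowered[key]
        contours: list[tuple[float, np.ndarray]] = []
        for c in contours_by_number.get(roi_numbers[stored], []):
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            contours.append((float(pts[0, 2]), pts[:, :2]))
        out.append(ContourSet(name=stored, contours=contours))
    return out


def resample_dose_to_frame(dose: DoseGrid, target: ImageFrame) -> DoseGrid:
    """Trilinearly resample a dose grid onto the voxel centers of ``target``.

    Target voxel centers outside the support of the dose grid (the bounding
    box of its voxel centers) receive 0 Gy.
    """
    if target.approx_equal(dose.frame):
        return DoseGrid(frame=target, values=dose.values.copy(),
                        prescription_dose=dose.prescription_dose)

    cx, cy, cz = target.voxel_centers()
    pts = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    idx = dose.frame.physical_to_index(pts)

    inside = np.all((idx >= 0.0) & (idx <= np.asarray(dose.frame.shape) - 1), axis=1)
    values = np.zeros(len(pts))
    if inside.any():
        values[inside] = ndimage.map_coordinates(
            dose.values, idx[inside].T, order=1, mode="nearest"
        )
    return DoseGrid(
        frame=target,
        values=values.reshape(target.shape),
        prescription_dose=dose.prescription_dose,
    )


def rasterize_contours(contours: ContourSet, target: ImageFrame) -> BinaryVolume:
    """Convert planar structure polygons into a voxel mask on ``target``.

    A voxel is set iff its center lies inside the polygon(s) of the nearest
    contour plane along z (within half the slice spacing; a contour exactly
    midway between two voxel planes goes to the lower-index plane). Nested
    polygons on one plane follow the even-odd rule, so holes are excluded.
    """
    from matplotlib.path import Path as MplPath

    if not contours.contours:
        raise ValueError(f"contour set {contours.name!r} is empty")
    if not target.is_axis_aligned():
        raise NotImplementedError("contour rasterization requires an axis-aligned frame")

    nz = target.shape[2]
    oz, sz = target.origin[2], target.spacing[2]

    # group polygons by the voxel plane they land on
    by_plane: dict[int, list[np.ndarray]] = {}
    for z, poly in contours.contours:
        k_float = (z - oz) / sz
        k = int(np.floor(k_float + 0.5 - 1e-9))  # ties go to the lower plane
        if abs(k_float - k) > 0.5 + 1e-9:
            continue
        if 0 <= k < nz:
            by_plane.setdefault(k, []).append(poly)

    mask = np.zeros(target.shape, dtype=bool)
    nx, ny = target.shape[0], target.shape[1]
    xs = target.origin[0] + np.arange(nx) * target.spacing[0]
    ys = target.origin[1] + np.arange(ny) * target.spacing[1]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel()], axis=1)

    for k, polys in by_plane.items():
        plane = np.zeros(nx * ny, dtype=bool)
        for poly in polys:
            ring = np.vstack([poly, poly[:1]])  # explicit closing vertex
            inside = MplPath(ring, closed=True).contains_points(centers)
            plane ^= inside  # even-odd rule handles holes
        mask[:, :, k] = plane.reshape(nx, ny)
    return BinaryVolume(frame=target, mask=mask)


# -- mask and mesh persistence ----------------------------------------------


def _frame_affine(frame: ImageFrame) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = frame.direction_matrix * np.asarray(frame.spacing)
    affine[:3, 3] = frame.origin
    return affine


def save_mask(volume: BinaryVolume, file_path: str | Path) -> None:
    """Write a binary mask as NIfTI, encoding the frame in the affine."""
    import nibabel as nib

    img = nib.Nifti1Image(volume.mask.astype(np.uint8), _frame_affine(volume.frame))
    nib.save(img, str(file_path))


def load_mask(file_path: str | Path) -> BinaryVolume:
    """Read a NIfTI binary mask written by :func:`save_mask`."""
    import nibabel as nib

    img = nib.load(str(file_path))
    affine = img.affine
    data = np.asanyarray(img.dataobj) > 0
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    direction = affine[:3, :3] / spacing
    frame = ImageFrame(
        origin=tuple(affine[:3, 3]),
        spacing=tuple(spacing),
        direction=tuple(map(tuple, direction)),
        shape=data.shape,
    )
    return BinaryVolume(frame=frame, mask=data)


def save_mesh(mesh, file_path: str | Path) -> None:
    """Export a surface mesh to STL or PLY (chosen by file extension)."""
    mesh.export(str(file_path))
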