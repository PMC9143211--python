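"""Core geometric containers shared by every stage of the pipeline.

All geometry lives in the DICOM patient coordinate system (LPS, millimetres).
Scalar and mask arrays are indexed ``[ix, iy, iz]`` so that array axes line up
with the columns of the frame's direction matrix; the DICOM reading layer
transposes from slice-major storage order into this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageFrame",
    "DoseGrid",
    "ContourSet",
    "BinaryVolume",
    "FrameMismatchError",
]


class FrameMismatchError(ValueError):
    """Raised when an operation requires two volumes to share one frame."""


@dataclass(frozen=True)
class ImageFrame:
    """Regular 3D voxel lattice in patient space.

    Parameters
    ----------
    origin : (3,) float
        Patient-space position (mm, LPS) of the center of voxel ``(0, 0, 0)``.
    spacing : (3,) float
        Voxel edge lengths in mm, strictly positive.
    direction : (3, 3) float
        Orthonormal matrix whose columns are the patient-space directions of
        the three array axes.
    shape : (3,) int
        Voxel counts per axis, each at least 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    direction: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    shape: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in self.origin)
        spacing = tuple(float(v) for v in self.spacing)
        shape = tuple(int(v) for v in self.shape)
        direction = np.asarray(self.direction, dtype=float)
        if direction.shape != (3, 3):
            raise ValueError("direction must be a 3x3 matrix")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        if any(n < 1 for n in shape):
            raise ValueError(f"shape must be >= 1 per axis, got {shape}")
        if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")
        if abs(abs(np.linalg.det(direction)) - 1.0) > 1e-6:
            raise ValueError("direction matrix must have |det| = 1")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "direction", tuple(map(tuple, direction)))

    # -- derived geometry ---------------------------------------------------

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (N, 3) to patient mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        pts = idx * np.asarray(self.spacing)
        return pts @ self.direction_matrix.T + np.asarray(self.origin)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map patient-mm points (N, 3) to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.origin)
        return (pts @ self.direction_matrix) / np.asarray(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Patient-space coordinates of every voxel center.

        Returns three arrays of shape ``self.shape`` holding the x, y and z
        patient coordinates (mm).
        """
        ii, jj, kk = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        pts = self.index_to_physical(idx).reshape(*self.shape, 3)
        return pts[..., 0], pts[..., 1], pts[..., 2]

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable x/y/z voxel-center coordinates (mm).

        For axis-aligned frames the three arrays have shapes (nx,1,1),
        (1,ny,1) and (1,1,nz) so elementwise expressions never materialize
        an (N, 3) point list; oblique frames fall back to full grids.
        """
        if self.is_axis_aligned():
            ax = [
                self.origin[i] + np.arange(self.shape[i]) * self.spacing[i]
                for i in range(3)
            ]
            return (
                ax[0][:, None, None],
                ax[1][None, :, None],
                ax[2][None, None, :],
            )
        return self.voxel_centers()

    def is_axis_aligned(self) -> bool:
        return np.allclose(self.direction_matrix, np.eye(3), atol=1e-9)

    def approx_equal(self, other: "ImageFrame", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction_matrix, other.direction_matrix, atol=tol)
        )


def _require_same_frame(a_frame: ImageFrame, b_frame: ImageFrame, what: str) -> None:
    if not a_frame.approx_equal(b_frame):
        raise FrameMismatchError(
            f"{what} requires both volumes in one frame; resample first "
            f"(got shapes {a_frame.shape} vs {b_frame.shape}, "
            f"origins {a_frame.origin} vs {b_frame.origin})"
        )


@dataclass
class DoseGrid:
    """Absorbed-dose field (Gy) on a regular lattice.

    Values are physical dose: any file scaling factor has already been
    applied by the reader.
    """

    frame: ImageFrame
    values: np.ndarray
    prescription_dose: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.frame.shape:
            raise ValueError(
                f"dose array shape {self.values.shape} != frame shape {self.frame.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def max_dose(self) -> float:
        return float(self.values.max())


@dataclass
class ContourSet:
    """Planar closed polygons for one structure, in patient mm.

    ``contours`` is a list of ``(z_mm, polygon)`` pairs where ``polygon`` is an
    (N, 2) array of in-plane (x, y) vertices; polygons are implicitly closed.
    """

    name: str
    contours: list[tuple[float, np.ndarray]] = field(default_factory=list)
    frame: ImageFrame | None = None

    def __post_init__(self) -> None:
        cleaned: list[tuple[float, np.ndarray]] = []
        for z, poly in self.contours:
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise ValueError("each contour polygon must be an (N, 2) array")
            # drop an explicit closing vertex; polygons are implicitly closed
            if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            if len(np.unique(poly.round(9), axis=0)) < 3:
                raise ValueError("contour polygons need >= 3 distinct vertices")
            cleaned.append((float(z), poly))
        cleaned.sort(key=lambda item: item[0])
        self.contours = cleaned

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([z for z, _ in self.contours])


@dataclass
class BinaryVolume:
    """Boolean voxel mask in a reference frame."""

    frame: ImageFrame
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.frame.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != frame shape {self.frame.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def same_frame_as(self, other: "BinaryVolume") -> bool:
        return self.frame.approx_equal(other.frame)
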