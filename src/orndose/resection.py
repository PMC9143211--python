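"""Virtual segmental resection and osteotomy-plane analysis.

A segmental mandibulectomy is modelled by one or more oriented cutting
planes. Applying them to the mandible mask partitions it exactly into the
resected segment and the residual bone, from which the resection volume VmR
and the residual irradiated volumes (Vm56R, Vm-PTV-R) follow. The module
also reconstructs cut planes from pre/post-operative mask pairs, rigidly
registers post-operative bone models back into the radiotherapy frame (ICP),
and classifies each osteotomy plane by which cortical plate — lingual
(tongue-facing, concave) or buccal (cheek-facing, convex) — intersects the
56 Gy mandibular volume at the cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.cluster.vq import kmeans2
from scipy.spatial import cKDTree

from .core import BinaryVolume, _require_same_frame

__all__ = [
    "ResectionPlane",
    "ResectionSpec",
    "RigidTransform",
    "CorticalClassification",
    "ICPResult",
    "ArchMidline",
    "register_rigid",
    "register_two_segment",
    "fit_cut_planes",
    "apply_resection",
    "classify_osteotomy",
]


@dataclass(frozen=True)
class ResectionPlane:
    """Oriented osteotomy plane: a point on the plane and the unit normal
    pointing *into* the resected segment."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        if abs(norm - 1.0) > 1e-9:
            n = n / norm
        object.__setattr__(self, "normal", tuple(n))
        object.__setattr__(self, "point", tuple(float(v) for v in self.point))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed mm distance; positive on the resected side."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.point)) @ np.asarray(self.normal)


@dataclass
class ResectionSpec:
    """One resection: its cutting planes plus the rule selecting the removed
    segment.

    ``mode="halfspace"`` removes the voxels on the resected side of *all*
    planes (intersection of half-spaces), the natural encoding of a two-plane
    segmental resection. ``mode="seed"`` treats the planes as pure cuts and
    removes the connected piece containing ``seed_point`` — needed for
    resections that are not an intersection of half-spaces (and, with no
    planes at all, for removals without a bone cut such as an isolated
    condylectomy).
    """

    planes: list[ResectionPlane] = field(default_factory=list)
    mode: Literal["halfspace", "seed"] = "halfspace"
    seed_point: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode == "halfspace" and len(self.planes) < 1:
            raise ValueError("halfspace mode needs at least one plane")
        if self.mode == "seed" and self.seed_point is None:
            raise ValueError("seed mode needs a seed_point")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in patient mm."""

    rotation: tuple
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", tuple(map(tuple, R)))
        object.__setattr__(self, "translation", tuple(float(v) for v in self.translation))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=tuple(map(tuple, np.eye(3))), translation=(0.0, 0.0, 0.0))

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = np.asarray(self.rotation)
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        R1, R2 = np.asarray(self.rotation), np.asarray(other.rotation)
        t1, t2 = np.asarray(self.translation), np.asarray(other.translation)
        return RigidTransform(
            rotation=tuple(map(tuple, R1 @ R2)),
            translation=tuple(R1 @ t2 + t1),
        )

    def rotation_angle_deg(self) -> float:
        R = np.asarray(self.rotation)
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))


def read_planes_csv(file_path) -> dict[str, list[ResectionPlane]]:
    """Read osteotomy planes from CSV (columns case_id, plane_id, px, py, pz,
    nx, ny, nz; mm, patient frame), grouped by case."""
    import pandas as pd

    df = pd.read_csv(file_path)
    required = {"case_id", "plane_id", "px", "py", "pz", "nx", "ny", "nz"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"planes CSV missing columns: {sorted(missing)}")
    out: dict[str, list[ResectionPlane]] = {}
    for _, row in df.sort_values(["case_id", "plane_id"]).iterrows():
        out.setdefault(str(row["case_id"]), []).append(
            ResectionPlane(
                point=(row["px"], row["py"], row["pz"]),
                normal=(row["nx"], row["ny"], row["nz"]),
            )
        )
    return out


@dataclass(frozen=True)
class CorticalClassification:
    """Relation of one osteotomy plane to the 56 Gy mandibular volume.

    ``outside`` means the cut runs entirely through bone below the dose
    threshold; otherwise the involved cortical plate(s) are named.
    """

    category: Literal["outside", "lingual_only", "buccal_only", "bicortical"]
    lingual_area_mm2: float
    buccal_area_mm2: float

    def __post_init__(self) -> None:
        la, ba = self.lingual_area_mm2, self.buccal_area_mm2
        expected = _category_from_areas(la, ba)
        if expected != self.category:
            raise ValueError(
                f"category {self.category!r} inconsistent with areas ({la}, {ba})"
            )


def _category_from_areas(lingual: float, buccal: float) -> str:
    if lingual == 0 and buccal == 0:
        return "outside"
    if lingual > 0 and buccal == 0:
        return "lingual_only"
    if buccal > 0 and lingual == 0:
        return "buccal_only"
    return "bicortical"


# --------------------------------------------------------------------------
# Rigid registration (iterative closest point)
# --------------------------------------------------------------------------


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_mm: float
    converged: bool
    n_iterations: int
    overlap_fraction: float = 1.0
    warning: str | None = None

    def __iter__(self):  # allows ``transform, rms = register_rigid(...)``
        return iter((self.transform, self.rms_mm))


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src points onto dst points."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_d - R @ mu_s
    return RigidTransform(rotation=tuple(map(tuple, R)), translation=tuple(t))


def _principal_axis_inits(src: np.ndarray, dst: np.ndarray) -> list[RigidTransform]:
    """Centroid + principal-axes alignments, spun by quarter turns.

    The four proper sign choices of the principal axes, each additionally
    rotated by 90/180/270 degrees about every principal axis of the fixed
    cloud: near-symmetric bones (the arch is locally a surface of
    revolution) make ICP basins narrow, so a generous start set is needed.
    """
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    _, vs = np.linalg.eigh(np.cov((src - mu_s).T))
    _, vd = np.linalg.eigh(np.cov((dst - mu_d).T))
    bases = []
    for sx, sy in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
        S = np.diag([sx, sy, sx * sy])  # keeps det(R) = +1
        R = vd @ S @ vs.T
        if np.linalg.det(R) < 0:
            R = vd @ (S @ np.diag([1, 1, -1])) @ vs.T
        bases.append(R)

    spins = [np.eye(3)]
    for axis in range(3):
        u = vd[:, axis]
        K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
        for ang in np.arange(1, 60) * (np.pi / 30):  # 6 degree steps
            spins.append(np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K)

    inits = [
        RigidTransform.identity(),
        RigidTransform(rotation=tuple(map(tuple, np.eye(3))), translation=tuple(mu_d - mu_s)),
    ]
    for R in bases:
        for S in spins:
            Rfull = S @ R
            t = mu_d - Rfull @ mu_s
            inits.append(
                RigidTransform(rotation=tuple(map(tuple, Rfull)), translation=tuple(t))
            )
    return inits


def _points_of(mesh_or_points) -> np.ndarray:
    verts = getattr(mesh_or_points, "vertices", mesh_or_points)
    return np.asarray(verts, dtype=float)


def _normals_of(mesh_or_points, points: np.ndarray) -> np.ndarray:
    """Outward vertex normals of a mesh, or PCA-estimated normals for a bare
    point cloud (sign is irrelevant for point-to-plane residuals)."""
    normals = getattr(mesh_or_points, "vertex_normals", None)
    if normals is not None and len(normals) == len(points):
        return np.asarray(normals, dtype=float)
    tree = cKDTree(points)
    _, nn = tree.query(points, k=min(12, len(points)))
    out = np.empty_like(points)
    for i, idx in enumerate(nn):
        nbr = points[idx] - points[idx].mean(axis=0)
        _, _, Vt = np.linalg.svd(nbr, full_matrices=False)
        out[i] = Vt[-1]
    return out


def _rodrigues(omega: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(omega)
    if angle < 1e-14:
        return np.eye(3)
    u = omega / angle
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


def _point_to_plane_step(
    p: np.ndarray, q: np.ndarray, n: np.ndarray
) -> RigidTransform:
    """Linearized rigid update minimizing sum(n . (p + dx - q))^2."""
    b = np.einsum("ij,ij->i", q - p, n)
    A = np.hstack([np.cross(p, n), n])
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    R = _rodrigues(sol[:3])
    return RigidTransform(rotation=tuple(map(tuple, R)), translation=tuple(sol[3:]))


def register_rigid(
    moving,
    fixed,
    init: RigidTransform | None = None,
    max_iterations: int = 100,
    tolerance_mm: float = 1e-8,
    inlier_distance_mm: float = 2.0,
) -> ICPResult:
    """Rigidly register a moving surface onto a fixed surface by ICP.

    Point-to-point ICP over the mesh vertices, with nearest neighbours from a
    KD-tree. When no initial transform is given, the best of the four
    centroid + principal-axes alignments seeds the iteration, which makes the
    result invariant to the input pose. Robust to partial overlap (a resected
    specimen against the full pre-operative model): each iteration trims
    correspondences beyond 3x the median distance.

    Returns an :class:`ICPResult`; if the RMS has not stabilised after
    ``max_iterations`` the best transform so far is returned with
    ``converged=False`` and a warning message.
    """
    src = _points_of(moving)
    dst = _points_of(fixed)
    if len(src) == 0 or len(dst) == 0:
        raise ValueError("cannot register empty point sets")
    tree = cKDTree(dst)
    dst_normals = _normals_of(fixed, dst)

    def _run_icp(start: RigidTransform):
        # point-to-plane ICP: the normal-distance objective lets points
        # slide tangentially, which point-to-point correspondence locking
        # forbids, and is what "RMS point-to-surface distance" means
        transform = start
        prev_rms = np.inf
        converged = False
        n_iter = 0
        rms = np.inf
        for n_iter in range(1, max_iterations + 1):
            cur = transform.apply(src)
            dists, nn = tree.query(cur)
            cutoff = max(3.0 * np.median(dists), 1e-6)
            keep = dists <= cutoff
            p, q = cur[keep], dst[nn[keep]]
            n = dst_normals[nn[keep]]
            resid = np.einsum("ij,ij->i", p - q, n)
            rms = float(np.sqrt(np.mean(resid**2)))
            if abs(prev_rms - rms) < tolerance_mm:
                converged = True
                break
            prev_rms = rms
            transform = _point_to_plane_step(p, q, n).compose(transform)
        return transform, rms, converged, n_iter

    def _mean_dist(transform: RigidTransform, points: np.ndarray) -> float:
        d, _ = tree.query(transform.apply(points))
        return float(np.mean(d))

    if init is None:
        # partial, near-symmetric shapes make single-start ICP fall into
        # local minima (an arch is locally a surface of revolution, so poses
        # slid along the arch score almost as well as the true one).  Score a
        # dense rotational start set by subsampled mean nearest-neighbour
        # distance, refine the best few with full ICP, and rank the runs by
        # the untrimmed mean distance: trimming would hide exactly the
        # asymmetric landmarks that disambiguate the pose.
        sub = src[:: max(1, len(src) // 600)]
        sub_tree = cKDTree(dst[:: max(1, len(dst) // 6000)])

        def _score(start: RigidTransform) -> tuple[float, RigidTransform]:
            # partial clouds sit badly under centroid-to-centroid placement,
            # so let the translation settle before judging the rotation
            R = np.asarray(start.rotation)
            t = np.asarray(start.translation)
            rotated = sub @ R.T
            for _ in range(4):
                d, nn_idx = sub_tree.query(rotated + t)
                t = t + np.mean(sub_tree.data[nn_idx] - (rotated + t), axis=0)
            d, _ = sub_tree.query(rotated + t)
            settled = RigidTransform(rotation=start.rotation, translation=tuple(t))
            return float(np.mean(d)), settled

        scored = sorted(
            ((*(_score(start)), i) for i, start in
             enumerate(_principal_axis_inits(src, dst))),
            key=lambda item: (item[0], item[2]),
        )
        runs = [_run_icp(start) for _, start, _ in scored[:10]]
        transform, _, converged, n_iter = min(
            runs, key=lambda r: _mean_dist(r[0], src)
        )
    else:
        transform, _, converged, n_iter = _run_icp(init)

    cur = transform.apply(src)
    dists, nn = tree.query(cur)
    cutoff = max(3.0 * np.median(dists), 1e-6)
    keep = dists <= cutoff
    resid = np.einsum(
        "ij,ij->i", cur[keep] - dst[nn[keep]], dst_normals[nn[keep]]
    )
    rms = float(np.sqrt(np.mean(resid**2)))
    overlap = float(np.mean(dists <= inlier_distance_mm))
    warning = None
    if not converged:
        warning = f"ICP did not converge within {max_iterations} iterations"
    elif overlap < 0.25:
        warning = f"low overlap: only {overlap:.0%} of points matched the fixed surface"
    return ICPResult(
        transform=transform,
        rms_mm=rms,
        converged=converged,
        n_iterations=n_iter,
        overlap_fraction=overlap,
        warning=warning,
    )


def register_two_segment(
    segments: Sequence,
    fixed,
    inits: Sequence[RigidTransform | None] | None = None,
    **kwargs,
) -> list[ICPResult]:
    """Register each resected-bone segment to the fixed model independently.

    After a segmental resection with reconstruction, the two residual
    segments may no longer be in their original mutual pose, so each is
    registered on its own; the per-segment RMS and overlap fraction are
    reported in each result.
    """
    if inits is None:
        inits = [None] * len(segments)
    return [
        register_rigid(seg, fixed, init=init, **kwargs)
        for seg, init in zip(segments, inits)
    ]


# --------------------------------------------------------------------------
# Cut-plane recovery and application
# --------------------------------------------------------------------------

_FACE_SHIFTS = [
    (1, 0, 0), (-1, 0, 0),
    (0, 1, 0), (0, -1, 0),
    (0, 0, 1), (0, 0, -1),
]


def _cut_interface(preop: BinaryVolume, removed: np.ndarray):
    """Midpoints (mm) and outward face normals of kept/removed voxel faces."""
    kept = preop.mask & ~removed
    frame = preop.frame
    D = frame.direction_matrix
    spacing = np.asarray(frame.spacing)
    midpoints, normals = [], []
    for shift in _FACE_SHIFTS:
        shifted = np.roll(removed, tuple(-s for s in shift), axis=(0, 1, 2))
        # roll wraps around; kill the wrapped border
        for ax, s in enumerate(shift):
            if s == 1:
                shifted[(slice(None),) * ax + (-1,)] = False
            elif s == -1:
                shifted[(slice(None),) * ax + (0,)] = False
        faces = kept & shifted
        if not faces.any():
            continue
        idx = np.argwhere(faces).astype(float)
        idx += 0.5 * np.asarray(shift)  # face midpoint, in index units
        midpoints.append(frame.index_to_physical(idx))
        axis = int(np.argmax(np.abs(shift)))
        n = D[:, axis] * np.sign(shift[axis])
        normals.append(np.tile(n, (len(idx), 1)))
    if not midpoints:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.vstack(midpoints), np.vstack(normals)


def _fit_plane(points: np.ndarray, mean_normal: np.ndarray) -> ResectionPlane:
    centroid = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - centroid, full_matrices=False)
    normal = Vt[-1]
    if np.dot(normal, mean_normal) < 0:
        normal = -normal
    return ResectionPlane(point=tuple(centroid), normal=tuple(normal))


def fit_cut_planes(
    preop: BinaryVolume,
    postop_registered: BinaryVolume,
    n_planes: int = 2,
    normal_weight_mm: float = 20.0,
    seed: int = 0,
) -> ResectionSpec:
    """Reconstruct the osteotomy planes from a pre/post-operative mask pair.

    The removed material is ``preop AND NOT postop``. Faces between kept and
    removed voxels form the cut surface; their midpoints are clustered into
    ``n_planes`` groups by k-means on position plus (scaled) face normal, and
    a total-least-squares plane is fitted per cluster, its normal oriented
    toward the removed segment. The plane offsets are accurate to roughly
    half a voxel because face midpoints, not voxel centers, are fitted.
    """
    _require_same_frame(preop.frame, postop_registered.frame, "fit_cut_planes")
    removed = preop.mask & ~postop_registered.mask
    if not removed.any():
        raise ValueError("no resection detected: postoperative mask covers the preop bone")
    midpoints, normals = _cut_interface(preop, removed)
    if len(midpoints) == 0:
        raise ValueError("no resection detected: removed material is detached from residual bone")

    if n_planes == 1:
        labels = np.zeros(len(midpoints), dtype=int)
    else:
        feats = np.hstack([midpoints, normal_weight_mm * normals])
        _, labels = kmeans2(feats, n_planes, minit="++", seed=seed)

    planes = []
    for lbl in range(n_planes):
        sel = labels == lbl
        if sel.sum() < 3:
            continue
        planes.append(_fit_plane(midpoints[sel], normals[sel].mean(axis=0)))
    if not planes:
        raise ValueError("plane fitting failed: no cluster had enough cut-surface faces")
    return ResectionSpec(planes=planes, mode="halfspace")


def apply_resection(
    mandible: BinaryVolume, spec: ResectionSpec
) -> tuple[BinaryVolume, BinaryVolume]:
    """Split the mandible mask into (resected, residual) along the cut planes.

    The split is an exact voxel partition: every mandible voxel lands in
    exactly one of the two outputs, so resected + residual volumes always sum
    to the mandible volume. Voxel membership is decided by the voxel center's
    signed distance to each plane (centers exactly on a plane stay residual).
    An empty resected segment is returned as-is with a warning.
    """
    import warnings

    frame = mandible.frame
    x, y, z = frame.coordinate_grids()

    def _signed(plane):
        px, py, pz = plane.point
        nx_, ny_, nz_ = plane.normal
        return (x - px) * nx_ + (y - py) * ny_ + (z - pz) * nz_

    if spec.mode == "halfspace":
        resected_mask = mandible.mask.copy()
        for plane in spec.planes:
            resected_mask &= _signed(plane) > 0
    else:  # seed mode: planes are pure cuts
        seed_idx = np.round(frame.physical_to_index(spec.seed_point)[0]).astype(int)
        if (
            np.any(seed_idx < 0)
            or np.any(seed_idx >= np.asarray(frame.shape))
            or not mandible.mask[tuple(seed_idx)]
        ):
            raise ValueError("seed point must lie inside the mandible mask")
        # voxels are connected only if they share the side of every plane
        sign_code = np.zeros(frame.shape, dtype=np.int64)
        for i, plane in enumerate(spec.planes):
            sign_code |= np.broadcast_to(_signed(plane) > 0, frame.shape).astype(np.int64) << i
        seed_code = sign_code[tuple(seed_idx)]
        candidate = mandible.mask & (sign_code == seed_code)
        labels, _ = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=int))
        resected_mask = labels == labels[tuple(seed_idx)]

    if not resected_mask.any():
        warnings.warn("resection removed no voxels (planes outside the mandible)")
    residual_mask = mandible.mask & ~resected_mask
    return (
        BinaryVolume(frame=frame, mask=resected_mask),
        BinaryVolume(frame=frame, mask=residual_mask),
    )


# --------------------------------------------------------------------------
# Arch midline and cortical classification
# --------------------------------------------------------------------------


class ArchMidline:
    """Midline curve of the mandibular arch, used to tell lingual from buccal.

    Built by skeletonizing the axial projection of the mandible mask to a
    one-pixel curve and describing it in polar form ``radius(angle)`` about
    the arch's fitted circle center. The lingual (tongue) side is the concave
    side of the arch — radially inside the midline; buccal is outside.
    """

    def __init__(
        self,
        center_xy: np.ndarray,
        angles: np.ndarray,
        radii: np.ndarray,
        angle_offset: float = 0.0,
        bin_width_rad: float = np.radians(10.0),
    ):
        angles = np.asarray(angles, dtype=float)
        radii = np.asarray(radii, dtype=float)
        self.center_xy = np.asarray(center_xy, dtype=float)
        self.angle_offset = float(angle_offset)
        if len(angles) < 3:
            raise ValueError("degenerate midline: fewer than 3 skeleton points")
        # condense to a per-angle-bin median radius: this both smooths the
        # raw skeleton and prunes radial spurs at the arc ends; a genuinely
        # self-intersecting midline shows up as a wide in-bin radius spread
        n_bins = max(4, int(np.ceil((angles.max() - angles.min()) / bin_width_rad)))
        edges = np.linspace(angles.min(), angles.max(), n_bins + 1)
        which = np.clip(np.digitize(angles, edges) - 1, 0, n_bins - 1)
        centers, medians = [], []
        for b in range(n_bins):
            sel = which == b
            if sel.sum() == 0:
                continue
            r_bin = radii[sel]
            if sel.sum() >= 4:
                q25, q75 = np.percentile(r_bin, [25, 75])
                if q75 - q25 > 0.5 * np.median(radii):
                    raise ValueError(
                        "degenerate midline: radius is multivalued (self-intersection?)"
                    )
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            medians.append(np.median(r_bin))
        if len(centers) < 3:
            raise ValueError("degenerate midline: arc too short")
        self.angles = np.asarray(centers)
        self.radii = np.asarray(medians)

    @classmethod
    def from_mask(cls, mandible: BinaryVolume) -> "ArchMidline":
        from skimage.morphology import skeletonize

        frame = mandible.frame
        if not frame.is_axis_aligned():
            raise NotImplementedError("midline extraction requires an axis-aligned frame")
        mip = mandible.mask.any(axis=2)
        skel = skeletonize(mip)
        idx = np.argwhere(skel).astype(float)
        if len(idx) < 3:
            raise ValueError("degenerate midline: skeleton too short")
        xy = (
            idx * np.asarray(frame.spacing[:2])
            + np.asarray(frame.origin[:2])
        )
        center = _fit_circle(xy)
        rel = xy - center
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        radii = np.linalg.norm(rel, axis=1)
        # the arch is an open arc: re-zero the angle at the largest angular
        # gap so the parameterization never wraps across the arc itself
        ts = np.sort(theta)
        gaps = np.diff(np.concatenate([ts, [ts[0] + 2 * np.pi]]))
        cut = int(np.argmax(gaps))
        offset = ts[(cut + 1) % len(ts)] if cut + 1 < len(ts) else ts[0]
        shifted = np.mod(theta - offset, 2 * np.pi)
        return cls(center, shifted, radii, angle_offset=offset)

    def midline_radius(self, angle: np.ndarray) -> np.ndarray:
        """Midline radius (mm from arch center) at re-zeroed angle(s)."""
        return np.interp(angle, self.angles, self.radii)

    def side_of(self, points_mm: np.ndarray) -> np.ndarray:
        """+1 for lingual (concave side), -1 for buccal, per point (x, y, z)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))[:, :2]
        rel = pts - self.center_xy
        angle = np.mod(np.arctan2(rel[:, 1], rel[:, 0]) - self.angle_offset, 2 * np.pi)
        r = np.linalg.norm(rel, axis=1)
        return np.where(r < self.midline_radius(angle), 1, -1)


def _fit_circle(xy: np.ndarray) -> np.ndarray:
    """Algebraic (Kasa) least-squares circle fit; returns the center."""
    A = np.column_stack([2 * xy[:, 0], 2 * xy[:, 1], np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2]


def cortical_shell(mandible: BinaryVolume, shell_mm: float = 2.0) -> BinaryVolume:
    """Outer ``shell_mm`` of the mandible mask — a proxy for cortical bone."""
    frame = mandible.frame
    dist = ndimage.distance_transform_edt(mandible.mask, sampling=frame.spacing)
    return BinaryVolume(frame=frame, mask=mandible.mask & (dist <= shell_mm))


def classify_osteotomy(
    plane: ResectionPlane,
    vm56: BinaryVolume,
    mandible: BinaryVolume,
    shell_mm: float = 2.0,
    midline: ArchMidline | None = None,
) -> CorticalClassification:
    """Classify one osteotomy plane against the 56 Gy mandibular volume.

    Voxels of Vm56 lying within half a voxel diagonal of the plane (so the
    plane cannot slip between voxel centers) and within the outer cortical
    shell of the mandible are assigned lingual or buccal by their radial
    position relative to the arch midline. Contact areas are estimated from
    the voxel count in the plane slab divided by the slab thickness.
    """
    _require_same_frame(vm56.frame, mandible.frame, "classify_osteotomy")
    frame = mandible.frame
    if midline is None:
        midline = ArchMidline.from_mask(mandible)

    half_diag = 0.5 * float(np.linalg.norm(frame.spacing))
    shell = cortical_shell(mandible, shell_mm)
    candidates = vm56.mask & shell.mask
    if not candidates.any():
        return CorticalClassification("outside", 0.0, 0.0)

    idx = np.argwhere(candidates).astype(float)
    pts = frame.index_to_physical(idx)
    in_slab = np.abs(plane.signed_distance(pts)) <= half_diag
    if not in_slab.any():
        return CorticalClassification("outside", 0.0, 0.0)

    sides = midline.side_of(pts[in_slab])
    voxel_vol = frame.voxel_volume_mm3
    slab_thickness = 2.0 * half_diag
    lingual_area = float(np.sum(sides > 0)) * voxel_vol / slab_thickness
    buccal_area = float(np.sum(sides < 0)) * voxel_vol / slab_thickness
    return CorticalClassification(
        _category_from_areas(lingual_area, buccal_area), lingual_area, buccal_area
    )


def classify_resection_without_cut(
    vm56_residual: BinaryVolume,
) -> CorticalClassification:
    """Convention for resections with no bone cut (e.g. condylectomy only):
    if irradiated mandibular bone (Vm56) survives the surgery, the case counts
    as bicortical involvement, with the residual Vm56 surface standing in for
    the contact area on both cortices."""
    if not vm56_residual.mask.any():
        return CorticalClassification("outside", 0.0, 0.0)
    # surface area estimate: exposed voxel faces / 2 per cortex
    mask = vm56_residual.mask
    frame = vm56_residual.frame
    spacing = np.asarray(frame.spacing)
    area = 0.0
    for shift, face_area in [
        ((1, 0, 0), spacing[1] * spacing[2]),
        ((0, 1, 0), spacing[0] * spacing[2]),
        ((0, 0, 1), spacing[0] * spacing[1]),
    ]:
        padded = np.pad(mask, 1)
        diff = padded ^ np.roll(padded, shift, axis=(0, 1, 2))
        area += float(diff.sum()) * face_area
    half = area / 2.0
    return CorticalClassification("bicortical", half / 2.0, half / 2.0)
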