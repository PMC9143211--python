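"""Synthetic phantoms, dose fields, cases and cohorts.

Patient imaging of this kind (RT planning CT, RTDOSE, RTSTRUCT, post-operative
models) is rarely shareable, so every stage of the pipeline is exercised on
synthetic data with known ground truth instead:

* a **horseshoe phantom** — a circular-arc tube mimicking the mandibular
  arch, with a closed-form volume (Pappus: ``pi * r_tube^2 * R * arc``) and a
  two-level HU image (bone vs soft tissue);
* a **Gaussian point-source dose field** — not a beam model, just a smooth
  monotone field whose >= 56 Gy fraction of the bone is controllable, which is
  all the analysis needs;
* **two-plane segmental resections** perpendicular to the arch.

Ground-truth volume metrics for a generated case are computed by direct
analytic membership tests on a 4x-finer voxel grid, which serves as the
oracle the standard-resolution pipeline is checked against.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .core import BinaryVolume, ContourSet, DoseGrid, ImageFrame
from .metrics_stats import METRIC_FIELDS, VolumeMetrics
from .resection import ResectionPlane, ResectionSpec

__all__ = [
    "PhantomSpec",
    "DoseFieldSpec",
    "CohortSpec",
    "SyntheticCase",
    "make_phantom",
    "make_dose",
    "make_case",
    "make_cohort",
    "draw_case",
    "write_case_dicom",
]


# --------------------------------------------------------------------------
# Phantom geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of a synthetic bone phantom.

    ``sphere``: ball of ``radius_mm`` at ``center_mm``. ``horseshoe``:
    circular-arc tube in the axial plane through ``center_mm``, arch radius
    ``arch_radius_mm``, tube radius ``tube_radius_mm``, spanning
    ``arc_span_deg`` symmetric about the +x direction.
    """

    shape: Literal["sphere", "horseshoe"] = "horseshoe"
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_mm: float = 10.0
    arch_radius_mm: float = 30.0
    tube_radius_mm: float = 9.0
    arc_span_deg: float = 240.0
    hu_inside: float = 1200.0
    hu_outside: float = -1000.0

    def __post_init__(self) -> None:
        if self.shape == "sphere":
            if self.radius_mm <= 0:
                raise ValueError("sphere radius must be positive")
        else:
            if self.tube_radius_mm <= 0 or self.arch_radius_mm <= 0:
                raise ValueError("radii must be positive")
            if not (0.0 < self.arc_span_deg < 360.0):
                raise ValueError("arc span must be in (0, 360) degrees")
            if self.tube_radius_mm >= self.arch_radius_mm:
                raise ValueError("tube radius >= arch radius: the tube self-intersects")

    @property
    def analytic_volume_ml(self) -> float:
        if self.shape == "sphere":
            return 4.0 / 3.0 * math.pi * self.radius_mm**3 / 1000.0
        arc_length = self.arch_radius_mm * math.radians(self.arc_span_deg)
        return math.pi * self.tube_radius_mm**2 * arc_length / 1000.0

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Analytic membership test at arbitrary points (mm)."""
        cx, cy, cz = self.center_mm
        if self.shape == "sphere":
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= self.radius_mm**2
        rho = np.hypot(x - cx, y - cy)
        phi = np.arctan2(y - cy, x - cx)
        in_arc = np.abs(phi) <= math.radians(self.arc_span_deg) / 2.0
        in_tube = (rho - self.arch_radius_mm) ** 2 + (z - cz) ** 2 <= self.tube_radius_mm**2
        return in_arc & in_tube

    def arch_point(self, angle_rad: float) -> np.ndarray:
        """Point on the arch centerline at the given angle."""
        cx, cy, cz = self.center_mm
        R = self.arch_radius_mm
        return np.array([cx + R * math.cos(angle_rad), cy + R * math.sin(angle_rad), cz])

    def arch_tangent(self, angle_rad: float) -> np.ndarray:
        """Unit tangent of the centerline, pointing toward increasing angle."""
        return np.array([-math.sin(angle_rad), math.cos(angle_rad), 0.0])

    def default_frame(self, spacing_mm: float = 1.0, margin_mm: float = 5.0) -> ImageFrame:
        if self.shape == "sphere":
            half = self.radius_mm + margin_mm
            half_xyz = np.array([half, half, half])
        else:
            half_xy = self.arch_radius_mm + self.tube_radius_mm + margin_mm
            half_xyz = np.array([half_xy, half_xy, self.tube_radius_mm + margin_mm])
        n = np.ceil(2 * half_xyz / spacing_mm).astype(int)
        origin = np.asarray(self.center_mm) - (n - 1) / 2.0 * spacing_mm
        return ImageFrame(
            origin=tuple(origin), spacing=(spacing_mm,) * 3, shape=tuple(int(v) for v in n)
        )


def _refine_frame(frame: ImageFrame, factor: int) -> ImageFrame:
    """Subdivide every voxel ``factor``x per axis, covering the same extent."""
    spacing = np.asarray(frame.spacing) / factor
    shift = (np.asarray(frame.spacing) - spacing) / 2.0
    origin = np.asarray(frame.origin) - frame.direction_matrix @ shift
    return ImageFrame(
        origin=tuple(origin),
        spacing=tuple(spacing),
        direction=frame.direction,
        shape=tuple(int(n) * factor for n in frame.shape),
    )


def make_phantom(
    spec: PhantomSpec,
    frame: ImageFrame | None = None,
    spacing_mm: float = 1.0,
) -> tuple[np.ndarray, ImageFrame, float]:
    """Rasterize a phantom to a two-level HU image.

    Returns ``(hu_volume, frame, analytic_volume_ml)``; the closed-form
    volume (sphere, or Pappus' theorem for the arc tube) is exact for
    non-self-intersecting shapes. An empty rasterization (phantom outside
    the frame) only warns.
    """
    if frame is None:
        frame = spec.default_frame(spacing_mm)
    x, y, z = frame.coordinate_grids()
    inside = np.broadcast_to(spec.contains(x, y, z), frame.shape)
    if not inside.any():
        warnings.warn("phantom does not intersect the frame: empty rasterization")
    hu = np.where(inside, spec.hu_inside, spec.hu_outside)
    return hu, frame, spec.analytic_volume_ml


# --------------------------------------------------------------------------
# Dose fields
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseFieldSpec:
    """Analytic dose field.

    ``linear_ramp``: ``dose = offset + gradient . x`` (clipped at 0).
    ``point_source``: ``dose = peak * exp(-|x - focus|^2 / (2 sigma^2))``;
    the peak is constrained to the 56-72 Gy prescription envelope.
    """

    model: Literal["linear_ramp", "point_source"] = "point_source"
    gradient_gy_per_mm: tuple[float, float, float] = (0.0, 0.0, 1.0)
    offset_gy: float = 0.0
    focus_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    peak_gy: float = 66.0
    sigma_mm: float = 25.0

    def __post_init__(self) -> None:
        if self.model == "point_source":
            if not (56.0 <= self.peak_gy <= 72.0):
                raise ValueError(
                    f"peak dose {self.peak_gy} Gy outside the 56-72 Gy prescription envelope"
                )
            if self.sigma_mm <= 0:
                raise ValueError("falloff scale must be positive")

    def evaluate(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        if self.model == "linear_ramp":
            g = self.gradient_gy_per_mm
            return np.maximum(self.offset_gy + g[0] * x + g[1] * y + g[2] * z, 0.0)
        fx, fy, fz = self.focus_mm
        d2 = (x - fx) ** 2 + (y - fy) ** 2 + (z - fz) ** 2
        return self.peak_gy * np.exp(-d2 / (2.0 * self.sigma_mm**2))

    def radius_at_dose(self, dose_gy: float) -> float:
        """Distance from the focus at which a point-source field drops to
        ``dose_gy`` (0 if the peak never reaches it)."""
        if self.model != "point_source" or dose_gy > self.peak_gy:
            return 0.0
        return self.sigma_mm * math.sqrt(2.0 * math.log(self.peak_gy / dose_gy))


def make_dose(spec: DoseFieldSpec, frame: ImageFrame) -> DoseGrid:
    """Sample an analytic dose field at the voxel centers of ``frame``."""
    x, y, z = frame.coordinate_grids()
    return DoseGrid(frame=frame, values=np.broadcast_to(spec.evaluate(x, y, z), frame.shape))


# --------------------------------------------------------------------------
# Full cases with fine-grid ground truth
# --------------------------------------------------------------------------


@dataclass
class SyntheticCase:
    """One generated patient: image data plus analytic specs and ground truth."""

    phantom: PhantomSpec
    dose_spec: DoseFieldSpec
    resection: ResectionSpec | None
    ptv_dose_gy: float
    frame: ImageFrame
    hu: np.ndarray
    dose: DoseGrid
    ground_truth: VolumeMetrics
    case_dir: Path | None = None


def _membership_metrics(
    frame: ImageFrame,
    phantom: PhantomSpec,
    dose_spec: DoseFieldSpec,
    resection: ResectionSpec | None,
    ptv_dose_gy: float,
) -> VolumeMetrics:
    """Volume metrics by direct analytic membership counts on ``frame``."""
    x, y, z = frame.coordinate_grids()
    mand = np.broadcast_to(phantom.contains(x, y, z), frame.shape)
    dose = dose_spec.evaluate(x, y, z)
    v56 = np.broadcast_to(dose >= 56.0, frame.shape)
    ptv = np.broadcast_to(dose >= ptv_dose_gy, frame.shape)
    if resection is not None:
        if resection.mode != "halfspace":
            raise NotImplementedError("analytic ground truth supports halfspace resections")
        resected = mand.copy()
        for plane in resection.planes:
            px, py, pz = plane.point
            nx_, ny_, nz_ = plane.normal
            d = (x - px) * nx_ + (y - py) * ny_ + (z - pz) * nz_
            resected = resected & (d > 0)
    else:
        resected = np.zeros(frame.shape, dtype=bool)
    residual = mand & ~resected

    vox_ml = frame.voxel_volume_mm3 / 1000.0

    def ml(m: np.ndarray) -> float:
        return float(m.sum()) * vox_ml

    vm = ml(mand)

    def pct(v: float) -> float:
        return 100.0 * v / vm if vm > 0 else 0.0

    vm56, vmptv, vmr = ml(mand & v56), ml(mand & ptv), ml(resected)
    return VolumeMetrics(
        Vm=vm,
        V56=ml(v56),
        V_PTV=ml(ptv),
        Vm56=vm56,
        Vm_PTV=vmptv,
        VmR=vmr,
        Vm56R=ml(residual & v56),
        Vm_PTV_R=ml(residual & ptv),
        Vm56_over_Vm=pct(vm56),
        Vm_PTV_over_Vm=pct(vmptv),
        VmR_over_Vm=pct(vmr),
    )


def make_case(
    phantom: PhantomSpec,
    dose_spec: DoseFieldSpec,
    resection: ResectionSpec | None = None,
    ptv_dose_gy: float = 60.0,
    spacing_mm: float = 1.0,
    fine_factor: int = 4,
    write_dir: str | Path | None = None,
    seed: int = 0,
) -> SyntheticCase:
    """Assemble a full synthetic case.

    The ground-truth metric record is computed by analytic membership counts
    on a ``fine_factor``x finer voxel grid covering the same extent. With
    ``write_dir`` given, DICOM fixtures (CT series, RTDOSE, RTSTRUCT with
    mandible and PTV contours), a planes CSV and a ground-truth JSON are
    written for the I/O layer.
    """
    frame = phantom.default_frame(spacing_mm)
    hu, frame, _ = make_phantom(phantom, frame=frame)
    dose = make_dose(dose_spec, frame)
    fine = _refine_frame(frame, fine_factor)
    truth = _membership_metrics(fine, phantom, dose_spec, resection, ptv_dose_gy)

    case = SyntheticCase(
        phantom=phantom,
        dose_spec=dose_spec,
        resection=resection,
        ptv_dose_gy=ptv_dose_gy,
        frame=frame,
        hu=hu,
        dose=dose,
        ground_truth=truth,
    )
    if write_dir is not None:
        case.case_dir = Path(write_dir)
        write_case_dicom(case, case.case_dir, seed=seed)
    return case


def case_pipeline_metrics(case: SyntheticCase) -> VolumeMetrics:
    """Run the standard-resolution analysis pipeline on an in-memory case."""
    from .metrics_stats import compute_metrics
    from .volumetrics import isodose_region, segment_bone

    mandible = segment_bone(case.hu, case.frame, hu_threshold=300.0)
    iso56 = isodose_region(case.dose, 56.0)
    ptv = isodose_region(case.dose, case.ptv_dose_gy)
    return compute_metrics(mandible, iso56, ptv, case.resection)


# --------------------------------------------------------------------------
# Randomized case drawing
# --------------------------------------------------------------------------


def _tilted_normal(phantom: PhantomSpec, angle: float, sign: float, tilt_rad: float) -> np.ndarray:
    """Arch tangent at ``angle`` tilted out of the axial plane about the
    radial direction (osteotomies are rarely perfectly vertical)."""
    t = sign * phantom.arch_tangent(angle)
    radial = np.array([math.cos(angle), math.sin(angle), 0.0])
    c, s = math.cos(tilt_rad), math.sin(tilt_rad)
    # Rodrigues rotation of t about the radial axis
    n = t * c + np.cross(radial, t) * s + radial * np.dot(radial, t) * (1 - c)
    return n / np.linalg.norm(n)


def _wedge_resection(
    phantom: PhantomSpec,
    angle_lo: float,
    angle_hi: float,
    tilt_lo_rad: float = 0.0,
    tilt_hi_rad: float = 0.0,
) -> ResectionSpec:
    """Two cut planes transversal to the arch, removing the angular wedge
    ``[angle_lo, angle_hi]`` (radians; wedge must subtend < 180 deg).
    Optional tilts rock each plane out of the vertical about the local
    radial direction."""
    if not angle_lo < angle_hi:
        raise ValueError("need angle_lo < angle_hi")
    if angle_hi - angle_lo >= math.pi:
        raise ValueError("wedge must subtend less than 180 degrees")
    p1 = ResectionPlane(
        point=tuple(phantom.arch_point(angle_lo)),
        normal=tuple(_tilted_normal(phantom, angle_lo, +1.0, tilt_lo_rad)),
    )
    p2 = ResectionPlane(
        point=tuple(phantom.arch_point(angle_hi)),
        normal=tuple(_tilted_normal(phantom, angle_hi, -1.0, tilt_hi_rad)),
    )
    return ResectionSpec(planes=[p1, p2], mode="halfspace")


def draw_case(
    rng: np.random.Generator,
    spacing_mm: float = 0.85,
    fine_factor: int = 4,
    target_vm_ml: float | None = None,
    write_dir: str | Path | None = None,
) -> SyntheticCase:
    """Draw one random synthetic case.

    Geometry and dose are drawn so the case resembles the cohort the analysis
    is meant for: a mandible-sized horseshoe (roughly 27-60 mL), a 56-72 Gy
    Gaussian dose focus on the arch, and a two-plane segmental resection.
    Two resection scenarios occur: a *bracketing* resection that removes the
    >= 56 Gy bone entirely (with >= 3 mm geometric margin, so the residual
    irradiated volumes are exactly zero), and a *partial* resection cutting
    through the >= 56 Gy region. Degenerate cases — any nonzero metric below
    2.5 mL on the fine grid, a scale at which voxel counting is dominated by
    surface ambiguity — are redrawn.
    """
    for _ in range(200):
        span_deg = rng.uniform(220.0, 275.0)
        R = rng.uniform(28.0, 35.0)
        if target_vm_ml is None:
            r_tube = rng.uniform(9.0, 11.5)
        else:
            arc = R * math.radians(span_deg)
            r_tube = float(np.clip(math.sqrt(target_vm_ml * 1000.0 / (math.pi * arc)), 8.0, 13.0))
        phantom = PhantomSpec(
            shape="horseshoe",
            arch_radius_mm=R,
            tube_radius_mm=r_tube,
            arc_span_deg=span_deg,
        )
        half_span = math.radians(span_deg) / 2.0

        peak = rng.uniform(62.0, 72.0)
        bracket = rng.random() < 0.3
        d56 = rng.uniform(10.5, 12.0) if bracket else rng.uniform(11.0, 16.0)
        sigma = d56 / math.sqrt(2.0 * math.log(peak / 56.0))
        if not (8.0 <= sigma <= 32.0):
            continue
        d_ptv = rng.uniform(9.0, d56 - 1.0)
        ptv_dose = peak * math.exp(-(d_ptv**2) / (2.0 * sigma**2))

        phi_f = rng.uniform(-0.3, 0.3)  # focus angle on the arch (rad)
        mirror = rng.random() < 0.5
        focus = phantom.arch_point(phi_f)
        dose_spec = DoseFieldSpec(
            model="point_source", focus_mm=tuple(focus), peak_gy=peak, sigma_mm=sigma
        )

        def chord_angle(dist: float) -> float:
            # arch angle subtending a straight-line distance `dist` from a
            # centerline point (clipped if unreachable)
            s = min(dist / (2.0 * R), 0.999)
            return 2.0 * math.asin(s)

        if bracket:
            beta = chord_angle(d56 + r_tube + 6.0) + math.radians(3.0)
            lo, hi = phi_f - beta, phi_f + beta
        else:
            delta = chord_angle(rng.uniform(0.0, 3.0))
            beta_far = chord_angle(d56 + r_tube + 6.0) + math.radians(3.0)
            lo, hi = phi_f + delta, phi_f + delta + beta_far
            if mirror:
                lo, hi = phi_f - delta - beta_far, phi_f - delta
        margin = math.radians(4.0)
        if lo < -half_span + margin or hi > half_span - margin:
            continue
        if hi - lo >= math.pi:
            continue
        tilts = rng.uniform(math.radians(5.0), math.radians(14.0), size=2)
        tilts *= rng.choice([-1.0, 1.0], size=2)
        resection = _wedge_resection(phantom, lo, hi, tilts[0], tilts[1])

        case = make_case(
            phantom,
            dose_spec,
            resection,
            ptv_dose_gy=float(ptv_dose),
            spacing_mm=spacing_mm,
            fine_factor=fine_factor,
        )
        gt = case.ground_truth.as_dict()
        ml_fields = ["Vm", "V56", "V_PTV", "Vm56", "Vm_PTV", "VmR", "Vm56R", "Vm_PTV_R"]
        if any(0.0 < gt[f] < 2.5 for f in ml_fields):
            continue
        if any(gt[f] <= 0.0 for f in ["Vm", "V56", "V_PTV", "Vm56", "Vm_PTV", "VmR"]):
            continue
        if write_dir is not None:
            # write fixtures only for the accepted draw, never for rejected ones
            case.case_dir = Path(write_dir)
            write_case_dicom(case, case.case_dir)
        return case
    raise RuntimeError("failed to draw a valid synthetic case in 200 attempts")


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort generator settings.

    Defaults emulate the study structure the analysis targets: 5 recurrent
    vs 28 non-recurrent patients, with group-dependent mandible and
    irradiated-volume distributions (recurrent mandibles smaller on average).
    ``parametric`` sampling draws the metric table directly from those
    distributions (cheap, for statistical simulations); ``voxel`` sampling
    builds and measures an actual phantom per patient.
    """

    n_recurrent: int = 5
    n_nonrecurrent: int = 28
    seed: int = 0
    sampling: Literal["parametric", "voxel"] = "parametric"
    spacing_mm: float = 1.5
    # group parameter table: mean/sd pairs per metric primitive
    vm_recurrent: tuple[float, float] = (47.8, 10.0)
    vm_nonrecurrent: tuple[float, float] = (65.4, 15.0)
    vm56_recurrent: tuple[float, float] = (10.9, 5.0)
    vm56_nonrecurrent: tuple[float, float] = (30.7, 8.0)
    vmr_frac_recurrent: tuple[float, float] = (0.26, 0.10)
    vmr_frac_nonrecurrent: tuple[float, float] = (0.37, 0.10)

    def __post_init__(self) -> None:
        if self.n_recurrent < 2 or self.n_nonrecurrent < 2:
            raise ValueError("need n >= 2 per group")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


_PLANE_CATEGORY_P = {
    # per-plane cortical involvement frequencies by group
    "recurrent": {"outside": 0.25, "lingual_only": 0.125, "bicortical": 0.625},
    "nonrecurrent": {"outside": 12 / 52, "lingual_only": 9 / 52, "bicortical": 31 / 52},
}


def _parametric_patient(rng: np.random.Generator, spec: CohortSpec, group: str) -> dict:
    rec = group == "recurrent"
    vm = _trunc_normal(rng, *(spec.vm_recurrent if rec else spec.vm_nonrecurrent), 25.0, 95.0)
    vm56 = _trunc_normal(
        rng, *(spec.vm56_recurrent if rec else spec.vm56_nonrecurrent), 0.5, 0.85 * vm
    )
    vmptv = vm56 * rng.uniform(0.2, 0.8)
    vmr = vm * _trunc_normal(
        rng, *(spec.vmr_frac_recurrent if rec else spec.vmr_frac_nonrecurrent), 0.07, 0.78
    )
    leftover56 = _trunc_normal(rng, 0.20 if rec else 0.35, 0.15, 0.0, 0.8)
    vm56r = vm56 * leftover56
    vmptvr = vmptv * _trunc_normal(rng, 0.15, 0.15, 0.0, 0.8)
    v56 = vm56 * _trunc_normal(rng, 28.0, 8.0, 5.0, 50.0)
    vptv = min(vmptv * _trunc_normal(rng, 24.0, 8.0, 3.0, 50.0), v56)
    vptv = max(vptv, vmptv)
    return dict(
        Vm=vm, V56=v56, V_PTV=vptv, Vm56=vm56, Vm_PTV=vmptv,
        VmR=vmr, Vm56R=vm56r, Vm_PTV_R=vmptvr,
        Vm56_over_Vm=100 * vm56 / vm,
        Vm_PTV_over_Vm=100 * vmptv / vm,
        VmR_over_Vm=100 * vmr / vm,
    )


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort.

    Returns ``(metrics, planes)``: a tidy per-patient metric table (one row
    per patient, VolumeMetrics columns plus ``case_id`` and ``group``) and a
    per-plane classification table (``case_id``, ``plane_id``, ``group``,
    ``category``). Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    metric_rows, plane_rows = [], []
    patients = [("recurrent", i) for i in range(spec.n_recurrent)] + [
        ("nonrecurrent", i) for i in range(spec.n_nonrecurrent)
    ]
    for group, i in patients:
        case_id = f"{group[:3]}{i:03d}"
        if spec.sampling == "parametric":
            row = _parametric_patient(rng, spec, group)
            cats = list(_PLANE_CATEGORY_P[group])
            probs = list(_PLANE_CATEGORY_P[group].values())
            categories = rng.choice(cats, size=2, p=np.asarray(probs) / np.sum(probs))
        else:
            row, categories = _voxel_patient(rng, spec, group)
        VolumeMetrics(**{k: row[k] for k in METRIC_FIELDS}).validate()
        metric_rows.append({"case_id": case_id, "group": group} | row)
        for j, cat in enumerate(categories):
            plane_rows.append(
                {"case_id": case_id, "plane_id": j, "group": group, "category": str(cat)}
            )
    metrics = pd.DataFrame(metric_rows)
    planes = pd.DataFrame(plane_rows)
    return metrics, planes


def _voxel_patient(rng: np.random.Generator, spec: CohortSpec, group: str):
    from .resection import ArchMidline, classify_osteotomy
    from .volumetrics import isodose_region, segment_bone
    from .metrics_stats import compute_metrics

    rec = group == "recurrent"
    target_vm = _trunc_normal(
        rng, *(spec.vm_recurrent if rec else spec.vm_nonrecurrent), 27.0, 62.0
    )
    case = draw_case(rng, spacing_mm=spec.spacing_mm, target_vm_ml=target_vm)
    mandible = segment_bone(case.hu, case.frame, 300.0)
    iso56 = isodose_region(case.dose, 56.0)
    ptv = isodose_region(case.dose, case.ptv_dose_gy)
    metrics = compute_metrics(mandible, iso56, ptv, case.resection)
    midline = ArchMidline.from_mask(mandible)
    categories = [
        classify_osteotomy(plane, iso56.region, mandible, midline=midline).category
        for plane in case.resection.planes
    ]
    return metrics.as_dict(), categories


# --------------------------------------------------------------------------
# DICOM fixture writing
# --------------------------------------------------------------------------


def _uid(seed: int, tag: str) -> str:
    import pydicom.uid

    return pydicom.uid.generate_uid(entropy_srcs=[f"orndose-{seed}-{tag}"])


def _base_dataset(sop_class_uid: str, sop_instance_uid: str):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = sop_instance_uid
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = "SYN000"
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    return ds


def write_ct_series(
    frame: ImageFrame, hu: np.ndarray, directory: str | Path, seed: int = 0
) -> None:
    """Write an axial DICOM CT series (one file per slice)."""
    import pydicom.uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = _uid(seed, "ct-series")
    study_uid = _uid(seed, "study")
    frame_uid = _uid(seed, "frame")
    D = frame.direction_matrix
    for k in range(frame.shape[2]):
        ds = _base_dataset(pydicom.uid.CTImageStorage, _uid(seed, f"ct-{k}"))
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = frame.shape[1], frame.shape[0]
        ds.PixelSpacing = [frame.spacing[1], frame.spacing[0]]  # row, col
        ds.SliceThickness = frame.spacing[2]
        ds.ImageOrientationPatient = [*D[:, 0], *D[:, 1]]
        ipp = np.asarray(frame.origin) + k * frame.spacing[2] * D[:, 2]
        ds.ImagePositionPatient = [float(v) for v in ipp]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.clip(np.round(hu[:, :, k].T + 1024.0), 0, 65535).astype(np.uint16)
        ds.PixelData = stored.tobytes()
        ds.save_as(directory / f"ct_{k:04d}.dcm", enforce_file_format=True)


def write_rtdose(dose: DoseGrid, file_path: str | Path, seed: int = 0) -> None:
    """Write a DICOM RTDOSE object (32-bit, scaled integers)."""
    import pydicom.uid

    frame = dose.frame
    scaling = max(dose.values.max(), 1e-6) / (2**31 - 1)
    stored = np.round(dose.values / scaling).astype(np.uint32)
    D = frame.direction_matrix

    ds = _base_dataset(pydicom.uid.RTDoseStorage, _uid(seed, "rtdose"))
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = _uid(seed, "rtdose-series")
    ds.StudyInstanceUID = _uid(seed, "study")
    ds.FrameOfReferenceUID = _uid(seed, "frame")
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = float(scaling)
    ds.NumberOfFrames = frame.shape[2]
    ds.GridFrameOffsetVector = [float(k * frame.spacing[2]) for k in range(frame.shape[2])]
    ds.Rows, ds.Columns = frame.shape[1], frame.shape[0]
    ds.PixelSpacing = [frame.spacing[1], frame.spacing[0]]
    ds.ImageOrientationPatient = [*D[:, 0], *D[:, 1]]
    ds.ImagePositionPatient = [float(v) for v in frame.origin]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.transpose(stored, (2, 1, 0)).tobytes()
    ds.save_as(file_path, enforce_file_format=True)


def contours_from_mask(volume: BinaryVolume, name: str) -> ContourSet:
    """Trace closed polygons around a mask, slice by slice (for RTSTRUCT)."""
    from skimage import measure

    frame = volume.frame
    contours: list[tuple[float, np.ndarray]] = []
    for k in range(frame.shape[2]):
        plane = volume.mask[:, :, k]
        if not plane.any():
            continue
        z = frame.origin[2] + k * frame.spacing[2]
        for poly in measure.find_contours(np.pad(plane.astype(float), 1), 0.5):
            poly = poly - 1.0  # undo padding
            xy = poly * np.asarray(frame.spacing[:2]) + np.asarray(frame.origin[:2])
            if len(xy) >= 4:
                contours.append((z, xy))
    return ContourSet(name=name, contours=contours)


def write_rtstruct(
    contour_sets: list[ContourSet], file_path: str | Path, seed: int = 0
) -> None:
    """Write a minimal DICOM RTSTRUCT carrying the given contour sets."""
    import pydicom.uid
    from pydicom.dataset import Dataset
    from pydicom.sequence import Sequence

    ds = _base_dataset(pydicom.uid.RTStructureSetStorage, _uid(seed, "rtstruct"))
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = _uid(seed, "rtstruct-series")
    ds.StudyInstanceUID = _uid(seed, "study")
    ds.StructureSetLabel = "synthetic"

    roi_seq, contour_seq = Sequence(), Sequence()
    for number, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = cs.name
        roi.ReferencedFrameOfReferenceUID = _uid(seed, "frame")
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        seq = Sequence()
        for z, poly in cs.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            data = np.column_stack([poly, np.full(len(poly), z)]).ravel()
            c.ContourData = [float(f"{v:.6f}") for v in data]
            seq.append(c)
        rc.ContourSequence = seq
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(file_path, enforce_file_format=True)


def write_case_dicom(case: SyntheticCase, directory: str | Path, seed: int = 0) -> Path:
    """Write a full case directory: CT series, RTDOSE, RTSTRUCT, planes CSV
    and ground-truth JSON."""
    from .volumetrics import isodose_region, segment_bone

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ct_series(case.frame, case.hu, directory / "ct", seed=seed)
    write_rtdose(case.dose, directory / "rtdose.dcm", seed=seed)

    mandible = segment_bone(case.hu, case.frame, 300.0)
    ptv = isodose_region(case.dose, case.ptv_dose_gy).region
    sets = [contours_from_mask(mandible, "mandible")]
    if ptv.mask.any():
        sets.append(contours_from_mask(ptv, "ptv"))
    write_rtstruct(sets, directory / "rtstruct.dcm", seed=seed)

    if case.resection is not None:
        rows = [
            {
                "case_id": "case",
                "plane_id": i,
                "px": p.point[0], "py": p.point[1], "pz": p.point[2],
                "nx": p.normal[0], "ny": p.normal[1], "nz": p.normal[2],
            }
            for i, p in enumerate(case.resection.planes)
        ]
        pd.DataFrame(rows).to_csv(directory / "planes.csv", index=False)

    truth = {
        "ptv_dose_gy": case.ptv_dose_gy,
        "metrics": case.ground_truth.as_dict(),
    }
    (directory / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return directory
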