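"""Case-level orchestration: read -> fuse -> segment -> isodose -> resect ->
measure -> classify, with structured stage logging."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .core import BinaryVolume, DoseGrid, ImageFrame
from .dicom_rt_io import (
    rasterize_contours,
    read_ct_series,
    read_rtdose,
    read_rtstruct,
    resample_dose_to_frame,
)
from .metrics_stats import VolumeMetrics, compute_metrics
from .resection import (
    ArchMidline,
    CorticalClassification,
    ResectionSpec,
    classify_osteotomy,
    read_planes_csv,
)
from .volumetrics import isodose_region, segment_bone, volume_ml

log = logging.getLogger("orndose")

__all__ = ["CaseResult", "run_case", "MissingInputError"]


class MissingInputError(FileNotFoundError):
    pass


@dataclass
class CaseResult:
    frame: ImageFrame
    mandible: BinaryVolume
    iso56: BinaryVolume
    ptv: BinaryVolume
    resected: BinaryVolume | None
    residual: BinaryVolume | None
    metrics: VolumeMetrics
    classifications: list[CorticalClassification]
    dose: DoseGrid


def _stage(name: str, started: float, **volumes) -> None:
    summary = " ".join(f"{k}={v:.1f}mL" for k, v in volumes.items())
    log.info("stage=%s wall=%.2fs %s", name, time.monotonic() - started, summary)


def run_case(
    case_dir: str | Path,
    config: PipelineConfig | None = None,
    ptv_roi: str = "ptv",
    mandible_roi: str = "mandible",
) -> CaseResult:
    """Run the full analysis on one case directory.

    Expects ``ct/`` (DICOM series), ``rtdose.dcm`` and ``rtstruct.dcm``; an
    optional ``planes.csv`` provides the osteotomy planes. Without planes,
    metrics are still computed but the resection and plane classification
    are skipped with a warning.
    """
    config = config or PipelineConfig()
    case_dir = Path(case_dir)
    ct_dir = case_dir / "ct"
    dose_path = case_dir / "rtdose.dcm"
    struct_path = case_dir / "rtstruct.dcm"
    for p in (ct_dir, dose_path, struct_path):
        if not p.exists():
            raise MissingInputError(f"missing required input: {p}")

    t0 = time.monotonic()
    frame, hu = read_ct_series(ct_dir)
    _stage("read_ct", t0)

    t0 = time.monotonic()
    dose = resample_dose_to_frame(read_rtdose(dose_path), frame)
    _stage("fuse_dose", t0)

    t0 = time.monotonic()
    mandible = segment_bone(hu, frame, config.hu_threshold)
    _stage("segment_bone", t0, Vm=volume_ml(mandible))

    t0 = time.monotonic()
    iso56 = isodose_region(dose, config.isodose_threshold_gy).region
    roi_names = [mandible_roi, ptv_roi]
    try:
        contour_sets = read_rtstruct(struct_path, roi_names)
        ptv = rasterize_contours(contour_sets[1], frame)
    except ValueError:
        # no PTV structure: an empty PTV region, not a failure
        log.warning("PTV ROI %r absent from RTSTRUCT; PTV volumes will be zero", ptv_roi)
        ptv = BinaryVolume(frame=frame, mask=(dose.values < 0))
    _stage("isodose", t0, V56=volume_ml(iso56), V_PTV=volume_ml(ptv))

    planes_path = case_dir / "planes.csv"
    spec: ResectionSpec | None = None
    classifications: list[CorticalClassification] = []
    if planes_path.exists():
        planes = [p for ps in read_planes_csv(planes_path).values() for p in ps]
        spec = ResectionSpec(planes=planes, mode="halfspace")
    else:
        log.warning("no planes.csv in %s: resection metrics and classification skipped", case_dir)

    t0 = time.monotonic()
    metrics = compute_metrics(mandible, iso56, ptv, spec)
    metrics.validate()
    _stage("metrics", t0, Vm56=metrics.Vm56, VmR=metrics.VmR, Vm56R=metrics.Vm56R)

    resected = residual = None
    if spec is not None:
        from .resection import apply_resection

        resected, residual = apply_resection(mandible, spec)
        t0 = time.monotonic()
        midline = ArchMidline.from_mask(mandible)
        classifications = [
            classify_osteotomy(
                plane, iso56_and_mandible(iso56, mandible), mandible,
                shell_mm=config.cortical_shell_mm, midline=midline,
            )
            for plane in spec.planes
        ]
        _stage("classify", t0)

    return CaseResult(
        frame=frame, mandible=mandible, iso56=iso56, ptv=ptv,
        resected=resected, residual=residual,
        metrics=metrics, classifications=classifications, dose=dose,
    )


def iso56_and_mandible(iso56: BinaryVolume, mandible: BinaryVolume) -> BinaryVolume:
    from .volumetrics import intersect

    return intersect(iso56, mandible)


def write_case_outputs(result: CaseResult, out_dir: str | Path,
                       config: PipelineConfig | None = None,
                       case_id: str = "case") -> None:
    """Write metrics CSV, classification CSV, meshes and the resolved config."""
    from .dicom_rt_io import save_mesh
    from .volumetrics import mesh_from_mask

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    row = {"case_id": case_id} | result.metrics.as_dict()
    pd.DataFrame([row]).to_csv(out_dir / "metrics.csv", index=False, float_format="%.4f")

    if result.classifications:
        pd.DataFrame(
            [
                {
                    "case_id": case_id,
                    "plane_id": i,
                    "category": c.category,
                    "lingual_area_mm2": round(c.lingual_area_mm2, 2),
                    "buccal_area_mm2": round(c.buccal_area_mm2, 2),
                }
                for i, c in enumerate(result.classifications)
            ]
        ).to_csv(out_dir / "classification.csv", index=False)

    for name, vol in [
        ("mandible", result.mandible),
        ("vm56", iso56_and_mandible(result.iso56, result.mandible)),
        ("residual", result.residual),
    ]:
        if vol is not None and vol.mask.any():
            save_mesh(mesh_from_mask(vol), out_dir / f"{name}.stl")

    (config or PipelineConfig()).to_yaml(out_dir / "config_resolved.yaml")
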