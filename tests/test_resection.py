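import math

import numpy as np
import pytest

from orndose.core import BinaryVolume, ImageFrame
from orndose.resection import (
    ArchMidline,
    CorticalClassification,
    ResectionPlane,
    ResectionSpec,
    RigidTransform,
    apply_resection,
    classify_osteotomy,
    classify_resection_without_cut,
    fit_cut_planes,
    read_planes_csv,
    register_rigid,
    register_two_segment,
)
from orndose.synthetic_data import DoseFieldSpec, PhantomSpec, make_dose, make_phantom
from orndose.volumetrics import intersect, isodose_region, segment_bone, volume_ml

from conftest import rotation_z


@pytest.fixture()
def cube():
    frame = ImageFrame(origin=(0.05, 0.07, 0.03), spacing=(0.5, 0.5, 0.5), shape=(80, 80, 80))
    x, y, z = frame.coordinate_grids()
    inside = (x > 2) & (x < 38) & (y > 2) & (y < 38) & (z > 2) & (z < 38)
    return BinaryVolume(frame=frame, mask=np.broadcast_to(inside, frame.shape))


class TestPlanesAndSpecs:
    def test_normal_is_normalized(self):
        p = ResectionPlane(point=(0, 0, 0), normal=(0, 0, 5.0))
        assert np.linalg.norm(p.normal) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ResectionPlane(point=(0, 0, 0), normal=(0, 0, 0))

    def test_signed_distance_positive_on_resected_side(self):
        p = ResectionPlane(point=(0, 0, 10.0), normal=(0, 0, 1.0))
        d = p.signed_distance(np.array([[0, 0, 12.0], [0, 0, 7.0]]))
        assert d[0] == pytest.approx(2.0) and d[1] == pytest.approx(-3.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ResectionSpec(planes=[], mode="halfspace")
        with pytest.raises(ValueError):
            ResectionSpec(planes=[], mode="seed", seed_point=None)

    def test_planes_csv_roundtrip(self, tmp_path):
        import pandas as pd

        rows = [
            dict(case_id="a", plane_id=0, px=1, py=2, pz=3, nx=0, ny=0, nz=1),
            dict(case_id="a", plane_id=1, px=4, py=5, pz=6, nx=0, ny=1, nz=0),
        ]
        pd.DataFrame(rows).to_csv(tmp_path / "planes.csv", index=False)
        planes = read_planes_csv(tmp_path / "planes.csv")
        assert len(planes["a"]) == 2
        assert planes["a"][1].normal == (0.0, 1.0, 0.0)
        pd.DataFrame(rows).drop(columns=["nz"]).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="nz"):
            read_planes_csv(tmp_path / "bad.csv")


class TestApplyResection:
    def test_single_plane_halves_cube(self, cube):
        plane = ResectionPlane(point=(20.0, 20.0, 20.05), normal=(0, 0, 1.0))
        resected, residual = apply_resection(cube, ResectionSpec(planes=[plane]))
        total = volume_ml(cube)
        assert volume_ml(resected) + volume_ml(residual) == pytest.approx(total)
        # cut plane and cube faces can each shift the split by one voxel layer
        layer_ml = 36 * 36 * 0.5 / 1000.0
        assert abs(volume_ml(resected) - volume_ml(residual)) <= 2 * layer_ml

    def test_plane_outside_gives_empty_resection(self, cube):
        plane = ResectionPlane(point=(0, 0, 100.0), normal=(0, 0, 1.0))
        with pytest.warns(UserWarning, match="no voxels"):
            resected, residual = apply_resection(cube, ResectionSpec(planes=[plane]))
        assert resected.voxel_count == 0
        assert residual.voxel_count == cube.voxel_count

    def test_volume_conservation_is_exact(self, horseshoe_mask):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = rng.normal(size=3)
            plane = ResectionPlane(point=tuple(rng.uniform(-20, 20, 3)), normal=tuple(n))
            resected, residual = apply_resection(
                horseshoe_mask, ResectionSpec(planes=[plane])
            )
            assert not (resected.mask & residual.mask).any()
            assert np.array_equal(resected.mask | residual.mask, horseshoe_mask.mask)

    def test_seed_mode_matches_halfspace_on_wedge(self, horseshoe_mask, horseshoe_spec):
        lo, hi = math.radians(-25), math.radians(30)
        p1 = ResectionPlane(
            point=tuple(horseshoe_spec.arch_point(lo)),
            normal=tuple(horseshoe_spec.arch_tangent(lo)),
        )
        p2 = ResectionPlane(
            point=tuple(horseshoe_spec.arch_point(hi)),
            normal=tuple(-horseshoe_spec.arch_tangent(hi)),
        )
        half_res, _ = apply_resection(horseshoe_mask, ResectionSpec(planes=[p1, p2]))
        seed = tuple(horseshoe_spec.arch_point(math.radians(0.0)))
        seed_res, _ = apply_resection(
            horseshoe_mask,
            ResectionSpec(planes=[p1, p2], mode="seed", seed_point=seed),
        )
        assert np.array_equal(half_res.mask, seed_res.mask)

    def test_seed_outside_mandible_rejected(self, horseshoe_mask):
        plane = ResectionPlane(point=(0, 0, 0), normal=(0, 0, 1))
        spec = ResectionSpec(planes=[plane], mode="seed", seed_point=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="seed point"):
            apply_resection(horseshoe_mask, spec)


class TestFitCutPlanes:
    def test_axis_aligned_slab_recovered(self, cube):
        p1 = ResectionPlane(point=(20, 20, 15.3), normal=(0, 0, 1.0))
        p2 = ResectionPlane(point=(20, 20, 24.7), normal=(0, 0, -1.0))
        _, residual = apply_resection(cube, ResectionSpec(planes=[p1, p2]))
        spec = fit_cut_planes(cube, residual, n_planes=2)
        assert len(spec.planes) == 2
        for plane in spec.planes:
            n = np.asarray(plane.normal)
            angle = math.degrees(math.acos(min(1.0, abs(n[2]))))
            assert angle < 0.5
            z0 = np.dot(plane.point, n) / n[2]
            target = 15.3 if n[2] > 0 else -24.7
            assert abs(abs(z0) - abs(target)) < 0.5

    def test_oblique_cut_recovered_within_one_degree(self, cube):
        n30 = (math.sin(math.radians(30)), 0.0, math.cos(math.radians(30)))
        plane = ResectionPlane(point=(20, 20, 22.13), normal=n30)
        _, residual = apply_resection(cube, ResectionSpec(planes=[plane]))
        spec = fit_cut_planes(cube, residual, n_planes=1)
        got = np.asarray(spec.planes[0].normal)
        angle_err = math.degrees(math.acos(np.clip(abs(np.dot(got, n30)), 0, 1)))
        offset_err = abs(np.dot(np.asarray(spec.planes[0].point) - np.asarray(plane.point), got))
        assert angle_err < 1.0
        assert offset_err < 0.5

    def test_no_resection_rejected(self, cube):
        with pytest.raises(ValueError, match="no resection"):
            fit_cut_planes(cube, cube, n_planes=1)


class TestRegistration:
    def test_identical_meshes_give_identity(self, landmark_mesh):
        res = register_rigid(landmark_mesh, landmark_mesh)
        assert res.rms_mm < 1e-6
        assert res.transform.rotation_angle_deg() < 1e-6

    def test_known_transform_recovered(self, landmark_mesh):
        import trimesh

        true = RigidTransform(rotation=tuple(map(tuple, rotation_z(15.0))),
                              translation=(5.0, -3.0, 2.0))
        moved = trimesh.Trimesh(
            vertices=true.apply(landmark_mesh.vertices),
            faces=landmark_mesh.faces, process=False,
        )
        res = register_rigid(moved, landmark_mesh)
        err = res.transform.compose(true)
        assert err.rotation_angle_deg() < 0.5
        assert np.linalg.norm(err.translation) < 0.1

    def test_partial_specimen_rms(self, landmark_mesh):
        # a ~60% angular segment of the bone, displaced, registers back on
        V = np.asarray(landmark_mesh.vertices)
        phi = np.degrees(np.arctan2(V[:, 1], V[:, 0]))
        seg = V[(phi > -20) & (phi < 120)]
        assert 0.5 < len(seg) / len(V) < 0.7
        true = RigidTransform(rotation=tuple(map(tuple, rotation_z(15.0))),
                              translation=(5.0, -3.0, 2.0))
        res = register_rigid(true.apply(seg), landmark_mesh)
        assert res.rms_mm < 0.5

    def test_two_segment_independent_recovery(self, landmark_mesh):
        V = np.asarray(landmark_mesh.vertices)
        phi = np.degrees(np.arctan2(V[:, 1], V[:, 0]))
        halves = [V[phi > 0], V[phi < 0]]
        a = math.radians(8.0)
        Rx = np.array([[1, 0, 0], [0, math.cos(a), -math.sin(a)], [0, math.sin(a), math.cos(a)]])
        trues = [
            RigidTransform(rotation=tuple(map(tuple, rotation_z(15.0))), translation=(4, 2, -1)),
            RigidTransform(rotation=tuple(map(tuple, Rx)), translation=(-3, 1, 2)),
        ]
        moved = [t.apply(h) for t, h in zip(trues, halves)]
        results = register_two_segment(moved, landmark_mesh)
        for res, true in zip(results, trues):
            err = res.transform.compose(true)
            assert err.rotation_angle_deg() < 0.5
            assert np.linalg.norm(err.translation) < 0.1

    def test_low_overlap_sets_warning(self, landmark_mesh):
        rng = np.random.default_rng(0)
        junk = rng.uniform(150, 250, (400, 3))
        res = register_rigid(junk, landmark_mesh)
        assert res.overlap_fraction < 0.1
        assert res.warning is not None


class TestMidlineAndClassification:
    def test_lingual_is_concave_side(self, horseshoe_mask, horseshoe_spec):
        midline = ArchMidline.from_mask(horseshoe_mask)
        R = horseshoe_spec.arch_radius_mm
        inner = [(R - 6) * math.cos(0.3), (R - 6) * math.sin(0.3), 0.0]
        outer = [(R + 6) * math.cos(0.3), (R + 6) * math.sin(0.3), 0.0]
        sides = midline.side_of(np.array([inner, outer]))
        assert sides[0] == 1 and sides[1] == -1

    def test_degenerate_mask_rejected(self, small_frame):
        blob = np.zeros(small_frame.shape, dtype=bool)
        blob[9:12, 9:12, 9:12] = True
        with pytest.raises((ValueError, NotImplementedError)):
            ArchMidline.from_mask(BinaryVolume(frame=small_frame, mask=blob))

    def test_classification_category_consistency(self):
        with pytest.raises(ValueError):
            CorticalClassification("outside", 10.0, 0.0)
        with pytest.raises(ValueError):
            CorticalClassification("lingual_only", 0.0, 5.0)

    @pytest.mark.parametrize("scenario", ["outside", "lingual_only", "bicortical"])
    def test_constructed_dose_focus_scenarios(self, scenario, horseshoe_spec):
        hu, frame, _ = make_phantom(horseshoe_spec, spacing_mm=1.0)
        mandible = segment_bone(hu, frame, 300.0)
        midline = ArchMidline.from_mask(mandible)
        R, r = horseshoe_spec.arch_radius_mm, horseshoe_spec.tube_radius_mm
        phic = 0.2
        plane = ResectionPlane(
            point=tuple(horseshoe_spec.arch_point(phic)),
            normal=tuple(horseshoe_spec.arch_tangent(phic)),
        )
        if scenario == "outside":
            d56, peak = 10.0, 66.0
            shift = 2 * math.asin((d56 + r + 6) / (2 * R)) + math.radians(8)
            focus = horseshoe_spec.arch_point(phic + shift)
        elif scenario == "lingual_only":
            d56, peak = 4.0, 60.0
            focus = np.array([(R - r) * math.cos(phic), (R - r) * math.sin(phic), 0.0])
        else:
            d56, peak = r + 4.0, 70.0
            focus = horseshoe_spec.arch_point(phic)
        sigma = d56 / math.sqrt(2 * math.log(peak / 56.0))
        dose = make_dose(
            DoseFieldSpec(model="point_source", focus_mm=tuple(focus),
                          peak_gy=peak, sigma_mm=sigma),
            frame,
        )
        vm56 = intersect(isodose_region(dose, 56.0).region, mandible)
        got = classify_osteotomy(plane, vm56, mandible, midline=midline)
        assert got.category == scenario

    def test_no_cut_with_residual_hot_bone_is_bicortical(self, horseshoe_mask):
        assert classify_resection_without_cut(horseshoe_mask).category == "bicortical"
        empty = BinaryVolume(
            frame=horseshoe_mask.frame,
            mask=np.zeros(horseshoe_mask.frame.shape, dtype=bool),
        )
        assert classify_resection_without_cut(empty).category == "outside"
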