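import numpy as np
import pydicom
import pytest

from orndose.core import ContourSet, DoseGrid, ImageFrame
from orndose.dicom_rt_io import (
    load_mask,
    rasterize_contours,
    read_ct_series,
    read_rtdose,
    read_rtstruct,
    resample_dose_to_frame,
    save_mask,
)
from orndose.synthetic_data import write_ct_series, write_rtdose, write_rtstruct
from orndose.volumetrics import volume_ml


@pytest.fixture()
def tiny_frame():
    return ImageFrame(origin=(-10.0, -12.0, 3.0), spacing=(2.0, 1.5, 2.5), shape=(16, 20, 3))


class TestCTSeries:
    def test_write_read_roundtrip_and_order_invariance(self, tiny_frame, tmp_path):
        rng = np.random.default_rng(0)
        hu = rng.integers(-1000, 1500, tiny_frame.shape).astype(float)
        write_ct_series(tiny_frame, hu, tmp_path / "ct")
        frame, back = read_ct_series(tmp_path / "ct")
        assert frame.approx_equal(tiny_frame, tol=1e-6)
        assert np.array_equal(back, hu)

        # shuffle on-disk order: reading must sort by patient position
        files = sorted((tmp_path / "ct").glob("*.dcm"))
        shuffled = tmp_path / "shuffled"
        shuffled.mkdir()
        for i, f in enumerate(reversed(files)):
            (shuffled / f"zz_{i}.dcm").write_bytes(f.read_bytes())
        frame2, back2 = read_ct_series(shuffled)
        assert frame2.approx_equal(frame)
        assert np.array_equal(back2, back)

    def test_mixed_series_rejected(self, tiny_frame, tmp_path):
        hu = np.zeros(tiny_frame.shape)
        write_ct_series(tiny_frame, hu, tmp_path / "ct", seed=0)
        write_ct_series(tiny_frame, hu, tmp_path / "ct2", seed=1)
        target = tmp_path / "ct"
        for f in (tmp_path / "ct2").glob("*.dcm"):
            (target / f"other_{f.name}").write_bytes(f.read_bytes())
        with pytest.raises(ValueError, match="multiple series"):
            read_ct_series(target)

    def test_inconsistent_spacing_rejected(self, tiny_frame, tmp_path):
        hu = np.zeros(tiny_frame.shape)
        write_ct_series(tiny_frame, hu, tmp_path / "ct")
        victim = sorted((tmp_path / "ct").glob("*.dcm"))[1]
        ds = pydicom.dcmread(victim)
        ds.PixelSpacing = [9.9, 9.9]
        ds.save_as(victim)
        with pytest.raises(ValueError, match="PixelSpacing"):
            read_ct_series(tmp_path / "ct")


class TestRTDose:
    def test_uniform_and_ramp_values(self, tiny_frame, tmp_path):
        uniform = DoseGrid(frame=tiny_frame, values=np.full(tiny_frame.shape, 60.0))
        write_rtdose(uniform, tmp_path / "u.dcm")
        got = read_rtdose(tmp_path / "u.dcm")
        assert got.frame.approx_equal(tiny_frame)
        assert np.allclose(got.values, 60.0, atol=1e-6)

        _, _, z = tiny_frame.coordinate_grids()
        ramp = np.broadcast_to(
            70.0 * (z - z.min()) / max(np.ptp(z), 1e-9), tiny_frame.shape
        )
        write_rtdose(DoseGrid(frame=tiny_frame, values=ramp), tmp_path / "r.dcm")
        got = read_rtdose(tmp_path / "r.dcm")
        assert got.values.max() == pytest.approx(70.0, abs=1e-5)
        assert got.values.min() == pytest.approx(0.0, abs=1e-5)

    def test_scaling_factor_definition(self, tiny_frame, tmp_path):
        # stored integers times the grid scaling give physical Gy
        dose = DoseGrid(frame=tiny_frame, values=np.full(tiny_frame.shape, 56.0))
        write_rtdose(dose, tmp_path / "d.dcm")
        ds = pydicom.dcmread(tmp_path / "d.dcm")
        stored = ds.pixel_array
        assert np.allclose(stored * float(ds.DoseGridScaling), 56.0, atol=1e-6)

    def test_missing_scaling_rejected(self, tiny_frame, tmp_path):
        dose = DoseGrid(frame=tiny_frame, values=np.zeros(tiny_frame.shape))
        write_rtdose(dose, tmp_path / "d.dcm")
        ds = pydicom.dcmread(tmp_path / "d.dcm")
        del ds.DoseGridScaling
        ds.save_as(tmp_path / "broken.dcm")
        with pytest.raises(ValueError, match="DoseGridScaling"):
            read_rtdose(tmp_path / "broken.dcm")


class TestRTStruct:
    @pytest.fixture()
    def struct_file(self, tmp_path):
        square = np.array([[0, 0], [20, 0], [20, 20], [0, 20]], dtype=float)
        mandible = ContourSet(
            name="mandible", contours=[(float(z), square) for z in range(5)]
        )
        ptv = ContourSet(name="ptv", contours=[(1.0, square * 0.5)])
        path = tmp_path / "rtstruct.dcm"
        write_rtstruct([mandible, ptv], path)
        return path

    def test_roundtrip_sorted_z(self, struct_file):
        (got,) = read_rtstruct(struct_file, ["mandible"])
        assert len(got.contours) == 5
        assert list(got.z_positions) == sorted(got.z_positions)

    def test_case_insensitive_match(self, struct_file):
        (got,) = read_rtstruct(struct_file, ["Mandible"])
        assert got.name == "mandible"

    def test_missing_roi_lists_available(self, struct_file):
        with pytest.raises(ValueError) as err:
            read_rtstruct(struct_file, ["maxilla"])
        assert "mandible" in str(err.value) and "ptv" in str(err.value)


class TestResampleDose:
    def test_identity_resampling_preserves_values(self, tiny_frame):
        rng = np.random.default_rng(1)
        dose = DoseGrid(frame=tiny_frame, values=rng.uniform(0, 70, tiny_frame.shape))
        out = resample_dose_to_frame(dose, tiny_frame)
        assert np.array_equal(out.values, dose.values)

    def test_trilinear_exact_for_affine_field(self):
        src = ImageFrame(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(10, 10, 30))
        x, y, z = src.coordinate_grids()
        dose = DoseGrid(frame=src, values=np.broadcast_to(2.0 * z + 1.0, src.shape).copy())
        target = ImageFrame(origin=(0, 0, 0.5), spacing=(1, 1, 1), shape=(10, 10, 25))
        out = resample_dose_to_frame(dose, target)
        _, _, tz = target.coordinate_grids()
        assert np.allclose(out.values, np.broadcast_to(2.0 * tz + 1.0, target.shape), atol=1e-9)

    def test_outside_support_is_zero(self):
        src = ImageFrame(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(10, 10, 10))
        dose = DoseGrid(frame=src, values=np.full(src.shape, 50.0))
        target = ImageFrame(origin=(0, 0, -10.0), spacing=(1, 1, 1), shape=(10, 10, 35))
        out = resample_dose_to_frame(dose, target)
        assert np.all(out.values[:, :, :10] == 0.0)  # 10 mm below the grid
        assert np.all(out.values[:, :, 30:] == 0.0)  # beyond the far edge
        assert np.all(out.values[:, :, 10:20] == 50.0)


def _brute_force_inside(poly: np.ndarray, px: float, py: float) -> bool:
    """Ray-casting point-in-polygon, written independently as the oracle."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


class TestRasterizeContours:
    def test_square_prism_matches_brute_force(self):
        frame = ImageFrame(origin=(-5, -5, 0), spacing=(1, 1, 1), shape=(32, 32, 4))
        square = np.array([[0.2, 0.3], [20.2, 0.3], [20.2, 20.3], [0.2, 20.3]])
        cs = ContourSet(name="sq", contours=[(float(z), square) for z in range(4)])
        vol = rasterize_contours(cs, frame)
        xs = frame.origin[0] + np.arange(32) * 1.0
        ys = frame.origin[1] + np.arange(32) * 1.0
        expected = np.array(
            [[_brute_force_inside(square, x, y) for y in ys] for x in xs]
        )
        for k in range(4):
            assert np.array_equal(vol.mask[:, :, k], expected)
        assert expected.sum() == 400  # 20x20 mm at 1 mm voxels, center-in rule

    def test_even_odd_hole_excluded(self):
        frame = ImageFrame(origin=(-5, -5, 0), spacing=(1, 1, 1), shape=(32, 32, 1))
        outer = np.array([[0.2, 0.3], [20.2, 0.3], [20.2, 20.3], [0.2, 20.3]])
        inner = np.array([[5.2, 5.3], [15.2, 5.3], [15.2, 15.3], [5.2, 15.3]])
        cs = ContourSet(name="annulus", contours=[(0.0, outer), (0.0, inner)])
        vol = rasterize_contours(cs, frame)
        assert vol.mask[:, :, 0].sum() == 400 - 100

    def test_half_spacing_tie_goes_to_lower_plane(self):
        frame = ImageFrame(origin=(0, 0, 0), spacing=(1, 1, 2.0), shape=(16, 16, 4))
        square = np.array([[0.2, 0.3], [10.2, 0.3], [10.2, 10.3], [0.2, 10.3]])
        # contour at z = 3.0: exactly midway between planes z=2 and z=4
        vol = rasterize_contours(ContourSet(name="t", contours=[(3.0, square)]), frame)
        assert vol.mask[:, :, 1].any() and not vol.mask[:, :, 2].any()

    def test_empty_contour_set_rejected(self, tiny_frame):
        with pytest.raises(ValueError, match="empty"):
            rasterize_contours(ContourSet(name="none", contours=[]), tiny_frame)

    def test_prism_volume_converges_to_analytic(self):
        # rasterized volume of a convex polygon prism approaches area x height
        tri = np.array([[0.0, 0.0], [17.0, 3.0], [5.0, 13.0]])
        area = 0.5 * abs(
            (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
            - (tri[2, 0] - tri[0, 0]) * (tri[1, 1] - tri[0, 1])
        )
        errors = []
        for spacing in (1.0, 0.5):
            nz = int(4 / spacing)
            frame = ImageFrame(
                origin=(-2, -2, 0), spacing=(spacing, spacing, spacing),
                shape=(int(24 / spacing), int(20 / spacing), nz),
            )
            cs = ContourSet(
                name="tri",
                contours=[(frame.origin[2] + k * spacing, tri) for k in range(nz)],
            )
            vol_ml = volume_ml(rasterize_contours(cs, frame))
            analytic_ml = area * nz * spacing / 1000.0
            errors.append(abs(vol_ml - analytic_ml) / analytic_ml)
        assert errors[1] <= 0.5 * errors[0] + 1e-12


class TestMaskPersistence:
    def test_nifti_roundtrip(self, tiny_frame, tmp_path):
        from orndose.core import BinaryVolume

        rng = np.random.default_rng(2)
        vol = BinaryVolume(frame=tiny_frame, mask=rng.random(tiny_frame.shape) > 0.5)
        save_mask(vol, tmp_path / "m.nii.gz")
        back = load_mask(tmp_path / "m.nii.gz")
        assert back.frame.approx_equal(tiny_frame, tol=1e-4)
        assert np.array_equal(back.mask, vol.mask)
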