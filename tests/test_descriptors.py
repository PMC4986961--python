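import math

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from fruitpheno.calibration import CalibrationScale
from fruitpheno.core_io import Scene
from fruitpheno.descriptors import (
    SPECIMEN_COLUMNS,
    assemble_records,
    measure_color,
    measure_geometry,
    prolate_spheroid_surface,
    records_to_frame,
    spheroid_volume,
)
from fruitpheno.morphology import ROLE_DISCARDED, DetectedObject, label_objects
from fruitpheno.segmentation import SegmentationMask
from fruitpheno.synthetic_scenes import generate_scene, random_scene_spec

from conftest import match_truth

SCALE_01 = CalibrationScale(
    cm_per_px=0.1, n_references_used=1, reference_diameters_px=[25.4], dispersion=0.0
)


def _object_from_bits(bits):
    objs = label_objects(SegmentationMask(bits=bits), min_area=1)
    live = [o for o in objs if o.role != ROLE_DISCARDED]
    assert len(live) == 1
    return live[0]


def _disk_object(radius, pad=10):
    n = 2 * radius + 2 * pad
    bits = np.zeros((n, n), dtype=bool)
    rr, cc = disk((n // 2, n // 2), radius)
    bits[rr, cc] = True
    return _object_from_bits(bits)


def _ellipse_object(a, b, rotation_deg=0.0, pad=12):
    n = 2 * int(max(a, b)) + 2 * pad
    bits = np.zeros((n, n), dtype=bool)
    rr, cc = ellipse(n // 2, n // 2, a, b, rotation=math.radians(rotation_deg))
    bits[rr, cc] = True
    return _object_from_bits(bits)


class TestGeometry:
    def test_disk_r50(self):
        rec = measure_geometry(_disk_object(50), SCALE_01)
        assert rec.length_cm == pytest.approx(10.0, rel=0.02)
        assert rec.width_cm == pytest.approx(10.0, rel=0.02)
        assert rec.shape_ratio == pytest.approx(1.0, abs=0.02)
        assert rec.eccentricity <= 0.05
        assert rec.solidity >= 0.98
        assert rec.length_cm >= rec.width_cm

    def test_ellipse_eccentricity(self):
        """Semi-axes 100 x 50: e = sqrt(1 - 1/4) = 0.866."""
        rec = measure_geometry(_ellipse_object(50, 100), SCALE_01)
        assert rec.eccentricity == pytest.approx(math.sqrt(3) / 2, abs=0.02)

    def test_disk_area_and_perimeter(self):
        rec = measure_geometry(_disk_object(50), SCALE_01)
        assert rec.area_cm2 == pytest.approx(math.pi * 25.0, rel=0.02)
        assert rec.perimeter_cm == pytest.approx(2 * math.pi * 5.0, rel=0.04)

    def test_revolution_solids_closed_form(self):
        # elongated fruit: L=10, W=6 -> V = (4/3) pi 5 * 3^2
        assert spheroid_volume(5, 3) == pytest.approx(188.4956, abs=0.01)
        # sphere: L=W=10 -> S = 4 pi 25
        assert prolate_spheroid_surface(5, 5) == pytest.approx(314.1593, abs=0.01)
        # prolate surface between sphere bounds
        s = prolate_spheroid_surface(5, 3)
        assert 4 * math.pi * 9 < s < 4 * math.pi * 25
        # continuity at the sphere limit
        assert prolate_spheroid_surface(5, 4.999999) == pytest.approx(
            prolate_spheroid_surface(5, 5), rel=1e-4
        )

    def test_units_scale_with_exponents(self):
        rec1 = measure_geometry(_disk_object(40), SCALE_01)
        half = CalibrationScale(
            cm_per_px=0.05, n_references_used=1, reference_diameters_px=[50], dispersion=0
        )
        rec2 = measure_geometry(_disk_object(40), half)
        assert rec2.length_cm == pytest.approx(rec1.length_cm / 2)
        assert rec2.area_cm2 == pytest.approx(rec1.area_cm2 / 4)
        assert rec2.volume_cm3 == pytest.approx(rec1.volume_cm3 / 8)

    @pytest.mark.parametrize("rot", [0, 30, 77])
    def test_rotation_invariance(self, rot):
        base = measure_geometry(_ellipse_object(45, 80), SCALE_01)
        rotated = measure_geometry(_ellipse_object(45, 80, rotation_deg=rot), SCALE_01)
        assert rotated.length_cm == pytest.approx(base.length_cm, rel=0.02)
        assert rotated.width_cm == pytest.approx(base.width_cm, rel=0.02)
        assert rotated.area_cm2 == pytest.approx(base.area_cm2, rel=0.02)

    def test_degenerate_line_object(self):
        bits = np.zeros((10, 40), dtype=bool)
        bits[5, 5:35] = True
        rec = measure_geometry(_object_from_bits(bits), SCALE_01)
        assert any("W-DEGENERATE" in w for w in rec.warnings)
        assert rec.eccentricity < 1.0
        assert rec.length_cm >= rec.width_cm > 0

    def test_isoperimetric_bound_on_batch(self, batch_result):
        for rec in batch_result.specimens + batch_result.references:
            q = 4 * math.pi * rec.area_px / rec.perimeter_px**2
            assert q <= 1.05

    def test_length_at_least_width_on_batch(self, batch_result):
        for rec in batch_result.specimens:
            assert rec.length_cm >= rec.width_cm > 0
            assert rec.shape_ratio >= 1.0
            assert 0 <= rec.eccentricity < 1
            assert 0 < rec.solidity <= 1


class TestColor:
    def _uniform_object(self, color, shape=(10, 10)):
        px = np.zeros(shape + (3,), dtype=np.uint8)
        px[:, :] = color
        bits = np.ones(shape, dtype=bool)
        return _object_from_bits(bits), Scene(pixels=px)

    def test_pure_red(self):
        obj, scene = self._uniform_object((255, 0, 0))
        c = measure_color(obj, scene)
        assert c == {
            "mean_R": 255.0,
            "mean_G": 0.0,
            "mean_B": 0.0,
            "gray_mean": 85.0,
            "color_variation": 0.0,
        }

    def test_two_point_distribution(self):
        px = np.zeros((2, 10, 3), dtype=np.uint8)
        px[0, :, 0] = 200
        px[1, :, 0] = 100
        bits = np.ones((2, 10), dtype=bool)
        c = measure_color(_object_from_bits(bits), Scene(pixels=px))
        assert c["mean_R"] == pytest.approx(150.0)
        assert c["gray_mean"] == pytest.approx(50.0)
        assert c["color_variation"] == pytest.approx(50.0 / 3)

    def test_luminance_mode(self):
        obj, scene = self._uniform_object((255, 0, 0))
        c = measure_color(obj, scene, gray_mode="luminance")
        assert c["gray_mean"] == pytest.approx(0.299 * 255)
        with pytest.raises(ValueError):
            measure_color(obj, scene, gray_mode="hsv")

    def test_gradient_fruit_matches_generator_mean(self, batch_scene, batch_result):
        """Radial colour gradient: measured gray within 1% of painted mean."""
        _, _, _, truth = batch_scene
        for rec in batch_result.specimens:
            t = match_truth(rec, truth)
            want_gray = sum(t.mean_color) / 3
            assert rec.gray_mean == pytest.approx(want_gray, rel=0.01)


class TestAssembleRecords:
    def test_counts_and_order(self, batch_scene, batch_result):
        assert len(batch_result.specimens) == 25
        assert len(batch_result.references) == 4
        assert [r.object_index for r in batch_result.specimens] == list(range(1, 26))
        # reading order: the first specimen starts in the top-left region
        first = batch_result.specimens[0]
        assert first.centroid_row <= min(r.centroid_row for r in batch_result.specimens) + 120

    def test_empty_records_give_header_only_frame(self):
        frame = records_to_frame([])
        assert list(frame.columns) == SPECIMEN_COLUMNS
        assert len(frame) == 0

    def test_rerun_is_identical(self, batch_scene):
        from fruitpheno.pipeline import RunConfig, process_scene

        _, scene, _, _ = batch_scene
        a = process_scene(scene, RunConfig(min_area=300))
        b = process_scene(scene, RunConfig(min_area=300))
        fa = records_to_frame(a.specimens)
        fb = records_to_frame(b.specimens)
        assert fa.equals(fb)
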