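"""Pedicle waist geometry, axis-offset accuracy, breach grading, summaries."""

import numpy as np
import pytest

from igtplan import evaluation as ev
from igtplan.errors import GeometryError
from igtplan.messages import RigidTransform
from igtplan.reslice import VolumeGrid
from igtplan.scene import ScrewPlan

GRADE_ORDER = {g: i for i, g in enumerate(ev.GRADES)}


def elliptic_pedicle_mask(a_w=5.0, b_w=7.0, waist_y=20.0, flare=2.0):
    """Parabolic-waist elliptic cylinder along y: waist width 2*a_w, height 2*b_w."""
    X, Y, Z = np.meshgrid(np.arange(30), np.arange(41), np.arange(36), indexing="ij")
    cx, cz = 14.5, 17.5
    a = a_w + flare * ((Y - waist_y) / 20.0) ** 2
    b = b_w + flare * ((Y - waist_y) / 20.0) ** 2
    mask = ((X - cx) / a) ** 2 + ((Z - cz) / b) ** 2 <= 1.0
    grid = VolumeGrid(mask.astype(np.uint8), (1, 1, 1), (0, 0, 0), np.eye(3))
    return grid, np.array([cx, waist_y, cz])


def axis_screw(center, direction=(0, 1, 0), diameter=4.5, length=40.0, back=20.0):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    pose = RigidTransform.from_z_axis(direction, np.asarray(center) - back * direction)
    return ScrewPlan("s", pose, diameter, length)


class TestExtractPedicleGeometry:
    def test_elliptic_cylinder_phantom_ground_truth(self):
        grid, center = elliptic_pedicle_mask()
        geo = ev.extract_pedicle_geometry(grid, side="right", level="L4")
        assert np.linalg.norm(geo.center_point - center) <= 1.0
        assert geo.width_mm == pytest.approx(10.0, abs=1.0)
        assert geo.height_mm == pytest.approx(14.0, abs=1.0)

    def test_sphere_center_recovered_in_plane(self):
        """By symmetry the in-plane centre of any coronal slice is the sphere centre."""
        X, Y, Z = np.meshgrid(*[np.arange(21)] * 3, indexing="ij")
        sphere = (X - 10) ** 2 + (Y - 10) ** 2 + (Z - 10) ** 2 <= 64
        grid = VolumeGrid(sphere.astype(np.uint8), (1, 1, 1), (0, 0, 0), np.eye(3))
        geo = ev.extract_pedicle_geometry(grid)
        assert geo.center_point[0] == pytest.approx(10.0)
        assert geo.center_point[2] == pytest.approx(10.0)

    def test_single_voxel_mask(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[2, 3, 1] = 1
        grid = VolumeGrid(data, (1, 1, 1), (0, 0, 0), np.eye(3))
        geo = ev.extract_pedicle_geometry(grid)
        assert np.allclose(geo.center_point, [2, 3, 1])
        assert geo.width_mm == 1.0
        assert geo.height_mm == 1.0

    def test_disconnected_mask_rejected_naming_count(self):
        data = np.zeros((9, 9, 9), dtype=np.uint8)
        data[1, 1, 1] = 1
        data[7, 7, 7] = 1
        grid = VolumeGrid(data, (1, 1, 1), (0, 0, 0), np.eye(3))
        with pytest.raises(GeometryError, match="2 components"):
            ev.extract_pedicle_geometry(grid)

    def test_empty_mask_rejected(self):
        grid = VolumeGrid(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1), (0, 0, 0), np.eye(3))
        with pytest.raises(GeometryError):
            ev.extract_pedicle_geometry(grid)


class TestAccuracyError:
    def test_axis_through_center_is_zero(self):
        grid, center = elliptic_pedicle_mask()
        geo = ev.extract_pedicle_geometry(grid, side="right")
        result = ev.accuracy_error(axis_screw(geo.center_point), geo)
        assert result.error_mm == pytest.approx(0.0, abs=1e-9)

    def test_pure_lateral_displacement(self):
        grid, _ = elliptic_pedicle_mask()
        geo = ev.extract_pedicle_geometry(grid, side="right")
        screw = axis_screw(geo.center_point + np.array([2.0, 0.0, 0.0]))
        result = ev.accuracy_error(screw, geo)
        assert result.ml_offset_mm == pytest.approx(2.0)
        assert result.is_offset_mm == pytest.approx(0.0)
        assert result.error_mm == pytest.approx(2.0)

    def test_left_side_flips_lateral_sign(self):
        grid, _ = elliptic_pedicle_mask()
        geo = ev.extract_pedicle_geometry(grid, side="left")
        screw = axis_screw(geo.center_point + np.array([2.0, 0.0, 0.0]))
        assert ev.accuracy_error(screw, geo).ml_offset_mm == pytest.approx(-2.0)

    def test_tilted_axis_against_line_plane_oracle(self, rng):
        """Brute-force line/plane intersection agrees for oblique axes."""
        grid, _ = elliptic_pedicle_mask()
        geo = ev.extract_pedicle_geometry(grid, side="right")
        for _ in range(10):
            direction = rng.normal(size=3)
            direction[1] = abs(direction[1]) + 0.5  # keep the AP component healthy
            direction /= np.linalg.norm(direction)
            head = geo.center_point + rng.uniform(-3, 3, 3) - 15 * direction
            screw = axis_screw(head + 15 * direction, direction, back=15.0)
            # independent solve: p = head + t*d with p_y = center_y
            t = (geo.center_point[1] - screw.head_point[1]) / direction[1]
            p = screw.head_point + t * direction
            result = ev.accuracy_error(screw, geo)
            assert result.ml_offset_mm == pytest.approx(p[0] - geo.center_point[0], abs=1e-9)
            assert result.is_offset_mm == pytest.approx(p[2] - geo.center_point[2], abs=1e-9)

    def test_parallel_axis_rejected(self):
        grid, _ = elliptic_pedicle_mask()
        geo = ev.extract_pedicle_geometry(grid)
        with pytest.raises(GeometryError, match="parallel"):
            ev.accuracy_error(axis_screw(geo.center_point, direction=(1, 0, 0)), geo)

    def test_invariant_under_common_rigid_transform(self, rng):
        from .conftest import random_rigid_transform

        grid, _ = elliptic_pedicle_mask()
        geo = ev.extract_pedicle_geometry(grid, side="right")
        screw = axis_screw(geo.center_point + np.array([1.0, 0.0, -0.5]))
        base = ev.accuracy_error(screw, geo)
        # translate both by the same vector (rotations would change the
        # anatomical axes, which are defined in world)
        shift = rng.uniform(-40, 40, 3)
        moved_geo = ev.PedicleGeometry(
            side=geo.side, level=geo.level, min_section_index=geo.min_section_index,
            center_point=geo.center_point + shift, width_mm=geo.width_mm,
            height_mm=geo.height_mm, coronal_axis=geo.coronal_axis,
        )
        moved_screw = ScrewPlan(
            "s", RigidTransform(screw.pose.rotation, screw.pose.translation + shift),
            screw.diameter, screw.length,
        )
        moved = ev.accuracy_error(moved_screw, moved_geo)
        assert moved.ml_offset_mm == pytest.approx(base.ml_offset_mm, abs=1e-9)
        assert moved.is_offset_mm == pytest.approx(base.is_offset_mm, abs=1e-9)


class TestGrading:
    def test_centered_screw_is_grade_a(self, cylinder_pedicle_mask):
        screw = axis_screw([20.0, 5.0, 20.0], diameter=4.5)
        result = ev.grade_gertzbein_robbins(screw, cylinder_pedicle_mask)
        assert result.grade == "A"
        assert result.breach_depth_mm == 0.0
        assert result.success

    @pytest.mark.parametrize("protrusion,expected", [(0.0, "A"), (1.0, "B"), (6.0, "E")])
    def test_cylinder_in_cylinder_oracle(self, cylinder_pedicle_mask, protrusion, expected):
        """Offset = R_pedicle - R_screw + protrusion gives an exact breach depth."""
        offset = 6.0 - 2.25 + protrusion
        screw = axis_screw([20.0 + offset, 5.0, 20.0], diameter=4.5)
        result = ev.grade_gertzbein_robbins(screw, cylinder_pedicle_mask)
        assert result.grade == expected
        if expected != "A":
            assert result.breach_depth_mm == pytest.approx(protrusion, abs=0.5)

    def test_grading_monotone_in_lateral_offset(self, cylinder_pedicle_mask):
        previous = -1
        for offset in np.linspace(0.0, 14.0, 29):
            screw = axis_screw([20.0 + offset, 5.0, 20.0], diameter=4.5)
            result = ev.grade_gertzbein_robbins(screw, cylinder_pedicle_mask)
            assert GRADE_ORDER[result.grade] >= previous
            previous = GRADE_ORDER[result.grade]

    def test_screw_missing_ap_span_flagged_e(self, cylinder_pedicle_mask):
        screw = axis_screw([20.0, 35.0, 20.0], length=30.0, back=-1.0)
        result = ev.grade_gertzbein_robbins(screw, cylinder_pedicle_mask)
        assert result.grade == "E"
        assert result.missed_pedicle


def make_records(grades, errors=None, method="AR", user="User1"):
    errors = errors if errors is not None else [1.0] * len(grades)
    return [
        ev.StudyRecord(
            user=user, method=method, patient="P1", level="L4",
            side="left" if i % 2 else "right", diameter=4.5, length=40.0,
            ml_offset_mm=e, is_offset_mm=0.0, error_mm=e, grade=g,
        )
        for i, (g, e) in enumerate(zip(grades, errors))
    ]


class TestSummaries:
    def test_success_percent_from_printed_grade_counts(self):
        """The published grade tallies reproduce 98% and 100% success."""
        assert ev.success_percent([35, 12, 0, 0, 1]) == 98
        assert ev.success_percent([39, 9, 0, 0, 0]) == 100

    def test_identical_errors_have_zero_spread(self):
        records = make_records(["A"] * 6, [1.5] * 6)
        summary = ev.summarize_study(records)
        method = summary.methods["AR"]
        assert method.sd_mm == 0.0
        assert method.iqr_mm == 0.0
        assert method.mean_mm == pytest.approx(1.5)

    def test_grade_counts_total_record_count(self, rng):
        grades = [str(g) for g in rng.choice(list("AABBC"), 17)]
        records = make_records(grades, rng.uniform(0, 4, 17).tolist())
        summary = ev.summarize_study(records)
        assert sum(summary.methods["AR"].grade_counts.values()) == 17

    def test_two_method_summary_runs_all_statistics(self, rng):
        records = make_records(["A"] * 10, rng.uniform(0, 3, 10).tolist(), method="AR")
        records += make_records(["A"] * 9 + ["B"], rng.uniform(0, 2, 10).tolist(), method="desktop")
        summary = ev.summarize_study(records)
        assert summary.mann_whitney is not None
        assert summary.noninferiority is not None
        assert 0 <= summary.methods["AR"].within_3mm_percent <= 100
        assert "Success" in summary.format_table()

    def test_records_csv_roundtrip(self, tmp_path, rng):
        records = make_records(["A", "B", "C"], [0.5, 1.5, 3.5])
        records[0].pose_matrix = np.eye(4).reshape(16).tolist()
        path = tmp_path / "records.csv"
        ev.write_records_csv(records, path)
        loaded = ev.read_records_csv(path)
        assert len(loaded) == 3
        assert loaded[0].grade == "A"
        assert loaded[0].pose_matrix == records[0].pose_matrix
        assert loaded[2].error_mm == pytest.approx(3.5)
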