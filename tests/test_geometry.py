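"""Test-point grid, displacement and sector-assignment geometry."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcc2vfs.geometry import (
    AREAS,
    GMDALabel,
    RetinalLocus,
    SectorScheme,
    VFTestPoint,
    build_hfa10_2_grid,
    drasdo_displace,
    field_deg_to_schematic_mm,
    map_point_to_gmda,
    mirror_left_eye,
    summarize_vfs_by_area,
)

SQRT2 = math.sqrt(2.0)
SQRT10 = math.sqrt(10.0)


class TestGrid:
    def test_has_68_points_in_three_central_groups(self, grid):
        assert len(grid) == 68
        ecc = Counter(round(p.eccentricity_deg, 6) for p in grid)
        assert ecc[round(SQRT2, 6)] == 4
        assert ecc[round(SQRT10, 6)] == 8
        assert sum(n for e, n in ecc.items() if e > round(SQRT10, 6)) == 56

    def test_most_centred_points_are_the_unit_diagonals(self, grid):
        central = {(p.x_deg, p.y_deg) for p in grid
                   if math.isclose(p.eccentricity_deg, SQRT2)}
        assert central == {(1, 1), (1, -1), (-1, 1), (-1, -1)}

    def test_coordinates_are_odd_and_within_radius(self, grid):
        for p in grid:
            assert p.x_deg % 2 == 1 or p.x_deg % 2 == -1
            assert p.y_deg % 2 != 0
            assert p.x_deg**2 + p.y_deg**2 <= 82

    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_reflection_symmetry_about_each_meridian(self, grid, axis):
        coords = {(p.x_deg, p.y_deg) for p in grid}
        flipped = {
            (-x, y) if axis == "x" else (x, -y) for x, y in coords
        }
        assert coords == flipped

    def test_sensitivities_attach_by_coordinate(self):
        grid = build_hfa10_2_grid({(1, 1): 31.0})
        by_coord = {(p.x_deg, p.y_deg): p.sensitivity_db for p in grid}
        assert by_coord[(1, 1)] == 31.0
        assert by_coord[(3, 1)] is None


class TestDegToMm:
    @pytest.mark.parametrize(
        "deg,mm",
        [(0.0, 0.0), (1.67, 0.5), (5.0, 1.5), (10.0, 3.0), (12.0, 3.6)],
    )
    def test_anchor_points_and_linear_tail(self, deg, mm):
        assert field_deg_to_schematic_mm(deg) == pytest.approx(mm)

    def test_inner_ring_overrides_use_published_locations(self):
        assert field_deg_to_schematic_mm(SQRT2) == 0.48
        assert field_deg_to_schematic_mm(SQRT10) == 0.94
        # without overrides the pure interpolant applies
        assert field_deg_to_schematic_mm(
            SQRT2, ring_overrides=None
        ) == pytest.approx(SQRT2 * 0.5 / 1.67)

    def test_negative_eccentricity_is_a_bug(self):
        with pytest.raises(ValueError):
            field_deg_to_schematic_mm(-1.0)


class TestDisplacement:
    def test_published_displaced_eccentricities(self):
        inner = drasdo_displace(VFTestPoint(1, 1))
        secondary = drasdo_displace(VFTestPoint(1, 3))
        assert inner.eccentricity_mm == pytest.approx(1.08)
        assert secondary.eccentricity_mm == pytest.approx(1.49)

    def test_displacement_is_radial_and_positive(self, grid):
        for p in grid:
            locus = drasdo_displace(p)
            expected_angle = math.degrees(
                math.atan2(-p.y_deg, p.x_deg)
            ) % 360.0
            assert locus.angle_deg == pytest.approx(expected_angle)
            undisplaced = field_deg_to_schematic_mm(p.eccentricity_deg)
            assert locus.eccentricity_mm > undisplaced

    def test_every_point_lands_inside_the_scanned_annulus(self, grid):
        for p in grid:
            ecc = drasdo_displace(p).eccentricity_mm
            assert 0.5 < ecc <= 3.0


class TestSectorAssignment:
    def test_partition_sizes_are_3_and_14_per_sector(self, grid):
        counts = Counter(
            map_point_to_gmda(drasdo_displace(p)).area for p in grid
        )
        assert counts == {
            "3_1": 3, "3_2": 3, "3_3": 3, "3_4": 3,
            "6_1": 14, "6_2": 14, "6_3": 14, "6_4": 14,
        }

    @pytest.mark.parametrize(
        "ecc,ring", [(1.08, "3"), (1.49, "3"), (1.5, "3"), (1.51, "6"), (3.0, "6")]
    )
    def test_ring_boundaries_are_half_open(self, ecc, ring):
        locus = RetinalLocus(ecc, 45.0, "superior-nasal")
        assert map_point_to_gmda(locus).ring == ring

    @pytest.mark.parametrize("ecc", [0.4, 0.5, 3.01])
    def test_out_of_annulus_loci_are_reported(self, ecc):
        locus = RetinalLocus(ecc, 45.0, "superior-nasal")
        with pytest.raises(ValueError, match="outside the scanned annulus"):
            map_point_to_gmda(locus)

    def test_field_to_retina_inversion(self):
        # superior-temporal field -> inferior-nasal retina (right eye)
        locus = drasdo_displace(VFTestPoint(5, 5))
        assert locus.quadrant == "inferior-nasal"
        assert map_point_to_gmda(locus).sector == 3

    def test_quadrant_must_match_angle(self):
        with pytest.raises(ValueError, match="inconsistent"):
            RetinalLocus(1.0, 45.0, "inferior-temporal")


class TestAreaSummary:
    def _exam(self, value_fn):
        return [
            VFTestPoint(p.x_deg, p.y_deg, value_fn(p))
            for p in build_hfa10_2_grid()
        ]

    def test_constant_field_gives_constant_means(self):
        summary = summarize_vfs_by_area(self._exam(lambda p: 30.0))
        assert list(summary.index) == list(AREAS)
        assert (summary["mean_vfs_db"] == 30.0).all()
        assert summary.loc["whole", "n_points"] == 68
        assert (summary.loc[["3_1", "3_2", "3_3", "3_4"], "n_points"] == 3).all()
        assert (summary.loc[["6_1", "6_2", "6_3", "6_4"], "n_points"] == 14).all()
        assert (summary.loc[["superior", "inferior"], "n_points"] == 34).all()

    @given(st.integers(0, 2**32 - 1))
    def test_whole_field_mean_is_sector_weighted_mean(self, seed):
        rng = np.random.default_rng(seed)
        summary = summarize_vfs_by_area(
            self._exam(lambda p: float(rng.uniform(0, 40)))
        )
        sectors = ["3_1", "3_2", "3_3", "3_4", "6_1", "6_2", "6_3", "6_4"]
        weights = summary.loc[sectors, "n_points"]
        weighted = (
            summary.loc[sectors, "mean_vfs_db"] * weights
        ).sum() / weights.sum()
        assert summary.loc["whole", "mean_vfs_db"] == pytest.approx(weighted)

    def test_horizontal_reflection_swaps_hemifield_means(self):
        rng = np.random.default_rng(5)
        values = {
            (p.x_deg, p.y_deg): float(rng.uniform(0, 40))
            for p in build_hfa10_2_grid()
        }
        exam = self._exam(lambda p: values[(p.x_deg, p.y_deg)])
        mirrored = self._exam(lambda p: values[(p.x_deg, -p.y_deg)])
        a = summarize_vfs_by_area(exam)
        b = summarize_vfs_by_area(mirrored)
        assert a.loc["superior", "mean_vfs_db"] == pytest.approx(
            b.loc["inferior", "mean_vfs_db"]
        )
        assert a.loc["inferior", "mean_vfs_db"] == pytest.approx(
            b.loc["superior", "mean_vfs_db"]
        )

    def test_missing_sensitivities_are_named(self):
        exam = self._exam(lambda p: 30.0)
        exam[0] = VFTestPoint(exam[0].x_deg, exam[0].y_deg, None)
        with pytest.raises(ValueError, match="missing sensitivities"):
            summarize_vfs_by_area(exam)

    def test_wrong_point_count_rejected(self):
        with pytest.raises(ValueError, match="68-point"):
            summarize_vfs_by_area([VFTestPoint(1, 1, 30.0)])


def test_left_eye_mirroring_is_an_involution(grid):
    assert mirror_left_eye(mirror_left_eye(grid)) == grid


def test_sector_scheme_rejects_unordered_radii():
    with pytest.raises(ValueError):
        SectorScheme(circle_radii_mm=(1.5, 0.5, 3.0))


def test_gmda_label_validation():
    with pytest.raises(ValueError):
        GMDALabel("5", 1)
    with pytest.raises(ValueError):
        GMDALabel("3", 5)
    assert GMDALabel("6", 3).area == "6_3"
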