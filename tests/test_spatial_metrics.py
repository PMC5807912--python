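import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from angioquant import (
    HistogramSpec,
    color_split,
    compute_sample_metrics,
    detect_marks,
    diameter,
    generate_sample,
    histogram,
    identify_central_vessels,
    ingrowth_distance,
    perfused_area,
    total_vessel_count,
    vessel_density,
)
from angioquant.errors import MissingReferenceError
from angioquant.spatial_metrics import dilated_union_area
from angioquant.vessel_detection import VesselMark, VesselTable
from angioquant import SampleSpec

from conftest import disk_mask, lens_area


def table_of_disks(centers_um, radii_um, scale=1.0, shape_um=2000.0):
    """A VesselTable of capillary disks with explicit pixel footprints."""
    n = int(shape_um / scale)
    marks = []
    for i, (c, r) in enumerate(zip(centers_um, radii_um)):
        mask = disk_mask((n, n), (c[1] / scale, c[0] / scale), r / scale)
        coords = np.argwhere(mask)
        marks.append(
            VesselMark(
                id=i, vessel_type="capillary",
                centroid=(c[0], c[1]), area=len(coords) * scale**2,
                major_axis=2 * r, minor_axis=2 * r,
                pixel_count=len(coords), pixels=coords,
            )
        )
    return VesselTable(sample_id="disks", marks=marks, scale=scale,
                       image_shape=(n, n))


def detected_table(spec):
    image, gt = generate_sample(spec)
    table = identify_central_vessels(detect_marks(color_split(image)))
    return table, gt


class TestVesselCount:
    def test_count_excludes_central_pair(self):
        spec = SampleSpec(image_px=1400, scale=3.0, n_capillaries=54, seed=9,
                          radial_distribution=("uniform", {"low": 300.0, "high": 1800.0}))
        table, gt = detected_table(spec)
        assert total_vessel_count(table) == gt.realized_count == 54
        assert len(table) == 56  # + artery + vein

    def test_only_central_pair_counts_zero(self):
        spec = SampleSpec(image_px=400, scale=4.0, n_capillaries=0, seed=1)
        table, _ = detected_table(spec)
        assert total_vessel_count(table) == 0


class TestPerfusedArea:
    def test_single_disk_matches_analytic_circle(self):
        table = table_of_disks([(1000.0, 1000.0)], [50.0], scale=1.0)
        area = perfused_area(table, radius=150.0)
        assert area * 1e6 == pytest.approx(math.pi * 200**2, rel=0.01)

    def test_disjoint_disks_add(self):
        table = table_of_disks([(700.0, 1000.0), (1300.0, 1000.0)], [25.0, 25.0])
        area = perfused_area(table, radius=150.0)
        assert area * 1e6 == pytest.approx(2 * math.pi * 175**2, rel=0.01)

    def test_overlapping_disks_single_counted(self):
        table = table_of_disks([(950.0, 1000.0), (1050.0, 1000.0)], [25.0, 25.0])
        area = perfused_area(table, radius=150.0)
        expected = 2 * math.pi * 175**2 - lens_area(175.0, 100.0)
        assert area * 1e6 == pytest.approx(expected, rel=0.01)
        assert area * 1e6 < 2 * math.pi * 175**2

    def test_union_bounds(self):
        # union <= sum of individual dilations, >= largest single dilation
        table = table_of_disks(
            [(900.0, 1000.0), (1100.0, 1000.0), (1000.0, 1150.0)],
            [40.0, 25.0, 10.0],
        )
        union = perfused_area(table, radius=150.0)
        singles = [
            perfused_area(table_of_disks([c], [r]), radius=150.0)
            for c, r in [((900.0, 1000.0), 40.0), ((1100.0, 1000.0), 25.0),
                         ((1000.0, 1150.0), 10.0)]
        ]
        assert union <= sum(singles) + 1e-9
        assert union >= max(singles) - 1e-9

    def test_monotone_in_radius(self):
        table = table_of_disks([(900.0, 1000.0), (1200.0, 900.0)], [30.0, 20.0])
        areas = [perfused_area(table, radius=r) for r in (50.0, 100.0, 150.0, 250.0)]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_empty_table_zero(self):
        table = VesselTable(sample_id="empty", marks=[], scale=1.0,
                            image_shape=(100, 100))
        assert perfused_area(table, radius=150.0) == 0.0

    def test_exclude_central_flag(self, small_spec):
        table, _ = detected_table(small_spec)
        with_central = perfused_area(table, radius=150.0, include_central=True)
        without = perfused_area(table, radius=150.0, include_central=False)
        assert without <= with_central

    def test_dilated_union_area_rejects_bad_radius(self):
        with pytest.raises(ValueError):
            dilated_union_area(np.ones((5, 5), bool), 1.0, 0.0)


class TestVesselDensity:
    def test_unit_case(self):
        assert vessel_density(100, 1.0) == 100.0

    def test_empty_sample_convention(self):
        assert vessel_density(0, 0.0) == 0.0

    def test_impossible_state(self):
        with pytest.raises(ValueError, match="impossible"):
            vessel_density(5, 0.0)

    def test_density_identity_on_processed_samples(self):
        for seed in (0, 1, 2):
            spec = SampleSpec(image_px=500, scale=4.0, n_capillaries=15, seed=seed,
                              radial_distribution=("uniform", {"low": 200.0, "high": 700.0}))
            table, _ = detected_table(spec)
            m = compute_sample_metrics(table)
            assert m.vessel_density * m.total_perfused_area == pytest.approx(
                m.total_vessel_count, abs=1e-9
            )


class TestIngrowthDistance:
    def _mark(self, x, y):
        return VesselMark(id=0, vessel_type="capillary", centroid=(x, y),
                          area=1.0, major_axis=1.0, minor_axis=1.0, pixel_count=1)

    def test_three_four_five_triangle(self):
        assert ingrowth_distance(self._mark(300.0, 400.0), self._mark(0.0, 0.0)) == 500.0

    def test_coincident_is_zero(self):
        assert ingrowth_distance(self._mark(5.0, 5.0), self._mark(5.0, 5.0)) == 0.0

    def test_missing_vein_raises(self):
        with pytest.raises(MissingReferenceError):
            ingrowth_distance(self._mark(0.0, 0.0), None)

    def test_placed_radii_recovered(self, small_spec):
        table, gt = detected_table(small_spec)
        metrics = compute_sample_metrics(table)
        placed = sorted(r.radius for r in gt.capillaries)
        recovered = sorted(metrics.ingrowth_distances)
        # centroid accuracy is sub-pixel; allow one pixel in um
        np.testing.assert_allclose(recovered, placed, atol=small_spec.scale)


class TestDiameter:
    def test_pass_through_minor_axis(self):
        mark = VesselMark(id=0, vessel_type="capillary", centroid=(0, 0),
                          area=100.0, major_axis=20.0, minor_axis=12.5, pixel_count=100)
        assert diameter(mark) == 12.5

    def test_circle_diameter_equals_major_axis(self):
        spec = SampleSpec(image_px=600, scale=2.0, n_capillaries=1, seed=3,
                          diameter_distribution=("constant", {"value": 80.0}),
                          eccentricity_range=(1.0, 1.0),
                          radial_distribution=("uniform", {"low": 280.0, "high": 350.0}))
        table, _ = detected_table(spec)
        (mark,) = table.capillaries
        assert mark.minor_axis == pytest.approx(mark.major_axis, rel=0.02)
        assert diameter(mark) == pytest.approx(80.0, rel=0.02)


class TestHistogram:
    def test_unit_counts(self):
        centers, heights = histogram([5, 15, 25], HistogramSpec(10.0, (0.0, 30.0)))
        np.testing.assert_allclose(centers, [5, 15, 25])
        np.testing.assert_allclose(heights, [1, 1, 1])

    def test_normalization_sums_to_one(self):
        _, heights = histogram([5, 15, 25],
                               HistogramSpec(10.0, (0.0, 30.0), normalized=True))
        np.testing.assert_allclose(heights, [1 / 3] * 3)
        assert heights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_moving_average_smoothing(self):
        _, heights = histogram([15, 15, 15],
                               HistogramSpec(10.0, (0.0, 30.0), smoothing_window=3))
        np.testing.assert_allclose(heights, [1, 1, 1])

    def test_empty_normalized_is_all_zero(self):
        _, heights = histogram([], HistogramSpec(10.0, (0.0, 30.0), normalized=True))
        assert (heights == 0).all()

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(ValueError):
            HistogramSpec(10.0, (0.0, 30.0), smoothing_window=2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 299.9), min_size=1, max_size=60))
    def test_normalized_heights_sum_to_one(self, values):
        _, heights = histogram(values,
                               HistogramSpec(10.0, (0.0, 300.0), normalized=True))
        assert heights.sum() == pytest.approx(1.0, abs=1e-9)
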