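"""Contour measurement, ratio aggregation, and nucleus placement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disccalib import (
    ContainmentError,
    Contour,
    GeometryError,
    InfeasiblePlacementError,
    MeasurementRecord,
    compute_ratios,
    measure_areas,
    measure_edge_distances,
    place_nucleus,
)
from disccalib.geometry import read_contour_csv, records_to_frame, write_contour_csv


def ray_cast_span(points: np.ndarray, y: float) -> tuple[float, float]:
    """Independent oracle: x-extent of a polygon on the horizontal line at y,
    from explicit edge/line crossings (no shapely)."""
    xs = []
    n = len(points)
    for i in range(n):
        (x1, y1), (x2, y2) = points[i], points[(i + 1) % n]
        if (y1 - y) * (y2 - y) <= 0 and y1 != y2:
            xs.append(x1 + (y - y1) * (x2 - x1) / (y2 - y1))
    assert xs, "line misses polygon"
    return min(xs), max(xs)


def fan_triangulation_area(points: np.ndarray) -> float:
    """Independent oracle: polygon area as a fan of signed triangles."""
    p0 = points[0]
    total = 0.0
    for a, b in zip(points[1:-1], points[2:]):
        total += 0.5 * ((a[0] - p0[0]) * (b[1] - p0[1]) - (b[0] - p0[0]) * (a[1] - p0[1]))
    return abs(total)


class TestContour:
    def test_rejects_degenerate_polygons(self):
        with pytest.raises(GeometryError):
            Contour(np.array([[0, 0], [1, 1]]))
        with pytest.raises(GeometryError):
            Contour(np.array([[0, 0], [1, 1], [2, 2]]))  # collinear, zero area
        with pytest.raises(GeometryError):  # bowtie self-intersection
            Contour(np.array([[0, 0], [1, 1], [1, 0], [0, 1]]))

    def test_explicit_closing_vertex_is_dropped(self):
        square = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]))
        assert len(square.points) == 4
        assert square.area == pytest.approx(1.0)

    def test_csv_round_trip(self, tmp_path, ellipse_disc):
        path = tmp_path / "contour.csv"
        write_contour_csv(ellipse_disc, path)
        back = read_contour_csv(path)
        np.testing.assert_allclose(back.points, ellipse_disc.points, atol=1e-9)


class TestEdgeDistances:
    def test_concentric_circles_are_symmetric(self):
        disc = Contour.circle(20.0, 720)
        nucleus = Contour.circle(10.0, 720)
        d1, d2 = measure_edge_distances(disc, nucleus)
        assert d1 == pytest.approx(10.0, abs=1e-6)
        assert d2 == pytest.approx(10.0, abs=1e-6)

    def test_posteriorly_shifted_circle_closed_form(self):
        disc = Contour.circle(20.0, 720)
        nucleus = Contour.circle(10.0, 720, center=(2.0, 0.0))  # +x = posterior
        d1, d2 = measure_edge_distances(disc, nucleus)
        assert d1 == pytest.approx(12.0, abs=1e-6)
        assert d2 == pytest.approx(8.0, abs=1e-6)

    def test_ellipse_matches_dense_ray_casting_oracle(self):
        disc = Contour.ellipse(25.0, 17.0, n_vertices=10_000)
        nucleus = disc.scaled(0.6).translated(3.0)
        d1, d2 = measure_edge_distances(disc, nucleus)
        yc = disc.centroid[1]
        d_lo, d_hi = ray_cast_span(disc.points, yc)
        n_lo, n_hi = ray_cast_span(nucleus.points, yc)
        assert d1 == pytest.approx(n_lo - d_lo, abs=1e-9)
        assert d2 == pytest.approx(d_hi - n_hi, abs=1e-9)

    def test_nucleus_outside_disc_raises(self):
        disc = Contour.circle(20.0, 256)
        nucleus = Contour.circle(10.0, 256, center=(15.0, 0.0))
        with pytest.raises(ContainmentError):
            measure_edge_distances(disc, nucleus)

    def test_midline_missing_nucleus_raises(self):
        disc = Contour.circle(20.0, 256)
        nucleus = Contour.circle(2.0, 256, center=(0.0, 10.0))
        with pytest.raises(GeometryError):
            measure_edge_distances(disc, nucleus)


class TestAreas:
    def test_unit_square_with_half_scale_nucleus(self):
        disc = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
        nucleus = disc.scaled(0.5)
        assert measure_areas(disc, nucleus) == pytest.approx((1.0, 0.25))

    def test_dense_circle_matches_closed_form(self):
        disc = Contour.circle(20.0, n_vertices=3600)
        area, _ = measure_areas(disc, disc.scaled(0.5))
        assert area == pytest.approx(np.pi * 400.0, rel=1e-4)

    def test_random_simple_polygon_matches_fan_triangulation(self):
        rng = np.random.default_rng(7)
        # star-convex polygon: random radii at sorted angles is always simple
        theta = np.sort(rng.uniform(0, 2 * np.pi, 40))
        r = rng.uniform(5.0, 15.0, 40)
        pts = np.c_[r * np.cos(theta), r * np.sin(theta)]
        poly = Contour(pts)
        assert poly.area == pytest.approx(fan_triangulation_area(pts), rel=1e-12)

    def test_orientation_invariance(self, ellipse_disc):
        reversed_contour = Contour(ellipse_disc.points[::-1])
        assert reversed_contour.area == pytest.approx(ellipse_disc.area, rel=1e-12)


def _record(d1, d2, disc_area=1761.0, nucleus_area=671.4, subject="S1", observer="O1"):
    return MeasurementRecord(
        subject_id=subject,
        observer_id=observer,
        d1_mm=d1,
        d2_mm=d2,
        disc_area_mm2=disc_area,
        nucleus_area_mm2=nucleus_area,
        pfirrmann_grade=1,
    )


class TestComputeRatios:
    def test_published_cohort_means(self):
        """The published mean measurements yield P1 = 1.22 and P2 = 38%."""
        ratios = compute_ratios([_record(8.87, 7.29)])
        assert ratios.p1_report == 1.22
        assert ratios.p2_percent == 38

    def test_concentric_shrink_gives_unit_p1(self, ellipse_disc):
        nucleus = ellipse_disc.scaled(0.6)
        d1, d2 = measure_edge_distances(ellipse_disc, nucleus)
        ratios = compute_ratios([_record(d1, d2)])
        assert ratios.p1 == pytest.approx(1.0, abs=1e-9)

    def test_ratio_of_means_not_mean_of_ratios(self):
        records = [_record(2.0, 1.0), _record(4.0, 4.0, subject="S2")]
        ratios = compute_ratios(records)
        assert ratios.p1 == pytest.approx(6.0 / 5.0)  # not (2 + 1)/2

    def test_accepts_dataframe_input(self):
        frame = records_to_frame([_record(8.87, 7.29)])
        assert compute_ratios(frame).p1_report == 1.22

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            compute_ratios([])
        with pytest.raises(ValueError):
            compute_ratios(pd.DataFrame(columns=records_to_frame([]).columns))

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            _record(-1.0, 2.0)
        with pytest.raises(ValueError):
            _record(1.0, 2.0, disc_area=100.0, nucleus_area=200.0)


class TestPlaceNucleus:
    def test_circle_closed_form(self):
        disc = Contour.circle(20.0, 720)
        nucleus = place_nucleus(disc, p1=1.5, p2=0.25)
        cx, cy = nucleus.centroid
        assert cx == pytest.approx(2.0, abs=1e-6)  # 2 mm posterior
        assert cy == pytest.approx(0.0, abs=1e-9)
        d1, d2 = measure_edge_distances(disc, nucleus)
        assert (d1, d2) == pytest.approx((12.0, 8.0), abs=1e-6)

    def test_unit_p1_is_concentric(self, ellipse_disc):
        nucleus = place_nucleus(ellipse_disc, p1=1.0, p2=0.4)
        assert nucleus.centroid == pytest.approx(ellipse_disc.centroid, abs=1e-9)

    def test_round_trip_on_ellipse(self, ellipse_disc):
        nucleus = place_nucleus(ellipse_disc, p1=1.62, p2=0.38)
        d1, d2 = measure_edge_distances(ellipse_disc, nucleus)
        _, n_area = measure_areas(ellipse_disc, nucleus)
        assert d1 / d2 == pytest.approx(1.62, rel=1e-6)
        assert n_area / ellipse_disc.area == pytest.approx(0.38, rel=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        p1=st.floats(1.0, 1.8),
        p2=st.floats(0.25, 0.50),
        a=st.floats(15.0, 28.0),
        b=st.floats(15.0, 32.0),
    )
    def test_round_trip_property(self, p1, p2, a, b):
        disc = Contour.ellipse(a, b, n_vertices=360)
        nucleus = place_nucleus(disc, p1, p2)
        d1, d2 = measure_edge_distances(disc, nucleus)
        assert d1 / d2 == pytest.approx(p1, rel=1e-6)
        assert nucleus.area / disc.area == pytest.approx(p2, rel=1e-6)

    def test_scale_equivariance(self, ellipse_disc):
        nucleus = place_nucleus(ellipse_disc, 1.4, 0.35)
        big = ellipse_disc.scaled(2.5)
        nucleus_big = place_nucleus(big, 1.4, 0.35)
        d1, d2 = measure_edge_distances(ellipse_disc, nucleus)
        D1, D2 = measure_edge_distances(big, nucleus_big)
        assert D1 / D2 == pytest.approx(d1 / d2, rel=1e-9)
        assert nucleus_big.area / big.area == pytest.approx(
            nucleus.area / ellipse_disc.area, rel=1e-9
        )

    @pytest.mark.parametrize("p1", [1.1, 1.4, 1.8])
    def test_posterior_shift_direction(self, ellipse_disc, p1):
        nucleus = place_nucleus(ellipse_disc, p1, 0.38)
        assert nucleus.centroid[0] > ellipse_disc.centroid[0]

    def test_infeasible_p1_raises_on_concave_disc(self, dented_disc):
        # feasible at moderate posterior shift, infeasible once the nucleus
        # would poke into the concavity
        place_nucleus(dented_disc, p1=1.5, p2=0.40)
        with pytest.raises(InfeasiblePlacementError):
            place_nucleus(dented_disc, p1=3.0, p2=0.40)

    def test_convex_disc_placement_always_feasible(self, ellipse_disc):
        # the ratio definition cannot push the nucleus out of a convex disc,
        # unlike a fixed millimetre offset
        for p1 in (5.0, 20.0, 100.0):
            nucleus = place_nucleus(ellipse_disc, p1, 0.40)
            d1, d2 = measure_edge_distances(ellipse_disc, nucleus)
            assert d1 / d2 == pytest.approx(p1, rel=1e-6)

    def test_invalid_arguments(self, circle_disc):
        with pytest.raises(ValueError):
            place_nucleus(circle_disc, p1=1.2, p2=1.2)
        with pytest.raises(ValueError):
            place_nucleus(circle_disc, p1=-1.0, p2=0.4)
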