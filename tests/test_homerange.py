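"""Kernel UDs, isopleths, bandwidth selection, MCPs and zonal summaries."""

import numpy as np
import pytest
from shapely.geometry import Point

from quollmove.homerange import (
    asymptote_check,
    availability_region,
    equal_area_radius,
    fit_kde,
    h_ad_hoc,
    isopleth,
    mcp,
    sample_available_ranges,
    summarize_range,
)
from quollmove.landscape import HABITAT_CODES, generate_landscape


class TestKde:
    def test_total_mass_is_one(self):
        rng = np.random.default_rng(0)
        ud = fit_kde(rng.normal(0, 50, (200, 2)), h=20.0)
        assert ud.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ud.mass >= 0).all()

    def test_gaussian_cluster_matches_closed_form_area(self):
        """N(0, s^2 I) smoothed by h: the 95% isopleth of the limit
        density has area pi * (s^2 + h^2) * 5.991."""
        rng = np.random.default_rng(1)
        sigma, h = 100.0, 30.0
        pts = rng.normal(0.0, sigma, (8000, 2))
        ud = fit_kde(pts, h)
        area = isopleth(ud, 0.95).area_m2
        expected = np.pi * (sigma**2 + h**2) * 5.991
        assert abs(area - expected) / expected < 0.10

    def test_resolution_refinement_stability(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0.0, 60.0, (500, 2))
        a1 = isopleth(fit_kde(pts, 25.0, grid_resolution=25.0 / 4), 0.95).area_m2
        a2 = isopleth(fit_kde(pts, 25.0, grid_resolution=25.0 / 8), 0.95).area_m2
        assert abs(a1 - a2) / a2 < 0.02

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_kde(np.zeros((4, 2)), 10.0)
        with pytest.raises(ValueError):
            fit_kde(np.random.default_rng(0).normal(size=(10, 2)), -1.0)


class TestIsopleth:
    def test_uniform_mass_takes_95_cells(self):
        from quollmove.homerange import UtilisationDistribution

        ud = UtilisationDistribution(0, 10, 1.0, np.full((10, 10), 0.01), 1.0, 100)
        r = isopleth(ud, 0.95)
        assert r.area_m2 == pytest.approx(95.0)

    def test_nested_levels(self):
        rng = np.random.default_rng(3)
        ud = fit_kde(rng.normal(0, 40, (300, 2)), 15.0)
        assert isopleth(ud, 0.50).area_m2 <= isopleth(ud, 0.95).area_m2

    def test_matches_brute_force_greedy_selection(self):
        rng = np.random.default_rng(4)
        ud = fit_kde(rng.normal(0, 30, (100, 2)), 12.0)
        r = isopleth(ud, 0.8)
        flat = sorted(ud.mass.ravel(), reverse=True)
        csum, k = 0.0, 0
        for v in flat:
            csum += v
            k += 1
            if csum >= 0.8:
                break
        assert r.area_m2 == pytest.approx(k * ud.cell_area)


class TestBandwidth:
    def test_tight_cluster_shrinks_below_reference(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 50, (300, 2))
        sigma = np.sqrt(0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)))
        h_ref = sigma * len(pts) ** (-1 / 6)
        h = h_ad_hoc(pts)
        assert h < h_ref
        # the returned h is itself contiguous
        ud = fit_kde(pts, h)
        from quollmove.homerange import _contiguous_no_holes, _isopleth_mask

        assert _contiguous_no_holes(_isopleth_mask(ud, 0.95))

    def test_two_distant_clusters_return_reference(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1.0, (150, 2))
        b = rng.normal(0, 1.0, (150, 2)) + 200.0
        pts = np.vstack([a, b])
        sigma = np.sqrt(0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)))
        h_ref = sigma * len(pts) ** (-1 / 6)
        assert h_ad_hoc(pts) == pytest.approx(h_ref)

    def test_scale_equivariance_within_one_step(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 30, (200, 2))
        h1 = h_ad_hoc(pts)
        h2 = h_ad_hoc(pts * 4.0)
        sigma = np.sqrt(0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1)))
        step = 0.05 * sigma * len(pts) ** (-1 / 6)
        assert abs(h2 / 4.0 - h1) <= 4.0 * step / 4.0 + 1e-9


def gift_wrap(points):
    """Brute-force convex hull (independent oracle)."""
    pts = [tuple(p) for p in points]
    start = min(pts)
    hull = [start]
    current = start
    while True:
        cand = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = ((cand[0] - current[0]) * (p[1] - current[1])
                     - (cand[1] - current[1]) * (p[0] - current[0]))
            if cross < 0 or (cross == 0 and
                             np.hypot(p[0] - current[0], p[1] - current[1])
                             > np.hypot(cand[0] - current[0], cand[1] - current[1])):
                cand = p
        if cand == start:
            break
        hull.append(cand)
        current = cand
    return set(hull)


class TestMcp:
    def test_unit_square(self):
        poly = mcp(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert poly.area == pytest.approx(1.0)

    def test_collinear_points_degenerate(self):
        poly = mcp(np.array([[0, 0], [1, 1], [2, 2]]))
        assert poly.area == 0.0

    def test_hull_vertices_match_gift_wrapping(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 10, (200, 2)).round(3)
        poly = mcp(pts)
        got = set((round(x, 3), round(y, 3)) for x, y in
                  np.asarray(poly.exterior.coords)[:-1])
        assert got == gift_wrap(pts)


class TestAvailableRanges:
    def test_study_design_counts(self):
        rng = np.random.default_rng(9)
        total = 0
        for ind in range(9):
            pts = rng.normal(ind * 1000.0, 200.0, (50, 2))
            region = availability_region(pts, r_max=800.0, r_focal=300.0)
            total += len(sample_available_ranges(region, np.pi * 300.0**2, n=5,
                                                 seed=ind, individual_id=str(ind)))
        assert total == 45

    def test_circle_area_exact(self):
        region = availability_region(np.array([[0, 0], [0, 900], [900, 0]]), 500.0, 100.0)
        ranges = sample_available_ranges(region, 1e6, n=3, seed=0)
        for r in ranges:
            assert r.radius == pytest.approx(equal_area_radius(1e6))
            assert r.area_m2 == pytest.approx(1e6)

    def test_centres_uniform_over_region(self):
        """Chi-square on a 4x4 partition of a square region, 10,000 draws."""
        from shapely.geometry import Polygon

        region = Polygon([(0, 0), (400, 0), (400, 400), (0, 400)])
        ranges = sample_available_ranges(region, 100.0, n=10_000, seed=10)
        centres = np.array([r.centre for r in ranges])
        hist, _, _ = np.histogram2d(centres[:, 0], centres[:, 1],
                                    bins=[np.linspace(0, 400, 5)] * 2)
        from scipy.stats import chisquare

        stat, p = chisquare(hist.ravel())
        assert p > 0.001


class TestSummaries:
    def test_range_inside_rocky(self):
        land = generate_landscape(1, 60, 60, proportions={"rocky": 1.0})
        r = sample_available_ranges(
            availability_region(np.array([[200, 200], [400, 400], [200, 400]]), 100, 50),
            np.pi * 50.0**2, n=1, seed=0)[0]
        summary = summarize_range(r, land)
        assert summary.proportions["rocky"] == pytest.approx(1.0)
        assert summary.mean_dist_rocky == 0.0

    def test_half_split_landscape(self):
        from quollmove.landscape import Landscape
        from quollmove.raster import RasterGrid

        n = 100
        vals = np.zeros((n, n))
        vals[:, n // 2:] = HABITAT_CODES["rocky"]
        habitat = RasterGrid(0, n * 10.0, 10.0, vals, name="habitat")
        tri = RasterGrid(0, n * 10.0, 10.0, np.ones((n, n)), name="tri")
        zeros = RasterGrid(0, n * 10.0, 10.0, np.zeros((n, n)))
        land = Landscape(habitat, tri, zeros, zeros)
        from quollmove.homerange import MovementRange

        centre = (n * 10.0 / 2, n * 10.0 / 2)
        r = MovementRange("x", "available", 0.95, np.pi * 300.0**2,
                          centre, centre=centre, radius=300.0)
        summary = summarize_range(r, land)
        assert summary.proportions["rocky"] == pytest.approx(0.5, abs=0.02)
        assert summary.proportions["spinifex"] == pytest.approx(0.5, abs=0.02)

    def test_summary_matches_brute_force_scan(self, small_landscape):
        from quollmove.homerange import MovementRange

        centre = (600.0, 600.0)
        r = MovementRange("x", "available", 0.95, np.pi * 200.0**2,
                          centre, centre=centre, radius=200.0)
        summary = summarize_range(r, small_landscape)
        hab = small_landscape.habitat
        inside, codes = [], []
        for row in range(hab.n_rows):
            for col in range(hab.n_cols):
                cx = hab.origin_x + (col + 0.5) * hab.cell_size
                cy = hab.origin_y - (row + 0.5) * hab.cell_size
                if np.hypot(cx - centre[0], cy - centre[1]) <= 200.0:
                    codes.append(hab.values[row, col])
        codes = np.asarray(codes)
        assert summary.proportions["rocky"] == pytest.approx(
            (codes == HABITAT_CODES["rocky"]).mean(), abs=1e-12)


class TestAsymptote:
    def test_stationary_cloud_reaches_asymptote(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(0, 80.0, (260, 2))
        areas, reached = asymptote_check(pts, interval=20)
        assert reached
        assert np.isfinite(areas[~np.isnan(areas)]).all()
        assert (areas[~np.isnan(areas)] >= 0).all()

    def test_short_track_insufficient_evidence(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 80.0, (25, 2))
        _, reached = asymptote_check(pts, interval=10)
        assert not reached


def test_equal_area_radius_of_largest_range():
    # 8,576.21 ha -> 5,224.7 m, within 0.1% of the 5,220 m design constant
    r = equal_area_radius(8576.21 * 1e4)
    assert r == pytest.approx(5224.7, abs=0.5)
    assert abs(r - 5220.0) / 5220.0 < 0.001
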