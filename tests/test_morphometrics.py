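"""Per-cell shape measures: closed forms, oracles, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomorph.morphometrics import (
    cell_area,
    cell_circularity,
    cell_orientation,
    cell_perimeter,
    summarise_regions,
    welch_ttest,
)
from cardiomorph._geometry import rotate_points, smooth_closed_polygon
from conftest import star_polygon


def regular_polygon(k, r=1.0):
    ang = np.arange(k) * 2 * np.pi / k
    return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)


class TestArea:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert cell_area(sq) == pytest.approx(1.0)

    def test_fine_polygon_approaches_circle(self):
        poly = regular_polygon(360)
        assert cell_area(poly) == pytest.approx(math.pi, rel=1e-3)

    def test_monte_carlo_rejection_oracle(self):
        # random simple 12-gon vs. an independent point-in-polygon estimate
        rng = np.random.default_rng(42)
        poly = star_polygon(rng, n=12)
        lo, hi = poly.min(axis=0), poly.max(axis=0)
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        from shapely import contains_xy
        from shapely.geometry import Polygon

        frac = contains_xy(Polygon(poly), pts[:, 0], pts[:, 1]).mean()
        mc_area = frac * np.prod(hi - lo)
        assert cell_area(poly) == pytest.approx(mc_area, rel=0.01)


class TestCircularity:
    @pytest.mark.parametrize("k", [3, 5, 6])
    def test_regular_kgon_closed_form(self, k):
        # isoperimetric quotient of a regular k-gon: pi * cot(pi/k) / k
        expected = math.pi / (k * math.tan(math.pi / k))
        assert cell_circularity(regular_polygon(k)) == pytest.approx(expected, rel=1e-12)

    def test_square_is_pi_over_4(self):
        sq = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
        assert cell_circularity(sq) == pytest.approx(math.pi / 4)

    def test_fine_circle_approaches_one(self):
        assert cell_circularity(regular_polygon(720)) > 0.999
        assert cell_circularity(regular_polygon(720)) <= 1.0001

    def test_degenerate_polygon_raises(self):
        line = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            cell_circularity(line)


class TestOrientation:
    def test_axis_aligned_rectangle(self):
        rect = np.array([[0, 0], [2, 0], [2, 1], [0, 1]], dtype=float)
        axis, elong = cell_orientation(rect)
        assert axis == pytest.approx(0.0, abs=1e-9)
        assert elong == pytest.approx(0.75)  # eigenvalues 4:1

    @pytest.mark.parametrize("angle", [30.0, 75.0, 120.0])
    def test_rotation_equivariance(self, angle):
        rect = np.array([[0, 0], [2, 0], [2, 1], [0, 1]], dtype=float)
        # y-down storage frame: a +30 deg visual (y-up) rotation is -30 here
        rot = rotate_points(rect, -math.radians(angle))
        axis, elong = cell_orientation(rot)
        assert axis == pytest.approx(angle % 180.0, abs=1e-6)
        assert elong == pytest.approx(0.75, abs=1e-9)

    def test_isotropic_axis_undefined(self):
        axis, elong = cell_orientation(regular_polygon(64))
        assert math.isnan(axis)
        assert elong == 0.0

    def test_rasterisation_covariance_oracle(self):
        # dense pixel covariance of the filled polygon as independent oracle
        rng = np.random.default_rng(5)
        poly = star_polygon(rng, n=10, r_lo=2.0, r_hi=5.0)
        axis, elong = cell_orientation(poly)
        step = 0.02
        xs = np.arange(poly[:, 0].min(), poly[:, 0].max(), step) + step / 2
        ys = np.arange(poly[:, 1].min(), poly[:, 1].max(), step) + step / 2
        gx, gy = np.meshgrid(xs, ys)
        from shapely import contains_xy
        from shapely.geometry import Polygon

        inside = contains_xy(Polygon(poly), gx.ravel(), gy.ravel())
        pts = np.stack([gx.ravel()[inside], gy.ravel()[inside]], axis=1)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        ang = math.degrees(math.atan2(evecs[1, 1], evecs[0, 1]))
        oracle_axis = (-ang) % 180.0  # storage frame is y-down
        diff = min(abs(axis - oracle_axis), 180.0 - abs(axis - oracle_axis))
        assert diff < 0.5
        assert elong == pytest.approx(1.0 - evals[0] / evals[1], abs=5e-3)


class TestRigidMotionAndScale:
    @given(
        seed=st.integers(0, 10_000),
        angle=st.floats(0, 2 * math.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariance_under_rigid_motion(self, seed, angle, tx, ty):
        poly = star_polygon(np.random.default_rng(seed))
        moved = rotate_points(poly, angle) + [tx, ty]
        assert cell_area(moved) == pytest.approx(cell_area(poly), rel=1e-9)
        assert cell_perimeter(moved) == pytest.approx(cell_perimeter(poly), rel=1e-9)
        assert cell_circularity(moved) == pytest.approx(cell_circularity(poly), rel=1e-9)
        _, e0 = cell_orientation(poly)
        _, e1 = cell_orientation(moved)
        assert e1 == pytest.approx(e0, abs=1e-9)

    @pytest.mark.parametrize("s", [0.25, 3.0])
    def test_scale_law(self, s):
        poly = star_polygon(np.random.default_rng(7))
        assert cell_area(poly * s) == pytest.approx(s * s * cell_area(poly))
        assert cell_perimeter(poly * s) == pytest.approx(s * cell_perimeter(poly))
        assert cell_circularity(poly * s) == pytest.approx(cell_circularity(poly))
        _, e0 = cell_orientation(poly)
        _, e1 = cell_orientation(poly * s)
        assert e1 == pytest.approx(e0, rel=1e-9)


class TestSmoothing:
    def test_window3_preserves_area_of_staircase(self):
        # pixel-edge disc: smoothing must keep area within 2 %
        from cardiomorph.mesh import PixelGrid, mesh_from_labels

        lab = np.zeros((60, 60), dtype=np.int32)
        yy, xx = np.mgrid[0:60, 0:60]
        lab[(yy - 30) ** 2 + (xx - 30) ** 2 < 25**2] = 1
        cell = mesh_from_labels(PixelGrid(lab, 1.0)).cells[0]
        raw = cell_area(cell)
        sm = smooth_closed_polygon(cell.boundary)
        from cardiomorph._geometry import polygon_area

        assert polygon_area(sm) == pytest.approx(raw, rel=0.02)
        # and brings the staircase circularity close to the ideal circle
        assert cell_circularity(cell, smooth=True) > 0.95


class TestRegionSummary:
    def test_identical_cells_have_zero_sd(self):
        df = pd.DataFrame(
            dict(
                cell_id=range(6),
                region=["a"] * 3 + ["b"] * 3,
                area_um2=[10.0] * 6,
                circularity=[0.7] * 6,
            )
        )
        out = summarise_regions(df)
        assert (out["area_sd"] == 0).all()
        assert out.loc[out.region == "a", "area_mean"].iloc[0] == 10.0

    def test_singleton_region_reports_zero_sd(self):
        df = pd.DataFrame(
            dict(cell_id=[0], region=["solo"], area_um2=[5.0], circularity=[0.5])
        )
        out = summarise_regions(df)
        assert out["area_sd"].iloc[0] == 0.0
        assert out["n"].iloc[0] == 1

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            dict(
                cell_id=range(40),
                region=["a"] * 20 + ["b"] * 20,
                area_um2=np.concatenate([rng.normal(100, 10, 20), rng.normal(85, 8, 20)]),
                circularity=0.5,
            )
        )
        from scipy import stats

        t, p = welch_ttest(df, "a", "b")
        t2, p2 = stats.ttest_ind(
            df[df.region == "a"].area_um2, df[df.region == "b"].area_um2, equal_var=False
        )
        assert t == pytest.approx(float(t2))
        assert p == pytest.approx(float(p2))
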