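"""Line profiles, normalisation, accumulation calls, co-localisation."""

import numpy as np
import pytest

from cardiomorph.intensity import (
    ColocTable,
    InputError,
    apical_accumulation_call,
    colocalisation_at_ts,
    joint_normalise,
    line_profile,
    minmax_normalise,
    normalise_cohort,
    round_half_up,
    ventricular_mean_intensity,
)
from cardiomorph.mesh import PixelGrid
from cardiomorph.transitions import TransitionState
from cardiomorph.mesh import JunctionVertex
import pandas as pd


def _ts_at(x, y):
    v = JunctionVertex(position=np.array([x, y]), incident_cells=frozenset([1, 2, 3, 4]))
    return TransitionState.from_vertex(v)


class TestLineProfile:
    def test_constant_image(self):
        img = PixelGrid(np.full((40, 40), 7.0), 0.5)
        path = np.array([[2.0, 10.0], [18.0, 10.0]])
        prof = line_profile(img, path, width_px=10)
        assert np.allclose(prof.raw, 7.0)
        assert prof.arc_um[0] == 0.0
        assert prof.arc_um[-1] == pytest.approx(16.0, abs=0.5)

    def test_perpendicular_gradient_cancels(self):
        # pure vertical gradient, horizontal path: symmetric width averaging
        vals = np.tile(np.arange(40.0)[:, None], (1, 40))
        img = PixelGrid(vals, 1.0)
        path = np.array([[5.0, 20.0], [35.0, 20.0]])
        prof = line_profile(img, path, width_px=8)
        assert np.allclose(prof.raw, prof.raw[0], atol=1e-9)

    def test_gaussian_ridge_matches_supersampled_oracle(self):
        # ridge along y = 25 with sigma 2 px; oracle integrates the same
        # stencil with 10x supersampling along the perpendicular
        h = w = 50
        yy = np.arange(h)[:, None] + 0.5
        img_vals = np.exp(-((yy - 25.0) ** 2) / (2 * 2.0**2)) * np.ones((h, w))
        img = PixelGrid(img_vals * 100.0, 1.0)
        path = np.array([[10.0, 25.0], [40.0, 25.0]])
        prof = line_profile(img, path, width_px=10)
        offsets = np.arange(10) - 4.5
        fine = np.linspace(offsets.min(), offsets.max(), 100)
        oracle_coarse = np.mean(100.0 * np.exp(-((offsets) ** 2) / 8.0))
        assert prof.raw.mean() == pytest.approx(oracle_coarse, rel=0.01)

    def test_path_outside_raster(self):
        img = PixelGrid(np.zeros((10, 10)), 1.0)
        with pytest.raises(InputError):
            line_profile(img, np.array([[50.0, 50.0], [60.0, 60.0]]))
        with pytest.raises(InputError):
            line_profile(img, np.array([[5.0, 5.0], [5.0, 5.0]]))  # zero length


class TestNormalisation:
    def test_minmax_basic(self):
        from cardiomorph.intensity import IntensityProfile

        p = IntensityProfile(
            path=np.zeros((2, 2)), side="x", arc_um=np.arange(3.0),
            raw=np.array([2.0, 4.0, 6.0]),
        )
        minmax_normalise(p)
        assert np.allclose(p.normalised, [0.0, 0.5, 1.0])

    def test_affine_invariance(self):
        from cardiomorph.intensity import IntensityProfile

        rng = np.random.default_rng(0)
        raw = rng.uniform(10, 200, 50)
        mk = lambda r: IntensityProfile(
            path=np.zeros((2, 2)), side="x", arc_um=np.arange(50.0), raw=r
        )
        p0 = minmax_normalise(mk(raw))
        p1 = minmax_normalise(mk(3.5 * raw + 17.0))
        assert np.allclose(p0.normalised, p1.normalised, atol=1e-12)

    def test_flat_profile_rejected(self):
        from cardiomorph.intensity import IntensityProfile

        p = IntensityProfile(
            path=np.zeros((2, 2)), side="x", arc_um=np.arange(3.0),
            raw=np.full(3, 9.0),
        )
        with pytest.raises(ValueError, match="dynamic range"):
            minmax_normalise(p)


class TestAccumulationCall:
    def _profile(self, vals, win=(0.0, 10.0)):
        from cardiomorph.intensity import IntensityProfile

        return IntensityProfile(
            path=np.zeros((2, 2)), side="x",
            arc_um=np.linspace(0, 10, len(vals)), raw=np.asarray(vals, float),
            oft_window=win,
        )

    def test_clear_separation_is_true(self):
        ap = self._profile([100.0] * 10 + [0.0])  # last point gives range
        ba = self._profile([0.0] * 11)
        call = apical_accumulation_call(ap, ba)
        assert call.aa is True

    def test_identical_profiles_are_false(self):
        ap = self._profile(np.linspace(0, 100, 11))
        ba = self._profile(np.linspace(0, 100, 11))
        call = apical_accumulation_call(ap, ba)
        assert call.aa is False
        assert call.apical_mean == pytest.approx(call.basal_mean)


class TestVentricularMean:
    def test_identical_cohort_normalises_to_one(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 50.0
        roi = img > 0
        bg = np.zeros_like(roi)
        bg[:3, :3] = True
        grids = [PixelGrid(img, 1.0) for _ in range(4)]
        vals = [ventricular_mean_intensity(g, roi, bg) for g in grids]
        assert np.allclose(normalise_cohort(vals), 1.0)

    def test_background_equal_to_signal_gives_zero(self):
        img = np.full((20, 20), 30.0)
        roi = np.zeros((20, 20), bool)
        roi[5:15, 5:15] = True
        bg = np.zeros_like(roi)
        bg[:3, :3] = True
        assert ventricular_mean_intensity(PixelGrid(img, 1.0), roi, bg) == 0.0

    def test_known_amplitudes_recovered_proportionally(self):
        rng = np.random.default_rng(1)
        amps = np.array([20.0, 40.0, 80.0])
        vals = []
        roi = np.zeros((30, 30), bool)
        roi[10:20, 10:20] = True
        bg = np.zeros_like(roi)
        bg[:4, :4] = True
        for a in amps:
            img = rng.normal(5.0, 0.2, (30, 30))
            img[roi] += a
            vals.append(ventricular_mean_intensity(PixelGrid(img, 1.0), roi, bg))
        ratio = normalise_cohort(vals) / (amps / amps.mean())
        assert np.allclose(ratio, 1.0, atol=0.02)

    def test_overlapping_rois_rejected(self):
        roi = np.ones((10, 10), bool)
        with pytest.raises(InputError):
            ventricular_mean_intensity(PixelGrid(np.zeros((10, 10)), 1.0), roi, roi)


class TestColocalisation:
    def test_bright_everywhere_gives_100_percent(self):
        img = np.full((60, 60), 10.0)
        img[20:40, 20:40] = 200.0
        a = PixelGrid(img, 0.5)
        b = PixelGrid(img.copy(), 0.5)
        bg = np.zeros((60, 60), bool)
        bg[:8, :8] = True
        ts = [_ts_at(15.0, 15.0), _ts_at(14.0, 16.0)]
        tab = colocalisation_at_ts(ts, a, b, bg, radius_um=1.5)
        assert tab.percent == 100

    def test_reported_percent_arithmetic(self):
        # count -> half-up rounded integer percent, e.g. 20 of 41 -> 49 %
        recs = pd.DataFrame(
            dict(ts_id=range(41), presence_A=[True] * 41,
                 presence_B=[True] * 20 + [False] * 21)
        )
        tab = ColocTable(records=recs, n_total=41, n_coloc=20)
        assert tab.percent == 49
        assert round_half_up(100 * 10 / 15) == 67
        assert round_half_up(100 * 11 / 13) == 85

    def test_percent_is_permutation_invariant(self):
        rng = np.random.default_rng(0)
        pres = rng.random(30) < 0.6
        recs = pd.DataFrame(dict(ts_id=range(30), presence_A=True, presence_B=pres))
        t1 = ColocTable(recs, 30, int(pres.sum()))
        perm = rng.permutation(30)
        t2 = ColocTable(recs.iloc[perm].reset_index(drop=True), 30, int(pres.sum()))
        assert t1.percent == t2.percent

    def test_absence_detected_against_background(self):
        img_a = np.full((60, 60), 10.0)
        img_a[28:32, 28:32] = 200.0
        img_b = np.full((60, 60), 10.0)  # channel B dark at the TS
        bg = np.zeros((60, 60), bool)
        bg[:8, :8] = True
        ts = [_ts_at(15.0, 15.0)]
        tab = colocalisation_at_ts(ts, PixelGrid(img_a, 0.5), PixelGrid(img_b, 0.5), bg)
        assert tab.records.presence_A.iloc[0]
        assert not tab.records.presence_B.iloc[0]
        assert tab.n_coloc == 0


class TestWidthMonotonicity:
    def test_wider_lines_reduce_noise_variance(self):
        rng = np.random.default_rng(3)
        variances = {1: [], 4: [], 10: []}
        path = np.array([[5.0, 25.0], [45.0, 25.0]])
        for _ in range(15):
            img = PixelGrid(rng.normal(100, 10, (50, 50)), 1.0)
            for w in variances:
                variances[w].append(line_profile(img, path, width_px=w).raw.var())
        means = {w: np.mean(v) for w, v in variances.items()}
        assert means[1] > means[4] > means[10]
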