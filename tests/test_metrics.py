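"""Gaussian kernel weights, ellipse membership, dwell time and WSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wsdgaze as wg
from wsdgaze.metrics import fwhm_to_sigma, gaussian_weight
from .conftest import make_trial

GEOM = wg.GeometryConfig()
KCFG = wg.KernelConfig()  # sigma 0.75 deg = 45 px, 3-decimal weights


class TestGaussianWeight:
    @pytest.mark.parametrize(
        "d_px, expected",
        [
            (60.0, 0.411),  # 1 degree from the POI -> ~0.41
            (120.0, 0.029),  # 2 degrees -> ~0.03
            (0.0, 1.0),
        ],
    )
    def test_worked_values_at_default_sigma(self, d_px, expected):
        assert gaussian_weight(d_px, 45.0) == pytest.approx(expected, abs=1e-12)

    def test_half_maximum_at_fwhm_over_two(self):
        d = 45.0 * np.sqrt(2 * np.log(2))
        assert gaussian_weight(d, 45.0) == 0.5

    def test_two_degree_fwhm_gives_085_sigma(self):
        # the foveal-vision kernel variant: FWHM 2 deg <-> sigma 0.85 deg
        assert fwhm_to_sigma(2.0) == pytest.approx(0.85, abs=0.005)
        assert wg.sigma_to_fwhm(fwhm_to_sigma(2.0)) == 2.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_weight(10.0, 0.0)

    @given(
        st.floats(0, 500, allow_nan=False),
        st.floats(0, 500, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_decreasing_in_distance(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert gaussian_weight(lo, 45.0) >= gaussian_weight(hi, 45.0)

    def test_vectorized_matches_scalar(self):
        d = np.array([0.0, 30.0, 60.0, 200.0])
        w = gaussian_weight(d, 45.0)
        assert w.shape == d.shape
        assert all(w[i] == gaussian_weight(float(d[i]), 45.0) for i in range(len(d)))


class TestEllipse:
    def test_center_and_boundary(self):
        aoi = wg.EllipseAOI("img", "face", (500, 500), (100, 50), rotation=0.4)
        assert aoi.contains(aoi.center)
        boundary = (
            500 + 100 * np.cos(0.4),
            500 + 100 * np.sin(0.4),
        )  # endpoint of the major axis
        assert aoi.contains(boundary)

    def test_axis_aligned_membership(self):
        aoi = wg.EllipseAOI("img", "face", (500, 500), (100, 50))
        assert wg.ellipse_contains(aoi, (600, 500))  # on the boundary
        assert not wg.ellipse_contains(aoi, (601, 500))
        assert not wg.ellipse_contains(aoi, (500, 551))

    def test_rotation_parametrization_symmetric(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(300, 700, size=(200, 2))
        a = wg.EllipseAOI("img", "x", (500, 500), (80, 40), rotation=0.7)
        b = wg.EllipseAOI("img", "x", (500, 500), (80, 40), rotation=0.7 + np.pi)
        np.testing.assert_array_equal(a.contains(pts), b.contains(pts))

    def test_area(self):
        aoi = wg.EllipseAOI("img", "face", (0, 0), (100, 50))
        assert aoi.area_px2 == pytest.approx(np.pi * 5000)

    def test_invalid_axes(self):
        with pytest.raises(ValueError):
            wg.EllipseAOI("img", "face", (0, 0), (0, 50))


class TestDwellTime:
    def test_inside_outside(self):
        aoi = wg.EllipseAOI("img0", "face", (800, 450), (50, 50))
        trial = make_trial(
            fixations=[(1, 800, 450, 400), (2, 810, 450, 200), (3, 1200, 450, 300)]
        )
        # the first fixation (400 ms, dead center) is excluded by design
        assert wg.aoi_dwell_time(trial, aoi) == 200.0

    def test_no_fixation_inside(self):
        aoi = wg.EllipseAOI("img0", "face", (0, 0), (10, 10))
        trial = make_trial()
        assert wg.aoi_dwell_time(trial, aoi) == 0.0

    def test_matches_per_fixation_oracle(self):
        rng = np.random.default_rng(3)
        fx = [(i + 1, *rng.uniform(400, 1200, 2), rng.uniform(100, 500)) for i in range(10)]
        trial = make_trial(fixations=fx)
        aoi = wg.EllipseAOI("img0", "face", (800, 450), (120, 70), rotation=0.3)
        oracle = sum(
            dur
            for (idx, x, y, dur) in fx
            if idx > 1 and wg.ellipse_contains(aoi, (x, y))
        )
        assert wg.aoi_dwell_time(trial, aoi) == pytest.approx(oracle)


class TestWSD:
    def test_fixation_on_poi_keeps_full_duration(self):
        poi = wg.POI("img0", "face", 820.0, 470.0)
        trial = make_trial(fixations=[(1, 800, 450, 400), (2, 820, 470, 300)])
        assert wg.wsd(trial, poi, KCFG, GEOM) == 300.0

    def test_mixed_distances_worked_example(self):
        # 200 ms at the POI + 100 ms one degree away: 200*1.000 + 100*0.411
        poi = wg.POI("img0", "face", 800.0, 450.0)
        trial = make_trial(
            fixations=[(1, 700, 400, 999), (2, 800, 450, 200), (3, 860, 450, 100)]
        )
        assert wg.wsd(trial, poi, KCFG, GEOM) == pytest.approx(241.1)

    def test_far_fixations_round_to_zero(self):
        poi = wg.POI("img0", "face", 0.0, 0.0)
        trial = make_trial(
            fixations=[(1, 800, 450, 400), (2, 300, 0, 500), (3, 0, 500, 800)]
        )  # both analyzable fixations are >= 5 sigma away
        assert wg.wsd(trial, poi, KCFG, GEOM) == 0.0

    def test_bounded_by_total_duration(self, small_pipeline):
        ds = small_pipeline["dataset"]
        pois = small_pipeline["pois"]
        poi_by_key = {(p.image_id, p.label): p for p in pois}
        for trial in ds.retained_trials[:50]:
            poi = poi_by_key.get((trial.image_id, "face1"))
            val = wg.wsd(trial, poi, KCFG, GEOM)
            assert 0.0 <= val <= trial.total_analyzable_ms + 1e-9

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        fx = [(i + 1, *rng.uniform(0, 1000, 2), rng.uniform(100, 400)) for i in range(8)]
        trial = make_trial(fixations=fx)
        poi = wg.POI("img0", "face", 480.0, 520.0)
        shift = np.array([123.4, -56.7])
        moved = trial.shifted(shift)
        poi_moved = wg.POI("img0", "face", 480.0 + shift[0], 520.0 + shift[1])
        assert wg.wsd(trial, poi, KCFG, GEOM) == pytest.approx(
            wg.wsd(moved, poi_moved, KCFG, GEOM)
        )
        aoi = wg.EllipseAOI("img0", "face", (480, 520), (90, 60), 0.2)
        aoi_moved = wg.EllipseAOI(
            "img0", "face", (480 + shift[0], 520 + shift[1]), (90, 60), 0.2
        )
        assert wg.aoi_dwell_time(trial, aoi) == pytest.approx(
            wg.aoi_dwell_time(moved, aoi_moved)
        )

    def test_monotone_as_fixation_approaches_poi(self):
        poi = wg.POI("img0", "face", 800.0, 450.0)
        values = []
        for dist in (300.0, 200.0, 100.0, 50.0, 0.0):
            trial = make_trial(
                fixations=[(1, 0, 0, 100), (2, 800.0 + dist, 450.0, 250.0)]
            )
            values.append(wg.wsd(trial, poi, KCFG, GEOM))
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_dwell_equals_wsd_with_indicator_kernel(self):
        # the uniform-kernel view of dwell time: weight = 1 inside, 0 outside
        rng = np.random.default_rng(11)
        fx = [(i + 1, *rng.uniform(600, 1000, 2), rng.uniform(100, 400)) for i in range(20)]
        trial = make_trial(fixations=fx)
        aoi = wg.EllipseAOI("img0", "face", (800, 450), (100, 80), 0.5)
        inside = aoi.contains(trial.analyzable_xy)
        uniform_kernel_sum = float((trial.analyzable_durations * inside).sum())
        assert wg.aoi_dwell_time(trial, aoi) == pytest.approx(uniform_kernel_sum)


class TestMetricTable:
    def _simple_setup(self):
        aois = [
            wg.EllipseAOI("img0", "face1", (300, 300), (60, 60)),
            wg.EllipseAOI("img0", "contact", (900, 600), (40, 40)),
        ]
        pois = [
            wg.POI("img0", "face1", 300, 300),
            wg.POI("img0", "contact", 900, 600),
        ]
        trials = [
            make_trial(pid="P0", img="img0",
                       fixations=[(1, 800, 450, 400), (2, 310, 300, 3000)]),
            make_trial(pid="P1", img="img0",
                       fixations=[(1, 800, 450, 400), (2, 1000, 600, 3200)]),
        ]
        return wg.Dataset(trials, GEOM), aois, pois

    def test_rows_per_trial_and_label(self):
        ds, aois, pois = self._simple_setup()
        mt = wg.metric_table(ds, aois, pois, KCFG)
        assert len(mt) == 4  # 2 trials x 2 labels
        assert set(mt["label"]) == {"face1", "contact"}

    def test_zero_dwell_nonzero_wsd_flags(self):
        ds, aois, pois = self._simple_setup()
        mt = wg.metric_table(ds, aois, pois, KCFG)
        row = mt[(mt.participant_id == "P1") & (mt.label == "contact")].iloc[0]
        # fixation 100 px from the POI: outside the 40 px AOI, weight 0.085
        assert row.aoi_dwell_ms == 0.0 and row.dwell_zero
        assert row.wsd_ms == pytest.approx(0.085 * 3200)
        assert not row.wsd_zero

    def test_discarded_trials_absent(self):
        ds, aois, pois = self._simple_setup()
        ds.trials[0].discarded = True
        mt = wg.metric_table(ds, aois, pois, KCFG)
        assert "P0" not in set(mt["participant_id"])

    def test_target_on_absent_image_warns_and_omits(self):
        ds, aois, pois = self._simple_setup()
        aois.append(wg.EllipseAOI("img_missing", "face1", (10, 10), (5, 5)))
        with pytest.warns(UserWarning, match="img_missing"):
            mt = wg.metric_table(ds, aois, pois, KCFG)
        assert "img_missing" not in set(mt["image_id"])
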