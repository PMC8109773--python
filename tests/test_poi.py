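"""Spherical GMM fitting, BIC model selection and POI definition."""

import numpy as np
import pandas as pd
import pytest

import wsdgaze as wg
from wsdgaze.poi import (
    GmmSettings,
    SphericalMixtureSelector,
    define_pois,
    fit_spherical_gmm,
    match_components_to_aois,
    select_k,
)
from .conftest import make_trial


def density_sum_loglik(points, means, sigmas, weights):
    """Independent oracle: total log-likelihood by direct density summation."""
    pts = np.asarray(points, dtype=float)
    total = 0.0
    for x in pts:
        dens = 0.0
        for m, s, w in zip(means, sigmas, weights):
            d2 = float(np.sum((x - m) ** 2))
            dens += w * np.exp(-d2 / (2 * s**2)) / (2 * np.pi * s**2)
        total += np.log(dens)
    return total


def two_cluster_points(rng, n=400, centers=((300, 300), (700, 300)), sigma=30.0):
    half = n // 2
    return np.concatenate(
        [rng.normal(c, sigma, size=(half, 2)) for c in centers]
    )


class TestFitSphericalGMM:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        pts = rng.normal((500, 400), (40, 60), size=(500, 2))
        fit = fit_spherical_gmm(pts, k=1, seed=0)
        np.testing.assert_allclose(fit.means[0], pts.mean(axis=0), atol=1e-6)
        # spherical MLE variance: mean of the two per-axis (biased) variances
        expected_var = pts.var(axis=0, ddof=0).mean()
        assert fit.sigmas[0] ** 2 == pytest.approx(expected_var, rel=1e-6)
        assert fit.weights[0] == pytest.approx(1.0)

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(1)
        pts = two_cluster_points(rng)
        fit = fit_spherical_gmm(pts, k=2, seed=0)
        recovered = sorted(map(tuple, fit.means))
        for rec, true in zip(recovered, [(300, 300), (700, 300)]):
            assert np.hypot(rec[0] - true[0], rec[1] - true[1]) < 5.0

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_loglik_and_bic_match_density_sum_oracle(self, k):
        rng = np.random.default_rng(2)
        pts = two_cluster_points(rng, n=180)  # n <= 200 keeps the oracle cheap
        fit = fit_spherical_gmm(pts, k=k, seed=3)
        oracle_ll = density_sum_loglik(pts, fit.means, fit.sigmas, fit.weights)
        assert fit.log_likelihood == pytest.approx(oracle_ll, abs=1e-6)
        n, p = len(pts), 4 * k - 1
        assert fit.n_parameters == p
        assert fit.bic == pytest.approx(p * np.log(n) - 2 * oracle_ll, abs=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        pts = two_cluster_points(rng)
        a = fit_spherical_gmm(pts, k=3, seed=9)
        b = fit_spherical_gmm(pts, k=3, seed=9)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.bic == b.bic

    def test_more_components_than_points_raises(self):
        with pytest.raises(ValueError, match="at least"):
            fit_spherical_gmm(np.zeros((3, 2)) + [[1, 1], [2, 2], [3, 3]], k=4)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        fit = fit_spherical_gmm(two_cluster_points(rng), k=5, seed=0)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(fit.sigmas > 0)


class TestSelectK:
    def test_three_cluster_data_selects_three(self):
        rng = np.random.default_rng(6)
        pts = np.concatenate(
            [
                rng.normal(c, 30.0, size=(300, 2))
                for c in [(300, 300), (800, 300), (550, 700)]
            ]
        )
        sel = select_k(pts, k_range=range(1, 8), repeats=5, seed=0)
        assert sel.chosen_k == 3
        assert sel.best_fit.k == 3

    def test_reproducible_bic_curve(self):
        rng = np.random.default_rng(7)
        pts = two_cluster_points(rng, n=200)
        a = select_k(pts, k_range=range(1, 5), repeats=4, seed=42)
        b = select_k(pts, k_range=range(1, 5), repeats=4, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        np.testing.assert_array_equal(a.best_fit.means, b.best_fit.means)

    def test_k_range_truncated_to_sample_size(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 2]], dtype=float)
        with pytest.warns(UserWarning, match="truncated"):
            sel = select_k(pts, k_range=range(1, 51), repeats=2, seed=0)
        assert sel.table["k"].max() <= 5

    def test_mean_bic_has_spread_column(self):
        rng = np.random.default_rng(8)
        sel = select_k(two_cluster_points(rng), k_range=range(1, 4), repeats=3, seed=0)
        assert {"k", "mean_bic", "sd_bic", "n_converged"} <= set(sel.table.columns)
        assert (sel.table["sd_bic"] >= 0).all()


class TestSklearnEstimator:
    def test_fit_attributes_and_predict(self):
        rng = np.random.default_rng(9)
        pts = two_cluster_points(rng)
        est = SphericalMixtureSelector(k_min=1, k_max=4, repeats=3, random_state=0)
        labels = est.fit_predict(pts)
        assert est.k_ == 2
        assert est.means_.shape == (2, 2)
        assert labels.shape == (len(pts),)
        # points from one cluster get one label
        assert len(set(labels[:200])) == 1 and len(set(labels[200:])) == 1

    def test_clonable_params(self):
        from sklearn.base import clone

        est = SphericalMixtureSelector(k_max=7, repeats=2, random_state=5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            SphericalMixtureSelector().predict(np.zeros((3, 2)))


def gmm_result(means, sigmas, weights, k=None):
    from wsdgaze.poi import GMMResult

    means = np.asarray(means, dtype=float)
    k = k or len(means)
    return GMMResult(
        k=k, means=means, sigmas=np.asarray(sigmas, float),
        weights=np.asarray(weights, float), log_likelihood=0.0, bic=0.0,
        converged=True, seed=0, n_samples=100,
    )


class TestMatching:
    AOI = wg.EllipseAOI("img", "face1", (500, 500), (80, 80))

    def test_component_at_center_matches(self):
        fit = gmm_result([[500, 500]], [30], [1.0])
        assert match_components_to_aois(fit, [self.AOI]) == {"face1": 0}

    def test_highest_weight_wins(self):
        fit = gmm_result([[510, 500], [490, 500]], [30, 30], [0.05, 0.30])
        assert match_components_to_aois(fit, [self.AOI]) == {"face1": 1}

    def test_no_component_inside_flags_fallback(self):
        fit = gmm_result([[900, 900]], [30], [1.0])
        assert match_components_to_aois(fit, [self.AOI]) == {"face1": None}

    def test_component_serves_at_most_one_aoi(self):
        other = wg.EllipseAOI("img", "face2", (520, 500), (80, 80))
        fit = gmm_result([[510, 500], [530, 500]], [30, 30], [0.6, 0.4])
        mapping = match_components_to_aois(fit, [self.AOI, other])
        assert sorted(v for v in mapping.values() if v is not None) == [0, 1]
        assert len(set(mapping.values())) == 2


def _dataset_for_define(rng, face_center=(400, 300), contact_center=(1200, 700),
                        n_trials=40, face_frac=0.7):
    """Trials whose fixations cluster at the face target; contact ignored."""
    trials = []
    for i in range(n_trials):
        n_fix = 25
        pts = []
        for _ in range(n_fix):
            if rng.random() < face_frac:
                pts.append(rng.normal(face_center, 45.0, 2))
            else:
                pts.append(rng.uniform((0, 0), (1600, 900), 2))
        fx = [(1, 800.0, 450.0, 400.0)] + [
            (j + 2, float(x), float(y), 250.0) for j, (x, y) in enumerate(pts)
        ]
        trials.append(make_trial(pid=f"P{i}", img="img0", fixations=fx))
    return wg.Dataset(trials, wg.GeometryConfig())


class TestDefinePois:
    def test_gmm_poi_recovery_and_contact_fallback(self):
        rng = np.random.default_rng(10)
        ds = _dataset_for_define(rng)
        aois = [
            wg.EllipseAOI("img0", "face1", (400, 300), (80, 80)),
            wg.EllipseAOI("img0", "contact", (1200, 700), (40, 40)),
        ]
        result = define_pois(ds, aois, GmmSettings(k_min=1, k_max=6, repeats=4), seed=0)
        by_label = {p.label: p for p in result.pois}
        face = by_label["face1"]
        assert face.provenance == "gmm_component"
        assert np.hypot(face.x - 400, face.y - 300) < 10.0
        # no fixation cluster near the contact AOI -> AOI-center fallback
        assert by_label["contact"].provenance == "aoi_center_fallback"
        assert (by_label["contact"].x, by_label["contact"].y) == (1200, 700)
        assert result.sigma.n_components >= 1
        assert result.sigma.mean_px == pytest.approx(45.0, abs=12.0)

    def test_image_without_fixations_falls_back_entirely(self):
        rng = np.random.default_rng(11)
        ds = _dataset_for_define(rng, n_trials=5)
        aois = [wg.EllipseAOI("img_empty", "face1", (100, 100), (50, 50))]
        with pytest.warns(UserWarning, match="no retained fixations"):
            result = define_pois(ds, aois, GmmSettings(k_max=3, repeats=2), seed=0)
        assert result.pois[0].provenance == "aoi_center_fallback"

    def test_sigma_is_arithmetic_mean_of_matched_components(self):
        # two single-cluster images with very different spreads: the pooled
        # estimate must be the plain average of the matched sigmas
        rng = np.random.default_rng(12)
        trials = []
        for img, sig in [("imgA", 30.0), ("imgB", 60.0)]:
            for i in range(20):
                pts = rng.normal((500, 400), sig, size=(30, 2))
                fx = [(1, 800.0, 450.0, 400.0)] + [
                    (j + 2, float(x), float(y), 250.0) for j, (x, y) in enumerate(pts)
                ]
                trials.append(make_trial(pid=f"P{i}", img=img, fixations=fx))
        ds = wg.Dataset(trials, wg.GeometryConfig())
        aois = [
            wg.EllipseAOI("imgA", "face1", (500, 400), (90, 90)),
            wg.EllipseAOI("imgB", "face1", (500, 400), (150, 150)),
        ]
        result = define_pois(ds, aois, GmmSettings(k_min=1, k_max=3, repeats=3), seed=1)
        sigmas = [f.sigmas[match_components_to_aois(f, [a])["face1"]]
                  for (img, f), a in zip(sorted(result.fits.items()), aois)]
        assert result.sigma.mean_px == pytest.approx(np.mean(sigmas), abs=1e-9)
        assert result.sigma.mean_px == pytest.approx(45.0, abs=8.0)
        assert result.sigma.mean_deg == pytest.approx(result.sigma.mean_px / 60.0)

    def test_manual_override_forces_fallback(self):
        rng = np.random.default_rng(13)
        ds = _dataset_for_define(rng)
        aois = [wg.EllipseAOI("img0", "face1", (400, 300), (80, 80))]
        result = define_pois(
            ds, aois, GmmSettings(k_max=4, repeats=2), seed=0,
            manual_overrides={("img0", "face1"): None},
        )
        assert result.pois[0].provenance == "aoi_center_fallback"

    def test_poi_csv_round_trip(self, tmp_path):
        from wsdgaze.io import read_pois, write_pois

        rng = np.random.default_rng(14)
        ds = _dataset_for_define(rng)
        aois = [wg.EllipseAOI("img0", "face1", (400, 300), (80, 80))]
        result = define_pois(ds, aois, GmmSettings(k_max=3, repeats=2), seed=0)
        path = tmp_path / "pois.csv"
        write_pois(result.pois, path)
        back = read_pois(path)
        assert [(p.image_id, p.label, p.x, p.y, p.provenance) for p in back] == [
            (p.image_id, p.label, p.x, p.y, p.provenance) for p in result.pois
        ]
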