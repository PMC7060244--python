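"""Tests for FPCA, QDA and the end-to-end classification rule."""

import numpy as np
import pandas as pd
import pytest

from lakethermal.classify import (ClassifierPipeline, cell_center,
                                  classify_location, fit_fpca, fit_qda,
                                  project_scores, reconstruct, train_pipeline)
from lakethermal.curves import SeasonalCurve, fit_population, seasonal_profile
from lakethermal.synthetic import generate_population, make_archetype

GRID12 = (np.arange(12) + 0.5) / 12
GRID96 = (np.arange(96) + 0.5) / 96


def curve(vals, grid=GRID96):
    return SeasonalCurve(grid, np.asarray(vals, dtype=float))


class TestFPCA:
    def test_rank_one_family_explained_by_first_component(self):
        shape = np.sin(2 * np.pi * GRID96)
        curves = [curve(10.0 + a * shape) for a in (-2, -1, 0.5, 1, 3)]
        model = fit_fpca(curves, n_retained=2)
        assert model.explained_fraction[0] == pytest.approx(1.0, abs=1e-8)

    def test_identical_curves_rejected(self):
        curves = [curve(np.full(96, 5.0))] * 4
        with pytest.raises(ValueError, match="zero variance"):
            fit_fpca(curves)

    def test_eigenvalues_match_dense_covariance_oracle(self):
        """FPCA eigenvalues = (weighted) dense covariance eigenvalues."""
        rng = np.random.default_rng(0)
        y = rng.standard_normal((20, 12)) + 10.0
        curves = [curve(v, GRID12) for v in y]
        model = fit_fpca(curves, n_retained=2)
        w = 1.0 / 12
        yc = y - y.mean(axis=0)
        dense = (yc.T @ yc) / (len(y) - 1) * w
        oracle = np.sort(np.linalg.eigvalsh(dense))[::-1]
        np.testing.assert_allclose(model.eigenvalues[:12], np.clip(oracle, 0, None),
                                   atol=1e-8)

    def test_eigenfunctions_orthonormal_under_quadrature(self):
        rng = np.random.default_rng(1)
        curves = [curve(10 + rng.standard_normal(96)) for _ in range(15)]
        model = fit_fpca(curves)
        phi = model.eigenfunctions[:5]
        gram = (phi * model.weights) @ phi.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_explained_fractions_sorted_and_sum_to_one(self):
        rng = np.random.default_rng(2)
        curves = [curve(rng.standard_normal(96)) for _ in range(10)]
        model = fit_fpca(curves)
        ef = model.explained_fraction
        assert np.all(np.diff(ef) <= 1e-12)
        assert ef.sum() == pytest.approx(1.0, abs=1e-8)


class TestProjection:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(3)
        curves = [curve(15 + np.cumsum(rng.standard_normal(96)) * 0.3)
                  for _ in range(25)]
        return fit_fpca(curves, n_retained=2), curves

    def test_mean_curve_projects_to_origin(self, model):
        m, _ = model
        s = project_scores(curve(m.mean_curve), m)
        np.testing.assert_allclose(s, 0.0, atol=1e-10)

    def test_eigen_direction_projects_to_unit_scores(self, model):
        m, _ = model
        s = project_scores(curve(m.mean_curve + 2.0 * m.eigenfunctions[0]), m)
        np.testing.assert_allclose(s, [2.0, 0.0], atol=1e-8)

    def test_reconstruction_error_bounded_by_discarded_variance(self, model):
        """Parseval: squared error of a 2-score reconstruction is at most the
        curve's total squared deviation (and equals it minus retained energy)."""
        m, curves = model
        w = m.weights
        for c in curves[:10]:
            s = project_scores(c, m)
            recon = reconstruct(s, m)
            err = np.sum(w * (c.values - recon) ** 2)
            total = np.sum(w * (c.values - m.mean_curve) ** 2)
            retained = np.sum(s ** 2)
            assert err <= total - retained + 1e-8

    def test_reconstruction_improves_with_more_components(self, model):
        m, curves = model
        w = m.weights
        errs = []
        for k in (1, 2, 5, 10):
            m.n_retained = k
            tot = 0.0
            for c in curves:
                recon = reconstruct(project_scores(c, m), m)
                tot += np.sum(w * (c.values - recon) ** 2)
            errs.append(tot)
        m.n_retained = 2
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_resampling_from_finer_grid(self, model):
        m, _ = model
        fine = (np.arange(192) + 0.5) / 192
        vals = np.interp(fine, m.grid, m.mean_curve, period=1.0)
        s = project_scores(SeasonalCurve(fine, vals), m)
        np.testing.assert_allclose(s, 0.0, atol=5e-3)


class TestQDA:
    def test_symmetric_classes_midpoint_posterior(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((50, 2)) * 0.5 + [-3.0, 0.0]
        b = rng.standard_normal((50, 2)) * 0.5 + [3.0, 0.0]
        b = -a + [0.0, 0.0]  # exact mirror for exact symmetry
        b[:, 0] += 0.0
        x = np.vstack([a, b])
        labels = ["L"] * 50 + ["R"] * 50
        q = fit_qda(x, labels, reg_eps=0.0)
        post = q.posterior(np.array([[0.0, 0.0]]))[0]
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-10)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((60, 2))
        labels = np.repeat(["a", "b", "c"], 20)
        q = fit_qda(x, labels)
        pts = rng.standard_normal((30, 2)) * 5
        np.testing.assert_allclose(q.posterior(pts).sum(axis=1), 1.0, atol=1e-12)

    def test_discriminants_match_hand_computed_gaussians(self):
        """Log joint equals log prior + hand-coded Gaussian log density."""
        xa = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        xb = np.array([[4.0, 4.0], [6.0, 4.0], [4.0, 7.0], [6.0, 7.0]])
        q = fit_qda(np.vstack([xa, xb]), ["a"] * 4 + ["b"] * 4, reg_eps=0.0)
        pt = np.array([2.0, 3.0])
        lj = q.log_joint(pt)[0]
        for j, xc in enumerate((xa, xb)):
            mu = xc.mean(axis=0)
            cov = np.cov(xc, rowvar=False)
            diff = pt - mu
            hand = (np.log(0.5) - 0.5 * np.log(np.linalg.det(cov))
                    - 0.5 * diff @ np.linalg.solve(cov, diff)
                    - np.log(2 * np.pi))
            assert lj[j] == pytest.approx(hand, abs=1e-10)

    def test_matches_sklearn_qda_posteriors(self):
        """Independent cross-check against sklearn's QDA (no regularization)."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
        rng = np.random.default_rng(6)
        x = np.vstack([rng.standard_normal((40, 2)) + [0, 0],
                       rng.standard_normal((40, 2)) * 1.5 + [4, 2]])
        y = np.repeat(["a", "b"], 40)
        ours = fit_qda(x, y, reg_eps=0.0)
        sk = QuadraticDiscriminantAnalysis(store_covariance=True).fit(x, y)
        pts = rng.standard_normal((20, 2)) * 3 + [2, 1]
        np.testing.assert_allclose(ours.posterior(pts), sk.predict_proba(pts),
                                   atol=1e-8)

    def test_argmax_posterior_equals_discriminant_argmax(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((30, 2)) + 3])
        y = np.repeat(["a", "b"], 30)
        q = fit_qda(x, y)
        pts = rng.standard_normal((50, 2)) * 4
        np.testing.assert_array_equal(np.argmax(q.posterior(pts), axis=1),
                                      np.argmax(q.log_joint(pts), axis=1))

    def test_tiny_class_requires_regularization(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="reg_eps"):
            fit_qda(x, ["a", "a", "b"], reg_eps=0.0)
        q = fit_qda(x, ["a", "a", "b"], reg_eps=1e-6)
        assert np.isfinite(q.log_joint(np.array([1.0, 1.0]))).all()


class TestEndToEnd:
    @pytest.fixture(scope="class")
    def trained(self, request):
        series, truth = generate_population(
            {"NF": 12, "NC": 12, "TH": 12, "SW": 12}, n_years=4, seed=21)
        fits = fit_population(series)
        profiles = [seasonal_profile(f) for f in fits]
        clf = train_pipeline(profiles, truth)
        return clf, series, truth

    def test_training_series_reassigned_to_own_label(self, trained):
        clf, series, truth = trained
        hits = sum(clf.classify_series(s)[0] == t
                   for s, t in zip(series, truth))
        assert hits / len(series) >= 0.96

    def test_short_series_rejected(self, trained):
        clf, series, _ = trained
        from lakethermal.synthetic import LakeSeries
        with pytest.raises(ValueError, match="1 year|24"):
            short = LakeSeries("x", series[0].values[:24], series[0].ice_flags[:24], 1)
            short.values = short.values[:23]
            short.ice_flags = short.ice_flags[:23]
            clf.classify_series(short)

    def test_noiseless_archetype_classified_with_high_confidence(self, trained):
        clf, _, _ = trained
        series, _ = generate_population({"TH": 1}, 0, 0, 0, n_years=4)
        code, post, _ = clf.classify_series(series[0])
        assert code == "TH"
        assert post.max() > 0.99

    def test_json_round_trip_preserves_decisions(self, trained):
        clf, series, _ = trained
        clf2 = ClassifierPipeline.from_json(clf.to_json())
        for s in series[::6]:
            c1, p1, s1 = clf.classify_series(s)
            c2, p2, s2 = clf2.classify_series(s)
            assert (c1, s1) == (c2, s2)
            np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestLocation:
    GRID = pd.DataFrame({
        "lat_center": [51.0, 51.0, -33.0],
        "lon_center": [-1.0, 1.0, 151.0],
        "region_code": ["NT", "NT", "SW"],
        "posterior": [0.9, 0.8, 0.95],
    })

    def test_cell_center_convention(self):
        assert cell_center(51.0, -1.0) == (51.0, -1.0)
        assert cell_center(50.0, -2.0) == (51.0, -1.0)   # south/west inclusive
        assert cell_center(49.999, -0.001) == (49.0, -1.0)
        assert cell_center(-0.5, 179.5) == (-1.0, 179.0)
        assert cell_center(90.0, 0.0)[0] == 89.0          # pole clamps inward

    def test_exact_center_hit(self):
        res = classify_location(51.0, -1.0, self.GRID)
        assert res.region_code == "NT"
        assert res.posterior == pytest.approx(0.9)

    def test_shared_edge_goes_to_north_east_cell(self):
        # lat 50 / lon 0 are south/west edges of the cell centred (51, 1)
        res = classify_location(50.0, 0.0, self.GRID)
        assert res.region_code == "NT"
        assert res.posterior == pytest.approx(0.8)

    def test_ocean_cell_reports_no_lake(self):
        res = classify_location(0.0, -140.0, self.GRID)
        assert not res.is_lake_cell
        assert res.reason == "no lake cell"
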