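"""Point-pattern statistics: clipping, quadrats, ppm, K, ellipses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from contourpass import gaze as gz
from contourpass.errors import (
    GeometryError,
    InsufficientDataError,
    InvalidArgumentError,
    NestingError,
)


def _pattern(pts, **marks):
    df = pd.DataFrame(dict(x_deg=pts[:, 0], y_deg=pts[:, 1]))
    for k, v in marks.items():
        df[k] = v
    return gz.PointPattern(df)


class TestClip:
    def test_central_points_kept(self):
        df = pd.DataFrame(dict(x_deg=[0.0, 0.0], y_deg=[0.0, 0.0],
                               group=["a", "a"]))
        pat, log = gz.clip_to_window(df)
        assert len(pat) == 2
        assert log["fraction_excluded"].iloc[0] == 0.0

    def test_boundary_inclusive_outside_excluded(self):
        df = pd.DataFrame(dict(x_deg=[20.0, 25.0, -20.0, 0.0],
                               y_deg=[0.0, 0.0, 11.25, -11.26]))
        pat, log = gz.clip_to_window(df)
        assert len(pat) == 2
        assert log["n_excluded"].iloc[0] == 2

    def test_wider_dispersion_excludes_more(self, rng):
        """Excluded fraction grows with dispersion, matching the bivariate
        normal rectangle probability."""
        sigma = 15.0
        pts = rng.normal(0, sigma, size=(20000, 2))
        df = pd.DataFrame(dict(x_deg=pts[:, 0], y_deg=pts[:, 1]))
        _, log = gz.clip_to_window(df)
        p_in = ((stats.norm.cdf(20 / sigma) - stats.norm.cdf(-20 / sigma))
                * (stats.norm.cdf(11.25 / sigma)
                   - stats.norm.cdf(-11.25 / sigma)))
        assert log["fraction_excluded"].iloc[0] == pytest.approx(
            1 - p_in, abs=0.01)


class TestQuadrat:
    def test_balanced_counts_give_zero(self):
        # one point in the middle of each of the 25 quadrats
        gx = -20 + (np.arange(5) + 0.5) * 8
        gy = -11.25 + (np.arange(5) + 0.5) * 4.5
        pts = np.array([(x, y) for x in gx for y in gy])
        out = gz.quadrat_test(_pattern(pts))
        assert out["chi2"] == 0.0
        assert out["df"] == 24

    def test_hand_computed_example(self):
        """100 points in 2x2 quadrats with counts (40, 20, 20, 20):
        chi2 = (15^2 + 3 * 5^2) / 25 = 12 on 3 df."""
        quads = [(-10, -5, 40), (10, -5, 20), (-10, 5, 20), (10, 5, 20)]
        pts = np.concatenate([np.tile([(x, y)], (n, 1))
                              for x, y, n in quads])
        out = gz.quadrat_test(_pattern(pts), 2, 2)
        assert out["chi2"] == pytest.approx(12.0)
        assert out["df"] == 3

    def test_empty_pattern_rejected(self):
        with pytest.raises(InsufficientDataError):
            gz.quadrat_test(_pattern(np.empty((0, 2))))


class TestPpm:
    def test_intercept_only_matches_analytic_mle(self, rng):
        pts = gz.simulate_ipp(0.6, rng=rng)
        m = gz.fit_ppm(_pattern(pts), spatial_degree=0)
        assert m.coefficients["const"] == pytest.approx(
            np.log(len(pts) / 900.0), abs=1e-6)
        # score equation: fitted integral reproduces the point count
        assert m.integral == pytest.approx(len(pts), rel=1e-3)

    def test_nested_loglik_never_decreases(self, rng):
        pts = gz.simulate_ipp(0.5, rng=rng)
        pat = _pattern(pts)
        lls = [gz.fit_ppm(pat, d).loglik for d in (0, 1, 2)]
        assert lls[1] >= lls[0] - 1e-8
        assert lls[2] >= lls[1] - 1e-8

    def test_matches_statsmodels_glm_oracle(self, rng):
        """Dual route: the hand-rolled IRLS agrees with statsmodels' GLM on
        the same Berman-Turner quadrature."""
        import statsmodels.api as sm

        beta = dict(const=np.log(1.2), x=0.03, y=-0.04)
        f = lambda x, y: np.exp(beta["const"] + 0.03 * x - 0.04 * y)
        pts = gz.simulate_ipp(f, rng=rng)
        pat = _pattern(pts)
        mine = gz.fit_ppm(pat, spatial_degree=1)
        quad = gz._quadrature_frame(pat, (), (64, 36))
        X = np.column_stack([np.ones(len(quad)), quad["x_deg"],
                             quad["y_deg"]])
        w = quad["_w"].to_numpy()
        yv = (quad["_z"] / quad["_w"]).to_numpy()
        res = sm.GLM(yv, X, family=sm.families.Poisson(),
                     var_weights=w).fit()
        assert np.allclose(mine.coefficients.to_numpy(), res.params,
                           atol=1e-6)
        assert np.allclose(mine.bse.to_numpy(), res.bse, rtol=1e-4)

    def test_log_quadratic_recovery_within_two_se(self, rng):
        beta = dict(const=np.log(2.0), x=0.02, y=-0.03, x2=-0.01,
                    y2=-0.02, xy=0.005)
        f = lambda x, y: np.exp(beta["const"] + beta["x"] * x
                                + beta["y"] * y + beta["x2"] * x * x
                                + beta["y2"] * y * y + beta["xy"] * x * y)
        pts = gz.simulate_ipp(f, rng=rng)
        m = gz.fit_ppm(_pattern(pts), spatial_degree=2)
        for name, true in beta.items():
            err = abs(m.coefficients[name] - true)
            assert err < 3.5 * m.bse[name]

    def test_covariate_effect_detected_and_strata_required(self, rng):
        pts_a = gz.simulate_ipp(0.8, rng=rng)
        pts_b = gz.simulate_ipp(0.3, rng=rng)
        df = pd.DataFrame(dict(
            x_deg=np.r_[pts_a[:, 0], pts_b[:, 0]],
            y_deg=np.r_[pts_a[:, 1], pts_b[:, 1]],
            group=["a"] * len(pts_a) + ["b"] * len(pts_b)))
        pat = gz.PointPattern(df)
        null = gz.fit_ppm(pat, 0, strata=("group",))
        full = gz.fit_ppm(pat, 0, covariates=("group",))
        out = gz.lr_test(null, full)
        assert out["df"] == 1
        assert out["p"] < 1e-6
        # the group coefficient recovers the intensity log-ratio
        assert full.coefficients["group[b]"] == pytest.approx(
            np.log(len(pts_b) / len(pts_a)), abs=0.05)
        # covariates not covered by the strata are rejected
        with pytest.raises(InvalidArgumentError):
            gz.fit_ppm(pat, 0, covariates=("group",), strata=())

    def test_lr_requires_matching_strata(self, rng):
        pts = gz.simulate_ipp(0.5, rng=rng)
        pat = _pattern(pts, group="a")
        plain = gz.fit_ppm(pat, 0)
        strat = gz.fit_ppm(pat, 1, strata=("group",))
        with pytest.raises(NestingError):
            gz.lr_test(plain, strat)
        with pytest.raises(NestingError):
            gz.lr_test(gz.fit_ppm(pat, 1), gz.fit_ppm(pat, 1))


class TestSimulateIpp:
    def test_zero_intensity_empty(self, rng):
        assert len(gz.simulate_ipp(0.0, rng=rng)) == 0

    def test_homogeneous_count_distribution(self, rng):
        """lambda = 1 on 900 deg^2: mean count over simulations within 2%."""
        counts = [len(gz.simulate_ipp(1.0, rng=rng)) for _ in range(1000)]
        assert np.mean(counts) == pytest.approx(900, rel=0.02)
        assert np.std(counts) == pytest.approx(30, rel=0.15)

    def test_thinned_quadrat_profile_matches_integral(self, rng):
        """Thinning: mean count in each half-window matches the numeric
        integral of the intensity over it."""
        f = lambda x, y: 0.5 * np.exp(0.05 * x)
        counts_left = counts_right = 0
        for _ in range(200):
            pts = gz.simulate_ipp(f, rng=rng)
            counts_left += (pts[:, 0] < 0).sum()
            counts_right += (pts[:, 0] >= 0).sum()
        from scipy.integrate import quad
        left = quad(lambda x: 0.5 * np.exp(0.05 * x) * 22.5, -20, 0)[0]
        right = quad(lambda x: 0.5 * np.exp(0.05 * x) * 22.5, 0, 20)[0]
        assert counts_left / 200 == pytest.approx(left, rel=0.05)
        assert counts_right / 200 == pytest.approx(right, rel=0.05)


class TestKinhom:
    def test_zero_at_zero(self, rng):
        pts = gz.simulate_ipp(0.5, rng=rng)
        k = gz.kinhom(pts, np.full(len(pts), 0.5), np.array([0.0]))
        assert k[0] == 0.0

    def test_r_range_guard(self, rng):
        pts = gz.simulate_ipp(0.5, rng=rng)
        with pytest.raises(GeometryError):
            gz.kinhom(pts, np.full(len(pts), 0.5), np.array([12.0]))

    def test_poisson_matches_pi_r_squared(self, rng):
        r = np.array([1.0, 2.0, 3.0, 5.0])
        ks = [gz.kinhom(p, np.full(len(p), 0.55), r)
              for p in (gz.simulate_ipp(0.55, rng=rng) for _ in range(80))]
        assert np.allclose(np.mean(ks, axis=0), np.pi * r ** 2, rtol=0.05)

    def test_clustered_pattern_exceeds_poisson_envelope(self, rng):
        """Neyman-Scott (parent-offspring) clustering pushes K above the
        envelope of the homogeneous fit at small r."""
        parents = gz.simulate_ipp(0.02, rng=rng)
        offsets = rng.normal(0, 0.5, size=(len(parents), 25, 2))
        pts = (parents[:, None, :] + offsets).reshape(-1, 2)
        inside = ((np.abs(pts[:, 0]) <= 20) & (np.abs(pts[:, 1]) <= 11.25))
        pat = _pattern(pts[inside])
        model = gz.fit_ppm(pat, spatial_degree=0)
        env = gz.kinhom_envelope(pat, model,
                                 r_grid=np.array([0.5, 1.0, 2.0]),
                                 n_sim=19, rng=rng)
        assert (env["k_obs"] > env["hi"]).all()

    def test_poisson_within_envelope(self, rng):
        pts = gz.simulate_ipp(0.6, rng=rng)
        pat = _pattern(pts)
        model = gz.fit_ppm(pat, spatial_degree=0)
        env = gz.kinhom_envelope(pat, model,
                                 r_grid=np.linspace(0.5, 5, 10),
                                 n_sim=39, rng=rng)
        inside = ((env["k_obs"] >= env["lo"]) & (env["k_obs"] <= env["hi"]))
        assert inside.mean() >= 0.8


class TestDistancesEllipses:
    def test_three_four_five_triangle(self):
        out = gz.pairwise_distance_summary(np.array([[0.0, 0.0],
                                                     [3.0, 4.0]]))
        assert out["median"] == 5.0

    def test_collinear_unit_spacing(self):
        out = gz.pairwise_distance_summary(np.array([[0.0, 0.0], [1.0, 0.0],
                                                     [2.0, 0.0]]))
        assert sorted(out["distances"]) == [1.0, 1.0, 2.0]
        assert out["median"] == 1.0

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            gz.pairwise_distance_summary(np.array([[0.0, 0.0]]))

    def test_isotropic_cloud_is_round(self, rng):
        pts = rng.normal(0, 1, size=(20000, 2))
        es = gz.variance_ellipse(pts)
        assert es.var_max / es.var_min < 1.05
        assert not es.degenerate

    def test_collinear_cloud_degenerate(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        es = gz.variance_ellipse(pts)
        assert es.degenerate and es.area == 0.0

    def test_orientation_of_elongated_cloud(self, rng):
        pts = rng.normal(0, 1, size=(5000, 2)) * [3.0, 0.5]
        es = gz.variance_ellipse(pts)
        assert min(es.orientation_deg, 180 - es.orientation_deg) < 5.0

    def test_f_test_behavior(self, rng):
        equal = gz.variance_f_test(2.0, 100, 2.0, 100)
        assert equal["F"] == 1.0 and equal["p"] == pytest.approx(1.0)
        unequal = gz.variance_f_test(2.0, 500, 1.0, 500)
        assert unequal["p"] < 0.01
        # eigenvalue ratio of an isotropic sample stays near 1
        pts = rng.normal(0, 1, size=(400, 2))
        es = gz.variance_ellipse(pts)
        out = gz.variance_f_test(es.var_max, 400, es.var_min, 400)
        assert out["F"] < 1.4


class TestDispersion:
    def test_identical_points_zero_sd(self):
        df = pd.DataFrame(dict(subject_id=["s"] * 5, group=["g"] * 5,
                               noise_level=[0.0] * 5,
                               x_deg=[1.0] * 5, y_deg=[2.0] * 5))
        out = gz.per_subject_dispersion(df, n_draws=10)
        assert out["table"]["sd_total"].iloc[0] == 0.0

    def test_known_gaussian_dispersion(self, rng):
        sx, sy = 1.5, 0.8
        df = pd.DataFrame(dict(
            subject_id=["s"] * 20000, group=["g"] * 20000,
            noise_level=[0.0] * 20000,
            x_deg=rng.normal(0, sx, 20000), y_deg=rng.normal(0, sy, 20000)))
        out = gz.per_subject_dispersion(df, n_draws=10)
        assert out["table"]["sd_total"].iloc[0] == pytest.approx(
            np.hypot(sx, sy), rel=0.02)


class TestAreaCorrelations:
    def test_planted_negative_coupling_recovered(self, rng):
        """Subjects with larger gaze area get lower accuracy by
        construction; the reported correlation must be significantly
        negative (and the RT coupling positive)."""
        rows_g, rows_a, rows_r = [], [], []
        for i in range(40):
            sigma = rng.uniform(0.3, 2.0)
            pts = rng.normal(0, sigma, size=(100, 2))
            rows_g.append(pd.DataFrame(dict(
                subject_id=f"s{i}", group="g",
                x_deg=pts[:, 0], y_deg=pts[:, 1])))
            rows_a.append(dict(subject_id=f"s{i}",
                               prop_correct=0.9 - 0.1 * sigma
                               + rng.normal(0, 0.02)))
            rows_r.append(dict(subject_id=f"s{i}",
                               median_rt=0.8 + 0.2 * sigma
                               + rng.normal(0, 0.05)))
        out = gz.gaze_area_correlations(
            pd.concat(rows_g), pd.DataFrame(rows_a), pd.DataFrame(rows_r))
        assert out["accuracy"]["r"] < -0.5 and out["accuracy"]["p"] < 0.01
        assert out["rt"]["r"] > 0.5 and out["rt"]["p"] < 0.01
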