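"""Synthetic observer cohort: decision statistics, responses, RT, gaze."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from contourpass import cohort as ch
from contourpass import stimulus as st
from contourpass.errors import InvalidArgumentError


def _trial(grid, contour, cls, delta, seed):
    rng = np.random.default_rng(seed)
    ori = st.assign_orientations(grid, contour, cls, delta, rng)
    return st.TrialStimulus(0, cls, delta, ori, np.asarray(contour), seed)


class TestDecisionStatistic:
    def test_all_template_elements_at_60_give_one(self, default_grid,
                                                  contour_indices):
        tmpl = ch.build_template(default_grid, contour_indices, 0.4)
        ori = np.full(975, 60.0)
        trial = st.TrialStimulus(0, "signal", 0.0, ori, contour_indices, 0)
        assert ch.decision_statistic(trial, tmpl) == pytest.approx(1.0)

    @pytest.mark.parametrize("delta,expected", [(45.0, 0.0), (60.0, -0.5)])
    def test_contour_only_balanced_jitter_is_deterministic(
            self, default_grid, contour_indices, delta, expected):
        """cos is even, so all 12 balanced +/-delta terms equal cos(2 delta):
        the contour-only cosine statistic is deterministic per level."""
        tmpl = ch.build_template(default_grid, contour_indices, 0.0)
        for seed in range(5):
            trial = _trial(default_grid, contour_indices, "signal", delta,
                           seed)
            s = ch.decision_statistic(trial, tmpl)
            assert s == pytest.approx(expected, abs=1e-12)

    def test_empty_template_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ch.Template(indices=np.array([], dtype=int),
                        weights=np.array([]), n_contour=0)

    def test_template_composition(self, default_grid, contour_indices):
        tmpl = ch.build_template(default_grid, contour_indices, 0.25)
        assert tmpl.n_contour == 12
        assert tmpl.indices.size == 12 + 28
        assert np.all(tmpl.weights[:12] == 1.0)
        assert np.all(tmpl.weights[12:] == 0.25)

    def test_channel_statistic_contour_is_one_on_signal(self, default_grid,
                                                        contour_indices):
        """Every balanced-jitter contour element matches one of the two
        channels exactly, so a contour-only channel statistic is
        1 + collinearity term."""
        obs = ch.ObserverParams(template_weight_bg=0.0,
                                collinearity_weight=0.0)
        tmpl = ch.build_template(default_grid, contour_indices, 0.0)
        for delta in (0.0, 10.0, 45.0, 60.0):
            trial = _trial(default_grid, contour_indices, "signal", delta, 3)
            assert ch.channel_statistic(trial, tmpl, obs) == pytest.approx(1.0)

    def test_collinearity_of_straight_and_alternating(self):
        assert ch.collinearity_statistic(np.full(12, 60.0)) == 1.0
        alternating = 60.0 + 45.0 * np.array([1, -1] * 6)
        assert ch.collinearity_statistic(alternating) == pytest.approx(-1.0)

    def test_expected_statistics_match_monte_carlo(self, default_grid,
                                                   contour_indices):
        obs = ch.ObserverParams()   # channel rule defaults
        tmpl = ch.build_template(default_grid, contour_indices,
                                 obs.template_weight_bg)
        rng = np.random.default_rng(0)
        for delta in (10.0, 45.0):
            sig = [ch.channel_statistic(
                _trial(default_grid, contour_indices, "signal", delta, s),
                tmpl, obs) for s in range(400)]
            noi = [ch.channel_statistic(
                _trial(default_grid, contour_indices, "noise", delta, s),
                tmpl, obs) for s in range(400, 800)]
            mu_s, mu_n = ch.expected_statistics(obs, delta)
            assert np.mean(sig) == pytest.approx(mu_s, abs=0.01)
            assert np.mean(noi) == pytest.approx(mu_n, abs=0.02)


class TestSimulateResponse:
    def test_noiseless_threshold(self, default_grid, contour_indices):
        obs = ch.ObserverParams(sigma_add=0.0, k_mult=0.0, lapse=0.0,
                                criterion=0.5, template_weight_bg=0.0,
                                decision_rule="cosine")
        tmpl = ch.build_template(default_grid, contour_indices, 0.0)
        trial = _trial(default_grid, contour_indices, "signal", 0.0, 0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            out = ch.simulate_response(trial, obs, rng, tmpl)
            assert out["response"] == "yes"
            assert out["decision_stat"] == pytest.approx(1.0)

    def test_gaussian_tail_probability(self, default_grid, contour_indices):
        """sigma_add 0.5, criterion 0.5, contour-only cosine template at
        delta 0 (s = 1): P(yes|signal) = Phi(1) ~ 0.841."""
        obs = ch.ObserverParams(sigma_add=0.5, k_mult=0.0, lapse=0.0,
                                criterion=0.5, template_weight_bg=0.0,
                                decision_rule="cosine")
        tmpl = ch.build_template(default_grid, contour_indices, 0.0)
        trial = _trial(default_grid, contour_indices, "signal", 0.0, 0)
        rng = np.random.default_rng(123)
        n = 20000
        yes = sum(ch.simulate_response(trial, obs, rng, tmpl)["response"]
                  == "yes" for _ in range(n))
        assert yes / n == pytest.approx(norm.cdf(1.0), abs=0.01)

    def test_guessing_limit_under_huge_noise(self, default_grid,
                                             contour_indices):
        obs = ch.ObserverParams(sigma_add=1e6, k_mult=0.0, lapse=0.0,
                                criterion=0.0, template_weight_bg=0.0,
                                decision_rule="cosine")
        tmpl = ch.build_template(default_grid, contour_indices, 0.0)
        trial = _trial(default_grid, contour_indices, "signal", 0.0, 0)
        rng = np.random.default_rng(5)
        yes = sum(ch.simulate_response(trial, obs, rng, tmpl)["response"]
                  == "yes" for _ in range(4000))
        assert yes / 4000 == pytest.approx(0.5, abs=0.03)


class TestSimulateRtGaze:
    def test_rt_mean_identity(self, rng):
        obs = ch.ObserverParams(rt_shift=0.3, rt_scale=0.2, rt_shape=2.0,
                                rt_noise_slope=0.01)
        delta = 45.0
        draws = ch.simulate_rt(delta, obs, rng, size=100000)
        expected = 0.3 + 2.0 * 0.2 * (1 + 0.01 * delta)
        assert draws.mean() == pytest.approx(expected, rel=0.02)
        assert draws.min() > 0.3

    def test_rt_slope_zero_is_level_independent(self):
        obs = ch.ObserverParams(rt_noise_slope=0.0)
        a = ch.simulate_rt(0.0, obs, np.random.default_rng(3), size=5000)
        b = ch.simulate_rt(60.0, obs, np.random.default_rng(3), size=5000)
        assert np.array_equal(a, b)

    def test_gaze_degenerate_at_zero_sigma(self, rng):
        obs = ch.ObserverParams(gaze_sigma0=1e-12, gaze_mu=(1.0, -2.0),
                                gaze_outlier_rate=0.0)
        pts = ch.simulate_gaze(obs, 0.0, 50, rng)
        assert np.allclose(pts, [1.0, -2.0], atol=1e-9)

    def test_gaze_covariance_recovery(self, rng):
        obs = ch.ObserverParams(gaze_sigma0=0.5, gaze_noise_slope=0.01,
                                gaze_aspect=1.6, gaze_outlier_rate=0.0)
        delta = 45.0
        pts = ch.simulate_gaze(obs, delta, 100000, rng)
        sd = 0.5 * (1 + 0.01 * delta)
        cov = np.cov(pts.T)
        assert cov[0, 0] == pytest.approx((1.6 * sd) ** 2, rel=0.02)
        assert cov[1, 1] == pytest.approx(sd ** 2, rel=0.02)
        assert abs(cov[0, 1]) < 0.01

    def test_dispersion_ratio_squares_variance_ratio(self, rng):
        a = ch.ObserverParams(gaze_sigma0=0.6, gaze_outlier_rate=0.0)
        b = ch.ObserverParams(gaze_sigma0=0.4, gaze_outlier_rate=0.0)
        pa = ch.simulate_gaze(a, 0.0, 50000, rng)
        pb = ch.simulate_gaze(b, 0.0, 50000, rng)
        assert pa[:, 1].var() / pb[:, 1].var() == pytest.approx(2.25,
                                                                rel=0.05)


class TestCohort:
    def test_cohort_shape(self, cohort_data):
        subs = cohort_data.subjects
        assert (subs["group"] == "ASD").sum() == 24
        assert (subs["group"] == "TD").sum() == 32
        per_subject = cohort_data.trials.groupby("subject_id").size()
        assert (per_subject == 480).all()
        assert len(cohort_data.gaze) == 56 * 480

    def test_cohort_determinism(self, cohort_data):
        again = ch.simulate_cohort(master_seed=0)
        for a, b in ((cohort_data.trials, again.trials),
                     (cohort_data.gaze, again.gaze),
                     (cohort_data.subjects, again.subjects)):
            assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_double_pass_coherence(self, cohort_data):
        """Frozen stimuli: identical decision statistics across passes,
        while responses are allowed to differ (fresh internal noise)."""
        tr = cohort_data.trials
        repeated = tr[tr["noise_level"].isin([10.0, 45.0])]
        any_response_differs = False
        for (sid, lv), g in repeated.groupby(["subject_id", "noise_level"]):
            p1 = g[g["pass_index"] == 1].sort_values("trial_index")
            p2 = g[g["pass_index"] == 2].sort_values("trial_index")
            assert len(p1) == len(p2) == 60
            assert np.allclose(p1["decision_stat"].values,
                               p2["decision_stat"].values)
            if (p1["response"].values != p2["response"].values).any():
                any_response_differs = True
        assert any_response_differs

    def test_zero_internal_noise_means_full_agreement(self):
        """With no internal noise and no lapses the two passes agree on
        every trial."""
        cfg = ch.default_cohort_config()
        from dataclasses import replace
        groups = tuple(
            replace(g, n_subjects=2,
                    observer=replace(g.observer, sigma_add=0.0, k_mult=0.0,
                                     lapse=0.0),
                    sigma_add_lognorm_sd=0.0, k_mult_lognorm_sd=0.0)
            for g in cfg.groups)
        data = ch.simulate_cohort(ch.CohortConfig(groups=groups),
                                  master_seed=3)
        tr = data.trials
        repeated = tr[tr["noise_level"].isin([10.0, 45.0])]
        for (sid, lv), g in repeated.groupby(["subject_id", "noise_level"]):
            p1 = g[g["pass_index"] == 1].sort_values("trial_index")
            p2 = g[g["pass_index"] == 2].sort_values("trial_index")
            assert (p1["response"].values == p2["response"].values).all()

    def test_cosine_observer_accuracy_non_increasing(self):
        """The spec's plain cosine observer declines monotonically with
        jitter (through chance at 45 into below-chance at 60)."""
        from dataclasses import replace
        cfg = ch.default_cohort_config()
        groups = tuple(
            replace(g, n_subjects=3,
                    observer=replace(g.observer, decision_rule="cosine",
                                     lapse=0.0))
            for g in cfg.groups)
        data = ch.simulate_cohort(ch.CohortConfig(groups=groups),
                                  master_seed=5)
        acc = (data.trials[data.trials["pass_index"] == 1]
               .groupby("noise_level")["correct"].mean())
        acc = acc.sort_index().to_numpy()
        assert np.all(np.diff(acc) <= 0.05)   # Monte-Carlo tolerance
        assert acc[0] > 0.9
        assert acc[-1] < 0.5

    def test_iq_and_noise_latent_coupling(self, cohort_data):
        """Subjects drawn noisier (larger sigma_add) should tend to have
        lower IQ within group (planted negative latent loading)."""
        subs = cohort_data.subjects
        r = np.corrcoef(subs["sigma_add"], subs["iq"])[0, 1]
        assert r < -0.1
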