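"""Vertex statistics and posterior-simulation peak-shift inference."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aveffort.models import MixedModelFit, ModelSpec, fit_lmm
from aveffort.peaks import (
    PeakPosterior,
    draw_posterior,
    peak_posterior,
    peak_shift_inference,
    recover_shift_end_to_end,
    vertex_from_coefficients,
)

from conftest import simulate_condition_table

PRINTED_PUPIL_BETA = {
    "intercept": 0.25, "mod": 0.05, "snr": 0.003,
    "mod:snr": -0.005, "snr2": -0.001, "mod:snr2": 2e-4,
}


def make_fit(beta, vcov_scale=1e-8, names=None):
    names = names or tuple(beta)
    v = np.eye(len(names)) * vcov_scale
    return MixedModelFit(
        beta=dict(beta), vcov=v, names=tuple(names),
        sigma2_subject=0.0, sigma2_resid=1.0, n_obs=168,
        converged=True, outcome="ppd", center_snr=-6.0,
    )


class TestVertexFormula:
    def test_zero_linear_term_peaks_at_center(self):
        v = vertex_from_coefficients({"snr": 0.0, "snr2": -0.001,
                                      "mod:snr": 0.0, "mod:snr2": 0.0})
        assert v["peak_ao_c"] == 0.0  # centered zero, i.e. -6 dB raw

    def test_group_level_pupil_coefficients(self):
        """The fitted pupil coefficients put the AO peak at -4.5 dB, the AV
        peak at -7.25 dB, a shift of 2.75 dB."""
        v = vertex_from_coefficients(PRINTED_PUPIL_BETA)
        assert v["peak_ao_c"] == pytest.approx(1.5)
        assert v["peak_av_c"] == pytest.approx(-1.25)
        assert v["peak_ao_c"] - v["peak_av_c"] == pytest.approx(2.75)
        assert v["ao_concave"] and v["av_concave"]

    def test_convex_vertex_flagged_as_minimum(self):
        v = vertex_from_coefficients({"snr": 0.003, "snr2": 0.001,
                                      "mod:snr": 0.0, "mod:snr2": 0.0})
        assert not v["ao_concave"]

    def test_zero_quadratic_rejected(self):
        with pytest.raises(ValueError, match="zero quadratic"):
            vertex_from_coefficients({"snr": 0.003, "snr2": 0.0,
                                      "mod:snr": 0.0, "mod:snr2": 0.0})

    def test_vertex_matches_grid_argmax_of_fitted_curve(self, rng):
        """For random concave coefficient draws the closed form agrees with a
        0.001 dB grid argmax over the centered range."""
        grid = np.arange(-30.0, 30.0 + 1e-9, 0.001)
        for _ in range(25):
            beta = {
                "snr": rng.uniform(-0.01, 0.01),
                "snr2": rng.uniform(-0.01, -1e-4),
                "mod:snr": rng.uniform(-0.005, 0.005),
                "mod:snr2": 0.0,
            }
            v = vertex_from_coefficients(beta)
            curve = beta["snr"] * grid + beta["snr2"] * grid**2
            if abs(v["peak_ao_c"]) < 29:
                assert abs(v["peak_ao_c"] - grid[np.argmax(curve)]) <= 0.001


class TestDrawPosterior:
    def test_zero_covariance_returns_point_estimates(self, rng):
        fit = make_fit(PRINTED_PUPIL_BETA, vcov_scale=0.0)
        draws = draw_posterior(fit, n_draws=50, rng=rng)
        for name, value in PRINTED_PUPIL_BETA.items():
            assert np.allclose(draws[name], value)

    def test_fixed_seed_reproducible(self):
        fit = make_fit(PRINTED_PUPIL_BETA, vcov_scale=1e-6)
        a = draw_posterior(fit, 100, np.random.default_rng(5))
        b = draw_posterior(fit, 100, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_sample_mean_approaches_estimates(self):
        fit = make_fit(PRINTED_PUPIL_BETA, vcov_scale=1e-6)
        draws = draw_posterior(fit, 100_000, np.random.default_rng(0))
        for name, value in PRINTED_PUPIL_BETA.items():
            tol = 4 * np.sqrt(1e-6) / np.sqrt(100_000)
            assert draws[name].mean() == pytest.approx(value, abs=tol)

    def test_asymmetric_vcov_rejected(self):
        fit = make_fit(PRINTED_PUPIL_BETA)
        fit.vcov[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            draw_posterior(fit, 10, np.random.default_rng(0))

    def test_negative_definite_vcov_rejected(self):
        fit = make_fit(PRINTED_PUPIL_BETA)
        fit.vcov[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive semi-definite"):
            draw_posterior(fit, 10, np.random.default_rng(0))


class TestShiftInference:
    def test_identical_draws_error_out_of_t_test(self):
        post = PeakPosterior(
            peak_ao_c=np.full(100, 1.5), peak_av_c=np.full(100, -1.1),
            center_snr=-6.0, concave_mask=np.ones(100, bool), n_nonfinite=0,
        )
        assert post.shift_draws.mean() == pytest.approx(2.6)
        with pytest.raises(ValueError, match="zero-variance"):
            peak_shift_inference(post)

    def test_normal_shift_draws_recover_mean_and_reject_null(self):
        rng = np.random.default_rng(0)
        shift = rng.normal(2.6, 1.0, 1000)
        post = PeakPosterior(
            peak_ao_c=shift, peak_av_c=np.zeros(1000),
            center_snr=-6.0, concave_mask=np.ones(1000, bool), n_nonfinite=0,
        )
        res = peak_shift_inference(post)
        assert res.ci95[0] < 2.6 < res.ci95[1]
        assert res.p_one_sided < 0.05
        assert res.mean_shift_db == pytest.approx(2.6, abs=0.1)
        assert res.p_shift_nonpositive == pytest.approx(stats.norm.cdf(-2.6), abs=0.02)

    def test_pairing_matters(self):
        """Permuting paired draws together changes nothing; independently
        shuffling one margin changes the t statistic."""
        rng = np.random.default_rng(1)
        common = rng.normal(0, 5.0, 1000)  # strongly correlated margins
        ao = 2.0 + common + rng.normal(0, 0.1, 1000)
        av = common + rng.normal(0, 0.1, 1000)
        post = PeakPosterior(ao, av, -6.0, np.ones(1000, bool), 0)
        res = peak_shift_inference(post)
        perm = rng.permutation(1000)
        post_perm = PeakPosterior(ao[perm], av[perm], -6.0, np.ones(1000, bool), 0)
        assert peak_shift_inference(post_perm).t_statistic == pytest.approx(res.t_statistic)
        post_broken = PeakPosterior(ao, av[rng.permutation(1000)], -6.0,
                                    np.ones(1000, bool), 0)
        broken = peak_shift_inference(post_broken)
        assert abs(broken.t_statistic) < abs(res.t_statistic) / 3

    def test_near_zero_quadratic_draws_blow_up_interval(self):
        """When the curvature is poorly resolved relative to its SE the
        vertex draws are a heavy-tailed ratio and the percentile interval
        widens to tens of dB."""
        names = ("snr", "mod:snr", "snr2", "mod:snr2")
        tight = make_fit({"snr": 0.02, "mod:snr": -0.001, "snr2": -0.002,
                          "mod:snr2": 0.0}, names=names)
        tight.vcov = np.diag([1e-6, 1e-6, 1e-8, 1e-8])
        loose = dataclasses.replace(tight)
        loose.vcov = np.diag([1e-4, 1e-4, 9e-6, 9e-6])  # SE ~ 1.5x |snr2|
        rng = np.random.default_rng(2)
        res_t = peak_shift_inference(peak_posterior(draw_posterior(tight, 1000, rng)))
        res_l = peak_shift_inference(peak_posterior(draw_posterior(loose, 1000, rng)))
        assert res_t.ci95[1] - res_t.ci95[0] < 2.0
        assert res_l.ci95[1] - res_l.ci95[0] > 20.0
        assert res_l.n_nonconcave > 0

    def test_concavity_filter_reported(self):
        names = ("snr", "mod:snr", "snr2", "mod:snr2")
        fit = make_fit({"snr": 0.02, "mod:snr": 0.0, "snr2": -0.002,
                        "mod:snr2": 0.0}, names=names)
        fit.vcov = np.diag([1e-4, 1e-4, 9e-6, 9e-6])
        post = peak_posterior(draw_posterior(fit, 1000, np.random.default_rng(3)))
        res = peak_shift_inference(post, concavity_filter=True)
        assert res.concavity_filtered
        assert res.n_used == 1000 - post.n_nonconcave

    def test_shrinking_vcov_concentrates_on_plugin_shift(self):
        plugin = vertex_from_coefficients(PRINTED_PUPIL_BETA)
        plugin_shift = plugin["peak_ao_c"] - plugin["peak_av_c"]
        names = tuple(PRINTED_PUPIL_BETA)
        spreads = []
        for scale in (1e-8, 1e-10, 1e-12):
            fit = make_fit(PRINTED_PUPIL_BETA, vcov_scale=scale, names=names)
            post = peak_posterior(draw_posterior(fit, 500, np.random.default_rng(4)))
            res = peak_shift_inference(post)
            spreads.append(res.ci95[1] - res.ci95[0])
            assert res.mean_shift_db == pytest.approx(plugin_shift, abs=10 * np.sqrt(scale) * 5000)
        assert spreads[0] > spreads[1] > spreads[2]

    def test_centered_and_raw_peaks_differ_by_center_only(self):
        post = PeakPosterior(
            peak_ao_c=np.array([1.5, 1.0]), peak_av_c=np.array([-1.25, -1.0]),
            center_snr=-6.0, concave_mask=np.ones(2, bool), n_nonfinite=0,
        )
        ao_db, av_db = post.peaks_db()
        assert np.allclose(ao_db - post.peak_ao_c, -6.0)
        assert np.allclose(av_db - post.peak_av_c, -6.0)
        # the shift is centering-invariant
        assert np.allclose(ao_db - av_db, post.shift_draws)


class TestEndToEnd:
    def test_noiseless_study_recovers_true_shift(self, tiny_pupil_study):
        res = recover_shift_end_to_end(
            tiny_pupil_study, "ppd", rng=np.random.default_rng(0)
        )
        assert res["true_shift_db"] == pytest.approx(2.75)
        assert abs(res["shift_error_db"]) < 0.2
        assert abs(res["posterior_mean_error_db"]) < 0.2

    def test_posterior_interval_from_fitted_model_covers_plugin(self, rng):
        table = simulate_condition_table(
            PRINTED_PUPIL_BETA, 21, rng, sigma_subject=0.03, sigma_resid=0.02
        )
        fit = fit_lmm(table, ModelSpec(outcome="ppd"))
        post = peak_posterior(draw_posterior(fit, 1000, rng))
        res = peak_shift_inference(post)
        plugin = vertex_from_coefficients(fit.beta)
        assert res.ci95[0] <= plugin["peak_ao_c"] - plugin["peak_av_c"] <= res.ci95[1]
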