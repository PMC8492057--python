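"""Template-matching CCA: oracle equivalence against grid search, pattern
algebra, component selection/sign convention, and projection linearity."""

import numpy as np
import pytest

from neurosep.cca import (fit_template_cca, activation_patterns,
                          select_and_standardize, project_trials,
                          RankDeficientError)
from neurosep.preprocess import Epochs

SRATE = 5000.0


def template(times_ms):
    w = (-np.exp(-((times_ms - 20.0) / 3.5) ** 2)
         + 0.55 * np.exp(-((times_ms - 35.0) / 6.0) ** 2))
    return w / np.abs(w).max()


def toy_epochs(pattern, n_trials=60, noise=0.3, seed=0, gain_sd=0.4):
    """Known mixing: per-trial gain x template through a channel pattern."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, 100.0, 1000.0 / SRATE)
    tmpl = template(times)
    gains = 1.0 + gain_sd * rng.standard_normal(n_trials)
    pattern = np.asarray(pattern, float)
    data = (gains[:, None, None] * pattern[None, :, None] * tmpl[None, None, :]
            + noise * rng.standard_normal((n_trials, pattern.size, times.size)))
    return Epochs(data=data, times=times, srate=SRATE), gains, tmpl


def grid_search_rho(epochs, window, n_theta=3142):
    """Independent oracle: exhaustive scan of 2-D filter directions.

    For each direction w the best achievable correlation with the template
    side is the Rayleigh quotient sqrt(w'Cxy Cyy^-1 Cyx w / w'Cxx w);
    maximized over theta in [0, pi)."""
    idx = epochs.time_indices(*window)
    trials = epochs.data[:, :, idx]
    avg = trials.mean(axis=0)
    X = np.concatenate(list(trials), axis=1)
    Y = np.tile(avg, (1, trials.shape[0]))
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    m = Xc.shape[1]
    cxx, cyy = Xc @ Xc.T / (m - 1), Yc @ Yc.T / (m - 1)
    cxy = Xc @ Yc.T / (m - 1)
    K = cxy @ np.linalg.solve(cyy, cxy.T)
    thetas = np.pi * np.arange(n_theta) / n_theta
    W = np.vstack([np.cos(thetas), np.sin(thetas)])  # (2, n_theta)
    num = np.einsum("ct,cd,dt->t", W, K, W)
    den = np.einsum("ct,cd,dt->t", W, cxx, W)
    rho = np.sqrt(num / den)
    return thetas[np.argmax(rho)], rho.max()


class TestOracleEquivalence:
    def test_two_channel_toy_matches_grid_search(self):
        pattern = np.array([0.8, 0.6])
        epochs, _, _ = toy_epochs(pattern, seed=1)
        res = fit_template_cca(epochs, window=(5, 80), shrinkage=0.0)
        theta_star, rho_star = grid_search_rho(epochs, (5, 80))
        assert res.rho[0] == pytest.approx(rho_star, abs=1e-6)
        w = res.w_x[:, 0]
        theta_fit = np.arctan2(w[1], w[0]) % np.pi
        dtheta = min(abs(theta_fit - theta_star),
                     np.pi - abs(theta_fit - theta_star))
        assert dtheta < 2e-3

    def test_noiseless_single_source_perfect_match(self):
        # identical noiseless trials: the template match is exact
        pattern = np.array([0.6, -0.3, 0.74])
        epochs, _, _ = toy_epochs(pattern, noise=0.0, gain_sd=0.0, seed=2)
        res = fit_template_cca(epochs, window=(5, 80))
        assert res.rho[0] == pytest.approx(1.0, abs=1e-6)
        pat = res.patterns[:, 0]
        cos = abs(pat @ pattern) / np.linalg.norm(pattern)
        assert cos > 0.999

    def test_channel_permutation_equivariance(self):
        pattern = np.array([0.5, -0.4, 0.6, 0.2])
        epochs, _, _ = toy_epochs(pattern, seed=3)
        perm = np.array([2, 0, 3, 1])
        permuted = Epochs(data=epochs.data[:, perm], times=epochs.times,
                          srate=SRATE)
        a = fit_template_cca(epochs, window=(5, 80))
        b = fit_template_cca(permuted, window=(5, 80))
        np.testing.assert_allclose(a.rho, b.rho, atol=1e-8)
        for k in range(a.n_components):
            cos = abs(a.w_x[perm, k] @ b.w_x[:, k]) / (
                np.linalg.norm(a.w_x[:, k]) * np.linalg.norm(b.w_x[:, k]))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_rank_deficient_without_shrinkage_raises(self):
        pattern = np.array([0.8, 0.6, 0.0])
        epochs, _, _ = toy_epochs(pattern, seed=4)
        # average-reference the toy: channel means removed -> rank deficit
        data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
        ref = Epochs(data=data, times=epochs.times, srate=SRATE)
        with pytest.raises(RankDeficientError, match="shrinkage"):
            fit_template_cca(ref, window=(5, 80), shrinkage=0.0)
        fit_template_cca(ref, window=(5, 80), shrinkage=1e-6)  # regularized: ok

    def test_noise_rho_shrinks_with_trial_count(self):
        # canonical correlation on pure noise is pure overfitting; its
        # median decreases as trials accumulate
        medians = []
        for n in (10, 100, 1000):
            rhos = []
            for seed in range(5):
                rng = np.random.default_rng(100 * n + seed)
                times = np.arange(0.0, 50.0, 1000.0 / SRATE)
                data = rng.standard_normal((n, 4, times.size))
                ep = Epochs(data=data, times=times, srate=SRATE)
                rhos.append(fit_template_cca(ep, window=(5, 45)).rho[0])
            medians.append(np.median(rhos))
        assert medians[0] > medians[1] > medians[2]


class TestActivationPatterns:
    def test_identity_covariance_pattern_equals_filter(self):
        pattern = np.array([0.8, 0.6])
        epochs, _, _ = toy_epochs(pattern, seed=5)
        res = fit_template_cca(epochs, window=(5, 80))
        rng = np.random.default_rng(6)
        X = rng.standard_normal((2, 5000))
        Xc = X - X.mean(axis=1, keepdims=True)
        chol = np.linalg.cholesky(Xc @ Xc.T / (X.shape[1] - 1))
        white = np.linalg.solve(chol, Xc)  # empirical covariance exactly I
        A = activation_patterns(res, white)
        for k in range(res.n_components):
            w = res.w_x[:, k] / np.linalg.norm(res.w_x[:, k])
            assert abs(A[:, k] @ w) == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        pattern = np.array([0.8, 0.6])
        epochs, _, _ = toy_epochs(pattern, seed=7)
        res = fit_template_cca(epochs, window=(5, 80))
        X = np.concatenate(list(epochs.data), axis=1)
        np.testing.assert_allclose(activation_patterns(res, X),
                                   activation_patterns(res, 2.0 * X), atol=1e-10)

    def test_pattern_recovers_generating_direction(self):
        pattern = np.array([0.5, -0.5, 0.5, -0.5])
        epochs, _, _ = toy_epochs(pattern, noise=0.3, seed=8)
        res = fit_template_cca(epochs, window=(5, 80))
        cos = abs(res.patterns[:, 0] @ pattern) / np.linalg.norm(pattern)
        assert cos > 0.95


class TestSelectionAndSign:
    def test_selected_pattern_matches_truth_and_sign_standardizes(self):
        pattern = np.array([0.6, -0.3, 0.74])
        epochs, _, _ = toy_epochs(pattern, seed=9)
        res = select_and_standardize(fit_template_cca(epochs, window=(5, 80)),
                                     template_pattern=pattern)
        cos = abs(res.patterns[:, res.selected] @ pattern) / np.linalg.norm(pattern)
        assert cos > 0.95
        j = np.argmin(np.abs(res.window_times - 20.0))
        assert res.sign * res.mean_waveforms[res.selected, j] < 0

    def test_flipped_generating_pattern_same_standardized_waveform(self):
        pattern = np.array([0.8, 0.6])
        ep_pos, _, _ = toy_epochs(pattern, seed=10)
        ep_neg = Epochs(data=-ep_pos.data, times=ep_pos.times, srate=SRATE)
        a = select_and_standardize(fit_template_cca(ep_pos, window=(5, 80)))
        b = select_and_standardize(fit_template_cca(ep_neg, window=(5, 80)))
        wa = a.sign * a.mean_waveforms[a.selected]
        wb = b.sign * b.mean_waveforms[b.selected]
        np.testing.assert_allclose(wa, wb, atol=1e-6)

    def test_no_matching_component_raises(self):
        pattern = np.zeros(8)
        pattern[:2] = [0.8, 0.6]
        epochs, _, _ = toy_epochs(pattern, seed=11)
        orthogonal = np.zeros(8)
        orthogonal[6:] = [0.6, -0.8]
        res = fit_template_cca(epochs, window=(5, 80))
        with pytest.raises(ValueError, match="no component"):
            select_and_standardize(res, template_pattern=orthogonal)


class TestProjection:
    def test_projection_is_linear(self):
        pattern = np.array([0.8, 0.6])
        epochs, _, _ = toy_epochs(pattern, seed=12)
        res = select_and_standardize(fit_template_cca(epochs, window=(5, 80)))
        comp = project_trials(epochs, res)
        np.testing.assert_allclose(comp.data[:, 0].mean(axis=0),
                                   (res.sign * res.w_x[:, res.selected]) @
                                   epochs.average(), atol=1e-10)

    def test_noiseless_projection_proportional_to_gain_times_template(self):
        pattern = np.array([0.6, -0.3, 0.74])
        epochs, gains, tmpl = toy_epochs(pattern, noise=0.0, seed=13)
        res = select_and_standardize(fit_template_cca(epochs, window=(5, 80)))
        comp = project_trials(epochs, res).data[:, 0]
        target = gains[:, None] * tmpl[None, :]
        scale = (comp * target).sum() / (target * target).sum()
        np.testing.assert_allclose(comp, scale * target, atol=1e-8)

    def test_channel_mismatch_rejected(self):
        pattern = np.array([0.8, 0.6])
        epochs, _, _ = toy_epochs(pattern, seed=14)
        res = select_and_standardize(fit_template_cca(epochs, window=(5, 80)))
        other = Epochs(data=epochs.data, times=epochs.times, srate=SRATE,
                       ch_names=["a", "b"])
        with pytest.raises(ValueError, match="channel"):
            project_trials(other, res)
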