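"""SDT estimation: rate corrections, d'/c formulas against an independent
quantile oracle, symmetry properties, binning machinery and the permutation
accuracy test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import brentq
from scipy.special import ndtr

import neurosep as ns
from neurosep.sdt import (rates_from_trials, d_prime_and_criterion,
                          cohens_d_paired, extreme_bin_contrast,
                          permutation_accuracy_test)


def quantile_oracle(p: float) -> float:
    """Normal quantile by root-finding on the CDF (independent of norm.ppf)."""
    return brentq(lambda z: ndtr(z) - p, -10.0, 10.0, xtol=1e-12)


class TestRates:
    def test_perfect_performance_corrected(self):
        stim = ["strong"] * 10 + ["weak"] * 10
        resp = list(stim)
        res = rates_from_trials(stim, resp)
        assert res.hit_rate == pytest.approx(0.95)
        assert res.fa_rate == pytest.approx(0.05)
        assert res.corrected

    def test_plain_proportions(self):
        stim = ["strong"] * 100 + ["weak"] * 100
        resp = (["strong"] * 72 + ["weak"] * 28) + (["strong"] * 28 + ["weak"] * 72)
        res = rates_from_trials(stim, resp)
        assert res.hit_rate == pytest.approx(0.72)
        assert res.fa_rate == pytest.approx(0.28)
        assert not res.corrected

    def test_chance_rates(self):
        stim = ["strong"] * 100 + ["weak"] * 100
        resp = (["strong"] * 50 + ["weak"] * 50) * 2
        res = rates_from_trials(stim, resp)
        assert (res.hit_rate, res.fa_rate) == (0.5, 0.5)
        assert res.d_prime == pytest.approx(0.0)

    def test_missing_category_named_in_error(self):
        with pytest.raises(ValueError, match="weak"):
            rates_from_trials(["strong"] * 5, ["strong"] * 5)

    def test_none_responses_excluded(self):
        stim = ["strong"] * 4 + ["weak"] * 4
        resp = ["strong", "strong", "none", "weak", "weak", "weak", "none", "strong"]
        res = rates_from_trials(stim, resp)
        assert res.n_strong == 3 and res.n_weak == 3


class TestDPrimeFormulas:
    @pytest.mark.parametrize("hit,fa,d_exp,c_exp", [
        (0.5, 0.5, 0.0, 0.0),
        (0.84, 0.16, 1.9889, 0.0),      # Phi^-1(0.84) = 0.99446
        (0.9, 0.5, 1.28155, -0.64078),  # Phi^-1(0.9) = 1.28155
    ])
    def test_reference_values(self, hit, fa, d_exp, c_exp):
        d, c = d_prime_and_criterion(hit, fa)
        assert d == pytest.approx(d_exp, abs=1e-4)
        assert c == pytest.approx(c_exp, abs=1e-4)

    def test_matches_independent_quantile_oracle_on_grid(self):
        grid = np.round(np.arange(0.05, 0.96, 0.05), 2)
        for hit in grid:
            for fa in grid:
                d, c = d_prime_and_criterion(hit, fa)
                zh, zf = quantile_oracle(hit), quantile_oracle(fa)
                assert d == pytest.approx(zh - zf, abs=1e-6)
                assert c == pytest.approx(-0.5 * (zh + zf), abs=1e-6)

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="correction"):
            d_prime_and_criterion(1.0, 0.2)

    @given(hit=st.floats(0.01, 0.99), fa=st.floats(0.01, 0.99))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_symmetry_properties(self, hit, fa):
        d, c = d_prime_and_criterion(hit, fa)
        d_sw, _ = d_prime_and_criterion(fa, hit)
        assert d_sw == pytest.approx(-d, abs=1e-9)
        d_m, c_m = d_prime_and_criterion(1.0 - fa, 1.0 - hit)
        assert d_m == pytest.approx(d, abs=1e-9)
        assert c_m == pytest.approx(-c, abs=1e-9)

    def test_criterion_shift_leaves_d_prime_invariant(self):
        # simulated observer with shifted criterion: c moves, d' does not
        n = 100_000
        rng = np.random.default_rng(0)
        stim = np.array(["strong", "weak"])[rng.integers(0, 2, n)]
        evidence = 1.2 * (stim == "strong") + rng.standard_normal(n)
        results = {}
        for shift in (0.0, 0.4):
            resp = np.where(evidence > 1.2 / 2 + shift, "strong", "weak")
            results[shift] = rates_from_trials(stim, resp)
        assert results[0.4].criterion_c - results[0.0].criterion_c == \
            pytest.approx(0.4, abs=0.03)
        assert results[0.4].d_prime == pytest.approx(results[0.0].d_prime, abs=0.05)

    def test_matches_likelihood_grid_on_small_tables(self):
        # ML estimate of (d', c) over a dense parameter grid agrees with the
        # closed-form estimate (the formulas are the exact MLE)
        n_s = n_w = 40
        k_hit, k_fa = 29, 11
        d_grid = np.linspace(-4, 4, 801)
        c_grid = np.linspace(-2, 2, 401)
        D, C = np.meshgrid(d_grid, c_grid, indexing="ij")
        p_hit = ndtr(D / 2 - C)
        p_fa = ndtr(-D / 2 - C)
        ll = (k_hit * np.log(p_hit) + (n_s - k_hit) * np.log1p(-p_hit)
              + k_fa * np.log(p_fa) + (n_w - k_fa) * np.log1p(-p_fa))
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        d_hat, c_hat = d_prime_and_criterion(k_hit / n_s, k_fa / n_w)
        assert d_grid[i] == pytest.approx(d_hat, abs=1e-2)
        assert c_grid[j] == pytest.approx(c_hat, abs=1e-2)


class TestCohensD:
    def test_reference_value(self):
        assert cohens_d_paired([0.0, 2.0]) == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cohens_d_paired([1.0, 1.0, 1.0])

    def test_antisymmetry(self):
        diffs = np.array([0.3, -0.1, 0.8, 0.2])
        assert cohens_d_paired(-diffs) == pytest.approx(-cohens_d_paired(diffs))


class TestExtremeBins:
    def make_table(self, n_subjects=12, n_trials=1000, seed=0, coupled=True):
        cfg = ns.GeneratorConfig(n_subjects=n_subjects, n_trials=n_trials,
                                 seed=seed,
                                 criterion_coupling=-0.08 if coupled else 0.0,
                                 alpha_coupling=-0.7 if coupled else 0.0)
        return ns.simulate_study(cfg)

    def test_quintile_bins_hold_200_of_1000_trials(self):
        tbl = self.make_table(n_subjects=2, seed=1)
        tbl["valid"] = True
        tbl.loc[:, "response"] = np.where(
            np.arange(len(tbl)) % 2 == 0, "weak", "strong")  # all valid
        c = extreme_bin_contrast(tbl, "alpha_log", "criterion_c")
        assert len(c.low_values) == 2
        # floor(1000 * 0.2) = 200 per extreme bin: verified via the count
        sub = tbl[tbl["subject"] == 0]
        assert int(np.floor(len(sub) * 0.2)) == 200

    def test_coupled_generator_shifts_criterion_across_alpha_bins(self):
        c = extreme_bin_contrast(self.make_table(seed=2), "alpha_log",
                                 "criterion_c")
        assert c.mean_high > c.mean_low
        assert c.p < 0.05

    def test_minimum_trial_count_enforced(self):
        tbl = self.make_table(n_subjects=2, n_trials=40, seed=3)
        with pytest.raises(ValueError, match="50"):
            extreme_bin_contrast(tbl, "alpha_log")


class TestPermutationTest:
    def test_perfect_agreement_gives_zero_p(self):
        stim = np.array(["strong", "weak"] * 5, dtype=object)
        assert permutation_accuracy_test(stim, stim.copy(), n_perm=2000,
                                         seed=0) == 0.0

    def test_below_chance_gives_p_near_one(self):
        stim = np.array(["strong", "weak"] * 50, dtype=object)
        resp = np.array(["weak", "strong"] * 50, dtype=object)
        assert permutation_accuracy_test(stim, resp, n_perm=2000, seed=0) > 0.99

    def test_matches_bruteforce_shuffling(self):
        rng = np.random.default_rng(4)
        stim = np.array(["strong"] * 12 + ["weak"] * 8, dtype=object)
        resp = np.array(["strong", "weak"] * 10, dtype=object)
        rng.shuffle(stim)
        observed = int(np.sum(stim == resp))
        accs = []
        for _ in range(20_000):
            perm = rng.permutation(resp)
            accs.append(int(np.sum(stim == perm)))
        p_brute = np.mean(np.asarray(accs) > observed)
        p_fast = permutation_accuracy_test(stim, resp, n_perm=100_000, seed=5)
        assert p_fast == pytest.approx(p_brute, abs=0.02)

    def test_null_p_values_uniform(self):
        # independent responses: p over repeated experiments is ~ Uniform(0,1)
        rng = np.random.default_rng(6)
        ps = []
        for k in range(200):
            stim = np.array(["strong", "weak"])[rng.integers(0, 2, 200)]
            resp = np.array(["strong", "weak"])[rng.integers(0, 2, 200)]
            ps.append(permutation_accuracy_test(stim, resp, n_perm=2000,
                                                seed=1000 + k, add_one=True))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bonferroni_companion(self):
        stim = np.array(["strong", "weak"] * 30, dtype=object)
        p, p_adj = permutation_accuracy_test(stim, stim.copy(), n_perm=1000,
                                             seed=0, family_size=32)
        assert p_adj == min(1.0, p * 32)
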