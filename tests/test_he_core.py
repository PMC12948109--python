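"""Haseman-Elston regression against brute-force oracles, F fidelity,
Delta_norm calibration machinery and the filtering rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hegcor import (
    CorrectionCoefficients, DEFAULT_CORRECTION, HEEstimate, SimSpec,
    calibration_experiment, correction_factor, delta_norm,
    derive_correction_coefficients, filter_rg, filter_traits, he_fit, he_h2,
    he_rg, kinship_from_genotypes, simulate_genotypes, simulate_trait, zscore,
)
from hegcor.he_core import RgEstimate

import pandas as pd


def brute_force_he(M, N, K, idx_M, idx_N):
    """Enumerate pairs one by one and fit OLS by the closed form.

    Same pair rules as the implementation: self-pairs excluded, unordered
    duplicates averaged; slope/SE from the textbook formulas.
    """
    pairs = {}
    for a, i in enumerate(idx_M):
        for b, j in enumerate(idx_N):
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            pairs.setdefault(key, []).append(M[a] * N[b])
    x = np.array([K[i, j] for (i, j) in pairs])
    y = np.array([np.mean(v) for v in pairs.values()])
    n = len(x)
    beta = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    alpha = y.mean() - beta * x.mean()
    rss = np.sum((y - alpha - beta * x) ** 2)
    se = np.sqrt(rss / (n - 2)) / np.sqrt(np.sum((x - x.mean()) ** 2))
    return beta, se, n


def _toy_kinship(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 0.5, size=(n, n))
    K = (A + A.T) / 2.0
    np.fill_diagonal(K, 0.5)
    return K


class TestHeFit:
    def test_matches_pair_enumeration_oracle_same_trait(self):
        rng = np.random.default_rng(2)
        K = _toy_kinship(7, 3)
        M = rng.standard_normal(7)
        fit = he_fit(M, None, K)
        beta, se, n = brute_force_he(M, M, K, np.arange(7), np.arange(7))
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        assert fit.se_beta == pytest.approx(se, abs=1e-10)
        assert fit.n_pairs == n

    def test_matches_oracle_cross_trait_same_animals(self):
        rng = np.random.default_rng(5)
        K = _toy_kinship(8, 9)
        M, N = rng.standard_normal(8), rng.standard_normal(8)
        fit = he_fit(M, N, K)
        beta, se, n = brute_force_he(M, N, K, np.arange(8), np.arange(8))
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        assert fit.se_beta == pytest.approx(se, abs=1e-10)
        assert fit.n_pairs == n

    def test_matches_oracle_disjoint_cohorts(self):
        rng = np.random.default_rng(8)
        K = _toy_kinship(10, 1)
        iM, iN = np.arange(0, 5), np.arange(5, 10)
        M, N = rng.standard_normal(5), rng.standard_normal(5)
        fit = he_fit(M, N, K, idx_M=iM, idx_N=iN)
        beta, se, n = brute_force_he(M, N, K, iM, iN)
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        assert fit.se_beta == pytest.approx(se, abs=1e-10)
        assert fit.n_pairs == n == 25

    def test_matches_oracle_overlapping_cohorts(self):
        rng = np.random.default_rng(13)
        K = _toy_kinship(9, 4)
        iM, iN = np.arange(0, 6), np.arange(3, 9)
        M, N = rng.standard_normal(6), rng.standard_normal(6)
        fit = he_fit(M, N, K, idx_M=iM, idx_N=iN)
        beta, se, n = brute_force_he(M, N, K, iM, iN)
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        assert fit.se_beta == pytest.approx(se, abs=1e-10)
        assert fit.n_pairs == n

    def test_three_animals_make_three_pairs(self):
        K = _toy_kinship(3, 0)
        fit = he_fit(np.array([0.3, -1.0, 0.7]), None, K)
        assert fit.n_pairs == 3

    def test_null_trait_slope_within_noise(self):
        rng = np.random.default_rng(42)
        K = _toy_kinship(60, 6)
        hits = 0
        for _ in range(20):
            fit = he_fit(rng.standard_normal(60), None, K)
            if abs(fit.beta) < 3 * fit.se_beta:
                hits += 1
        assert hits >= 18

    def test_missing_values_dropped(self):
        rng = np.random.default_rng(3)
        K = _toy_kinship(8, 2)
        M = rng.standard_normal(8)
        M[2] = np.nan
        fit = he_fit(M, None, K)
        keep = np.array([i for i in range(8) if i != 2])
        ref = he_fit(M[keep], None, K, idx_M=keep)
        assert fit.beta == pytest.approx(ref.beta)
        assert fit.n_pairs == 21

    def test_constant_kinship_rejected(self):
        K = np.full((5, 5), 0.25)
        with pytest.raises(ValueError, match="zero variance"):
            he_fit(np.random.default_rng(0).standard_normal(5), None, K)


class TestHeH2:
    def test_beta_to_h2_division_by_two(self):
        rng = np.random.default_rng(0)
        K = _toy_kinship(30, 7)
        M = rng.standard_normal(30)
        fit = he_fit(M, None, K)
        est = he_h2(M, K)
        assert est.h2 == pytest.approx(fit.beta / 2.0)
        assert est.se_raw == pytest.approx(fit.se_beta / 2.0)
        assert est.se_corrected == pytest.approx(
            est.se_raw * correction_factor(est.h2, 30))

    def test_recovers_simulated_h2(self):
        ests = []
        for r in range(40):
            G = simulate_genotypes(SimSpec(500, 1000, h2=0.4, seed=300 + r))
            tr = simulate_trait(G, 0.4, 10, seed=600 + r)
            K = kinship_from_genotypes(G)
            ests.append(he_h2(zscore(tr.values), K).h2)
        e = np.array(ests)
        assert abs(e.mean() - 0.4) < 2 * e.std(ddof=1) / np.sqrt(len(e))

    def test_precision_improves_with_sample_size(self):
        sds = []
        for n in (200, 800):
            ests = []
            for r in range(30):
                G = simulate_genotypes(SimSpec(n, 400, h2=0.4, seed=n + r))
                tr = simulate_trait(G, 0.4, 10, seed=2 * n + r)
                K = kinship_from_genotypes(G)
                ests.append(he_h2(zscore(tr.values), K).h2)
            sds.append(np.std(ests, ddof=1))
        assert sds[1] < sds[0]


class TestHeRg:
    def test_self_pair_gives_rg_one(self, small_cohort):
        G, K = small_cohort
        tr = simulate_trait(G, 0.5, 10, seed=2)
        M = zscore(tr.values)
        est_M = he_h2(M, K)
        est = he_rg(M, M, K, est_M, est_M)
        assert est.rho == pytest.approx(est_M.h2)
        assert est.rg == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, small_cohort):
        G, K = small_cohort
        from hegcor import simulate_correlated_pair
        tM, tN = simulate_correlated_pair(G, 0.6, 0.6, 0.5, 50, seed=19)
        M, N = zscore(tM.values), zscore(tN.values)
        eM, eN = he_h2(M, K), he_h2(N, K)
        a = he_rg(M, N, K, eM, eN)
        b = he_rg(N, M, K, eN, eM)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.rg == pytest.approx(b.rg, abs=1e-12)

    def test_nonpositive_h2_flagged_not_nan_surprise(self, small_cohort):
        _, K = small_cohort
        rng = np.random.default_rng(1)
        M = zscore(rng.standard_normal(400))
        bad = HEEstimate(beta=-0.1, h2=-0.05, se_raw=0.1, se_corrected=0.1,
                         p=0.5, n_animals=400, n_pairs=79800)
        good = he_h2(M, K)
        est = he_rg(M, M, K, bad, good)
        assert not est.estimable and not est.valid
        assert est.reason is not None

    def test_se_propagation_formula(self, small_cohort):
        G, K = small_cohort
        tM = simulate_trait(G, 0.5, 10, seed=31)
        tN = simulate_trait(G, 0.5, 10, seed=32)
        M, N = zscore(tM.values), zscore(tN.values)
        eM, eN = he_h2(M, K), he_h2(N, K)
        est = he_rg(M, N, K, eM, eN)
        if est.estimable and est.rho != 0:
            expect = abs(est.rg) * np.sqrt(est.rel_var_sum)
            assert est.se == pytest.approx(expect)


class TestCorrectionFactor:
    def test_printed_coefficients(self):
        c = DEFAULT_CORRECTION
        assert (c.slope_h2, c.slope_const, c.int_h2, c.int_const) == \
            (0.020225, 0.004225, -0.2352, 0.9467)

    def test_direct_evaluation(self):
        assert correction_factor(0.4, 900) == pytest.approx(1.22207, abs=1e-5)

    @given(h2=st.floats(0.0, 1.0), n1=st.integers(10, 5000), n2=st.integers(10, 5000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_increasing_in_n(self, h2, n1, n2):
        if n1 == n2:
            return
        lo, hi = sorted((n1, n2))
        assert correction_factor(h2, lo) < correction_factor(h2, hi)

    def test_h2_clipped_before_evaluation(self):
        assert correction_factor(1.7, 400) == correction_factor(1.0, 400)
        assert correction_factor(-0.3, 400) == correction_factor(0.0, 400)


def _est(h2, se):
    return HEEstimate(beta=2 * h2, h2=h2, se_raw=se, se_corrected=se,
                      p=0.5, n_animals=100, n_pairs=4950)


class TestDeltaNorm:
    def test_identical_estimates_give_zero(self):
        assert delta_norm(_est(0.4, 0.1), _est(0.4, 0.1)) == 0.0

    def test_direct_arithmetic(self):
        v = delta_norm(_est(0.5, 0.1), _est(0.3, 0.1))
        assert v == pytest.approx(0.2 / np.sqrt(0.02), abs=1e-5)
        assert v == pytest.approx(1.41421, abs=1e-4)

    @given(h1=st.floats(0, 1), h2=st.floats(0, 1),
           s=st.floats(0.01, 0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetric(self, h1, h2, s):
        a, b = _est(h1, s), _est(h2, s)
        assert delta_norm(a, b) == pytest.approx(-delta_norm(b, a))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            delta_norm(_est(0.4, 0.0), _est(0.3, 0.0))


class TestCalibration:
    def test_scaling_of_denominator(self):
        # multiplying all SEs by 10 shrinks Delta_norm (hence its SD) 10x
        a = [_est(0.5, 0.05), _est(0.30, 0.04)]
        b = [_est(0.5, 0.50), _est(0.30, 0.40)]
        assert delta_norm(*a) == pytest.approx(10 * delta_norm(*b))

    def test_sigma_near_one_with_corrected_ses(self):
        tab = calibration_experiment([0.4], [300], 80, seed=17)
        sigma = tab["sigma_delta_norm"].iloc[0]
        assert 0.7 < sigma < 1.3

    def test_warns_on_few_replicates(self):
        with pytest.warns(UserWarning, match="unstable"):
            calibration_experiment([0.4], [60], 25, seed=3, n_markers=100)


class TestDeriveCoefficients:
    @staticmethod
    def _table_from(coeffs, h2s, ns):
        rows = []
        for h2 in h2s:
            for n in ns:
                rows.append({"h2": h2, "n": n,
                             "sigma_delta_norm": correction_factor(h2, n, coeffs),
                             "n_replicates": 1000})
        return pd.DataFrame(rows)

    def test_noiseless_round_trip(self):
        tab = self._table_from(DEFAULT_CORRECTION, [0.1, 0.2, 0.4, 0.8, 0.99],
                               [220, 500, 1000, 2000, 5000])
        out = derive_correction_coefficients(tab)
        for field in ("slope_h2", "slope_const", "int_h2", "int_const"):
            assert getattr(out, field) == pytest.approx(
                getattr(DEFAULT_CORRECTION, field), abs=1e-8)

    def test_flat_sigma_gives_unit_intercept(self):
        tab = self._table_from(CorrectionCoefficients(0, 0, 0, 1.0),
                               [0.1, 0.4, 0.8], [200, 1000, 4000])
        out = derive_correction_coefficients(tab)
        assert out.slope_h2 == pytest.approx(0, abs=1e-10)
        assert out.slope_const == pytest.approx(0, abs=1e-10)
        assert out.int_h2 == pytest.approx(0, abs=1e-10)
        assert out.int_const == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_within_sampling_error(self):
        rng = np.random.default_rng(11)
        h2s, ns = [0.1, 0.2, 0.4, 0.8, 0.99], [220, 500, 1000, 2000, 5000]
        tab = self._table_from(DEFAULT_CORRECTION, h2s, ns)
        tab["sigma_delta_norm"] += rng.normal(0, 0.01, size=len(tab))
        out = derive_correction_coefficients(tab)
        # loose bound: 0.01 noise cannot move the sqrt(n) slope terms far
        assert out.slope_h2 == pytest.approx(DEFAULT_CORRECTION.slope_h2, abs=0.005)
        assert out.int_const == pytest.approx(DEFAULT_CORRECTION.int_const, abs=0.2)

    def test_degenerate_grid_rejected(self):
        tab = self._table_from(DEFAULT_CORRECTION, [0.4], [220, 500])
        with pytest.raises(ValueError):
            derive_correction_coefficients(tab)


class TestFilters:
    @pytest.mark.parametrize("h2,se,kept", [
        (0.05, 0.02, False),   # below the 10% floor
        (1.2, 0.1, False),     # exceeds 1 by more than SE
        (1.05, 0.10, True),    # 1.05 <= 1.10
        (0.5, 0.1, True),
        (0.10, 0.01, True),    # boundary inclusive
    ])
    def test_trait_filter(self, h2, se, kept):
        est = _est(h2, se)
        kept_list, excl = filter_traits([est])
        assert (est in kept_list) is kept
        if not kept:
            assert excl[0][1]

    @pytest.mark.parametrize("rg,se,valid", [
        (1.3, 0.1, False),
        (1.05, 0.1, True),
        (-1.05, 0.1, True),
        (-1.3, 0.1, False),
        (0.0, 0.0, True),
    ])
    def test_rg_filter(self, rg, se, valid):
        est = RgEstimate(rho=rg / 2, rg=rg, se=se, p=0.5, h2_M=0.4, h2_N=0.4,
                         n_M=100, n_N=100, rel_var_sum=0.1, valid=True)
        assert filter_rg(est) is valid
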