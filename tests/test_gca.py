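"""Pairwise Granger causality: AR fits, order selection, magnitudes, maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nirscausal import (
    DegenerateInputError,
    Recording,
    causal_map,
    fit_ar,
    generate_var_series,
    granger_pair,
    select_order_bic,
)


def brute_force_granger(a, b, p):
    """Independent oracle: explicit normal-equation solve with loops."""

    def ls_resid_var(y, preds):
        T = len(y)
        rows = []
        for t in range(p, T):
            row = [1.0]
            for series in preds:
                row.extend(series[t - l] for l in range(1, p + 1))
            rows.append(row)
        X = np.array(rows)
        yy = np.asarray(y[p:], dtype=float)
        beta = np.linalg.solve(X.T @ X, X.T @ yy)
        r = yy - X @ beta
        return float(r @ r) / len(yy)

    g_ab = np.log(ls_resid_var(b, [b]) / ls_resid_var(b, [b, a]))
    g_ba = np.log(ls_resid_var(a, [a]) / ls_resid_var(a, [a, b]))
    return max(0.0, g_ab), max(0.0, g_ba)


class TestFitAr:
    def test_white_noise_has_no_structure(self, rng):
        y = rng.standard_normal(10_000)
        f = fit_ar(y, 1)
        assert abs(f.own_coefs[0]) < 0.05
        assert f.resid_var == pytest.approx(np.var(y), rel=0.02)

    def test_recovers_ar1_coefficient(self):
        y = generate_var_series(np.array([[0.6]]), 100_000, 1.0, seed=2)[:, 0]
        f = fit_ar(y, 1)
        assert f.own_coefs[0] == pytest.approx(0.6, abs=0.01)

    def test_residuals_orthogonal_to_lagged_predictors(self, rng):
        y = rng.standard_normal(500)
        x = rng.standard_normal(500)
        f = fit_ar(y, 3, x=x)
        for l in range(1, 4):
            assert abs(f.resid @ y[3 - l:len(y) - l]) < 1e-7
            assert abs(f.resid @ x[3 - l:len(x) - l]) < 1e-7
        assert abs(f.resid.sum()) < 1e-7  # intercept column

    def test_nesting_inequality(self, rng):
        y = rng.standard_normal(800)
        x = rng.standard_normal(800)
        assert fit_ar(y, 2, x=x).resid_var <= fit_ar(y, 2).resid_var

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_ar(np.full(100, 2.0), 1)


class TestSelectOrderBic:
    def test_single_candidate(self, rng):
        a, b = rng.standard_normal((2, 200))
        assert select_order_bic(a, b, p_max=1) == 1

    def test_recovers_var2_order(self):
        hits = 0
        coeffs = np.zeros((2, 2, 2))
        coeffs[0] = [[0.4, 0.0], [0.3, 0.3]]
        coeffs[1] = [[-0.3, 0.0], [0.0, -0.35]]
        for s in range(20):
            x = generate_var_series(coeffs, 5000, 1.0, seed=s)
            hits += select_order_bic(x[:, 0], x[:, 1], p_max=5) == 2
        assert hits >= 18  # >= 90% of replicates

    def test_white_noise_prefers_order_one(self):
        hits = 0
        for s in range(20):
            w = np.random.default_rng(1000 + s).standard_normal((2000, 2))
            hits += select_order_bic(w[:, 0], w[:, 1], p_max=5) == 1
        assert hits > 10


class TestGrangerPair:
    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((2, 100_000))
        g_ab, g_ba = granger_pair(a, b, 1)
        assert g_ab < 1e-3 and g_ba < 1e-3

    def test_closed_form_lag_one_coupling(self):
        # b(t) = 0.8 a(t-1) + eps: reduced variance 1.64, full variance 1
        A = np.array([[0.0, 0.0], [0.8, 0.0]])
        x = generate_var_series(A, 100_000, 1.0, seed=1)
        g_ab, g_ba = granger_pair(x[:, 0], x[:, 1], 1)
        assert g_ab == pytest.approx(np.log(1.64), abs=0.01)
        assert g_ba < 0.005

    def test_scale_invariance(self, rng):
        a = rng.standard_normal(600)
        b = rng.standard_normal(600)
        g1 = granger_pair(a, b, 2)
        g2 = granger_pair(a, 1000.0 * b, 2)
        assert g1 == pytest.approx(g2, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), p=st.integers(1, 2))
    def test_matches_brute_force_oracle(self, seed, p):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(50)
        b = 0.3 * np.concatenate([[0], a[:-1]]) + rng.standard_normal(50)
        got = granger_pair(a, b, p)
        want = brute_force_granger(a, b, p)
        assert got == pytest.approx(want, abs=1e-10)

    def test_null_distribution_is_chi_square_over_t(self):
        """Under independence, T_eff * G is asymptotically chi2(p)."""
        T, p = 2000, 2
        stats = []
        for s in range(300):
            rng = np.random.default_rng(s)
            a, b = rng.standard_normal((2, T))
            g_ab, _ = granger_pair(a, b, p)
            stats.append((T - p) * g_ab)
        stats = np.array(stats)
        q_emp = np.quantile(stats, [0.5, 0.9, 0.95])
        q_chi = sps.chi2.ppf([0.5, 0.9, 0.95], df=p)
        assert np.allclose(q_emp, q_chi, rtol=0.25)
        assert sps.kstest(stats, sps.chi2(df=p).cdf).pvalue > 0.01


class TestCausalMap:
    @staticmethod
    def _null_recording(n_ch=6, T=2000, seed=0):
        rng = np.random.default_rng(seed)
        return Recording("p1", 7.0, "own", 10.0, rng.standard_normal((T, n_ch)),
                         preprocessed=True)

    def test_null_map_bias_matches_p_over_t(self):
        """Mean off-diagonal weight under the null is ~ p / T_eff
        (mean of chi2(p)/T at the selected order)."""
        rec = self._null_recording(n_ch=8, T=4000, seed=3)
        m = causal_map(rec, p_max=3)
        w = m.weights[np.isfinite(m.weights)]
        orders = m.orders[m.orders > 0]
        expected = np.mean(orders / (rec.n_samples - orders))
        se = np.std(w) / np.sqrt(len(w))
        assert abs(w.mean() - expected) < 3 * se + 0.1 * expected

    def test_planted_edge_is_map_maximum(self):
        rng = np.random.default_rng(4)
        A = np.eye(5) * 0.2
        A[2, 0] = 0.8  # channel 1 -> channel 3
        x = generate_var_series(A, 4000, 1.0, seed=rng)
        rec = Recording("p1", 7.0, "own", 10.0, x, preprocessed=True)
        m = causal_map(rec, p_max=3)
        i, j = np.unravel_index(np.nanargmax(m.weights), m.weights.shape)
        assert (i, j) == (0, 2)

    def test_permutation_equivariance(self):
        rec = self._null_recording(n_ch=5, T=1200, seed=9)
        perm = np.array([3, 0, 4, 1, 2])
        m1 = causal_map(rec, p_max=2)
        rec_p = Recording("p1", 7.0, "own", 10.0, rec.data[:, perm],
                          preprocessed=True)
        m2 = causal_map(rec_p, p_max=2)
        np.testing.assert_allclose(
            m2.weights, m1.weights[np.ix_(perm, perm)], atol=1e-10
        )

    def test_degenerate_channel_marked_missing(self):
        rec = self._null_recording(n_ch=4, T=900, seed=2)
        rec.data[:, 1] = 5.0  # constant channel
        with pytest.warns(UserWarning, match="degenerate"):
            m = causal_map(rec, p_max=2)
        assert np.isnan(m.weights[1, :]).all()
        assert np.isnan(m.weights[:, 1]).all()
        off = ~np.eye(4, dtype=bool)
        good = off & ~np.isnan(m.weights)
        assert good.sum() == 3 * 2  # remaining pairs all defined

    def test_nonnegative_and_consistent_with_granger_pair(self):
        rec = self._null_recording(n_ch=4, T=800, seed=5)
        m = causal_map(rec, p_max=3)
        assert np.all(m.weights[np.isfinite(m.weights)] >= 0)
        i, j = 0, 2
        p = int(m.orders[i, j])
        g_ij, g_ji = granger_pair(rec.data[:, i], rec.data[:, j], p)
        assert m.weights[i, j] == pytest.approx(g_ij, abs=1e-12)
        assert m.weights[j, i] == pytest.approx(g_ji, abs=1e-12)

    def test_edge_table_round_trip(self, tmp_path):
        from nirscausal import CausalMap

        rec = self._null_recording(n_ch=4, T=800, seed=6)
        m = causal_map(rec, p_max=2)
        tsv = m.save(tmp_path)
        m2 = CausalMap.load(tsv)
        np.testing.assert_allclose(m2.weights, m.weights, atol=1e-10)
        np.testing.assert_array_equal(m2.orders, m.orders)
        assert (m2.participant_id, m2.condition) == ("p1", "own")
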