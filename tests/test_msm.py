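import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from loopmsm import msm
from loopmsm.errors import EstimationError

# 3-state reversible chain with exact spectrum (1, 0.9, 0.75), uniform pi:
# T = (1/3)J + 0.9 v2 v2' + 0.75 v3 v3' with v2=(1,0,-1)/sqrt2, v3=(1,-2,1)/sqrt6
T3 = np.array([
    [109 / 120, 1 / 12, 1 / 120],
    [1 / 12, 5 / 6, 1 / 12],
    [1 / 120, 1 / 12, 109 / 120],
])


def sample_chain(t, n, rng, start=None):
    k = t.shape[0]
    cum = np.cumsum(t, axis=1)
    cum[:, -1] = 1.0
    s = np.empty(n, dtype=np.int64)
    s[0] = rng.integers(k) if start is None else start
    u = rng.random(n)
    for i in range(1, n):
        s[i] = np.searchsorted(cum[s[i - 1]], u[i], side="right")
    return s


def loglik(t, c):
    mask = c > 0
    return float(np.sum(c[mask] * np.log(t[mask])))


class TestCountTransitions:
    def test_single_pair(self):
        cm = msm.count_transitions([np.array([1, 2])], lag=1)
        want = np.zeros((3, 3))
        want[1, 2] = 1
        np.testing.assert_array_equal(cm.counts, want)

    def test_constant_sequence(self):
        cm = msm.count_transitions([np.full(50, 3)], lag=7)
        assert cm.counts[3, 3] == 50 - 7
        assert cm.total == 43

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        seq = rng.integers(0, 5, size=500)
        lag = 3
        cm = msm.count_transitions([seq], lag=lag)
        want = np.zeros((5, 5))
        for t in range(len(seq) - lag):
            want[seq[t], seq[t + lag]] += 1
        np.testing.assert_array_equal(cm.counts, want)

    def test_never_counts_across_boundaries(self):
        a, b = np.array([0, 0, 0]), np.array([1, 1, 1])
        cm = msm.count_transitions([a, b], lag=1)
        assert cm.counts[0, 1] == 0 and cm.counts[1, 0] == 0
        assert cm.counts[0, 0] == 2 and cm.counts[1, 1] == 2

    def test_negative_labels_break_windows(self):
        seq = np.array([0, -1, 1, 1])
        cm = msm.count_transitions([seq], lag=1)
        assert cm.counts.sum() == 1
        assert cm.counts[1, 1] == 1

    def test_all_too_short_raises(self):
        with pytest.raises(EstimationError):
            msm.count_transitions([np.array([0, 1])], lag=5)


class TestLargestConnectedSet:
    def _cm(self, c):
        c = np.asarray(c, dtype=float)
        return msm.CountMatrix(counts=c, lag_frames=1, lag_ns=1.0,
                               n_states=c.shape[0])

    def test_fully_connected_identity(self):
        c = np.ones((4, 4))
        active, trimmed = msm.largest_connected_set(self._cm(c))
        np.testing.assert_array_equal(active, np.arange(4))
        np.testing.assert_array_equal(trimmed.counts, c)

    def test_two_blocks_keeps_larger(self):
        c = np.zeros((5, 5))
        c[np.ix_([0, 1, 2], [0, 1, 2])] = 1
        c[np.ix_([3, 4], [3, 4])] = 5
        active, trimmed = msm.largest_connected_set(self._cm(c))
        np.testing.assert_array_equal(active, [0, 1, 2])
        assert trimmed.n_states == 3

    def test_matches_scipy_csgraph_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = (rng.random((8, 8)) < 0.15).astype(float)
            try:
                active, _ = msm.largest_connected_set(self._cm(c))
            except EstimationError:
                assert c.sum() == 0
                continue
            n, lab = connected_components(csr_matrix(c), connection="strong")
            used = np.flatnonzero(c.sum(axis=0) + c.sum(axis=1) > 0)
            sizes = {l: np.intersect1d(np.flatnonzero(lab == l), used).size
                     for l in set(lab[used])}
            assert len(active) == max(sizes.values())


class TestMLE:
    def test_symmetric_counts_both_estimators_agree(self):
        c = self_cm = msm.CountMatrix(counts=np.array([[9.0, 1], [1, 9]]),
                                      lag_frames=1, lag_ns=1.0, n_states=2)
        want = np.array([[0.9, 0.1], [0.1, 0.9]])
        for rev in (True, False):
            model = msm.mle_transition_matrix(self_cm, reversible=rev)
            np.testing.assert_allclose(model.transition_matrix, want, atol=1e-10)

    def test_nonreversible_is_row_normalized(self):
        cm = msm.CountMatrix(counts=np.array([[5.0, 3], [2, 6]]),
                             lag_frames=1, lag_ns=1.0, n_states=2)
        model = msm.mle_transition_matrix(cm, reversible=False)
        want = np.array([[0.625, 0.375], [0.25, 0.75]])
        np.testing.assert_allclose(model.transition_matrix, want, atol=1e-15)

    def test_reversible_matches_brute_force_grid(self):
        c = np.array([[5.0, 3], [2, 6]])
        cm = msm.CountMatrix(counts=c, lag_frames=1, lag_ns=1.0, n_states=2)
        model = msm.mle_transition_matrix(cm, reversible=True)
        # every 2-state chain satisfies detailed balance, so scan the full
        # (a, b) simplex of row-stochastic matrices for the likelihood max
        a = np.linspace(1e-4, 1 - 1e-4, 4001)
        b = np.linspace(1e-4, 1 - 1e-4, 4001)
        aa, bb = np.meshgrid(a, b, indexing="ij")
        ll = (c[0, 0] * np.log(1 - aa) + c[0, 1] * np.log(aa)
              + c[1, 0] * np.log(bb) + c[1, 1] * np.log(1 - bb))
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        t = model.transition_matrix
        assert t[0, 1] == pytest.approx(a[i], abs=1e-3)
        assert t[1, 0] == pytest.approx(b[j], abs=1e-3)
        # and the fixed point must hit the analytic optimum tightly
        np.testing.assert_allclose(t, np.array([[0.625, 0.375], [0.25, 0.75]]),
                                   atol=1e-6)

    def test_detailed_balance_residual(self):
        rng = np.random.default_rng(2)
        c = rng.integers(1, 50, size=(6, 6)).astype(float)
        cm = msm.CountMatrix(counts=c, lag_frames=1, lag_ns=1.0, n_states=6)
        model = msm.mle_transition_matrix(cm, reversible=True)
        pi, t = model.stationary, model.transition_matrix
        flux = pi[:, None] * t
        assert np.max(np.abs(flux - flux.T)) <= 1e-8

    def test_reversible_likelihood_bounded_by_unconstrained(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            c = rng.integers(1, 30, size=(4, 4)).astype(float)
            cm = msm.CountMatrix(counts=c, lag_frames=1, lag_ns=1.0, n_states=4)
            rev = msm.mle_transition_matrix(cm, reversible=True)
            nonrev = msm.mle_transition_matrix(cm, reversible=False)
            assert loglik(rev.transition_matrix, c) <= \
                loglik(nonrev.transition_matrix, c) + 1e-9

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        c = rng.integers(1, 20, size=(5, 5)).astype(float)
        cm = msm.CountMatrix(counts=c, lag_frames=1, lag_ns=1.0, n_states=5)
        for rev in (True, False):
            t = msm.mle_transition_matrix(cm, reversible=rev).transition_matrix
            np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)

    def test_estimator_converges_to_generator(self):
        rng = np.random.default_rng(5)
        seq = sample_chain(T3, 100_000, rng)
        model = msm.estimate_msm([seq], lag=1)
        c = model.counts.counts
        n_row = c.sum(axis=1)
        se = np.sqrt(T3 * (1 - T3) / n_row[:, None])
        assert np.all(np.abs(model.transition_matrix - T3) <= 3 * se + 1e-12)


class TestStationary:
    def test_doubly_stochastic_uniform(self):
        t = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        model = msm.model_from_transition_matrix(t, reversible=False)
        np.testing.assert_allclose(msm.stationary_distribution(model), 1 / 3,
                                   atol=1e-12)

    def test_two_state_hand_solution(self):
        t = np.array([[0.9, 0.1], [0.2, 0.8]])
        model = msm.model_from_transition_matrix(t)
        np.testing.assert_allclose(model.stationary, [2 / 3, 1 / 3], atol=1e-10)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(6)
        c = rng.integers(1, 40, size=(5, 5)).astype(float)
        t = c / c.sum(axis=1)[:, None]
        model = msm.model_from_transition_matrix(t, reversible=False)
        p = t.copy()
        for _ in range(20):           # T^(2^20)
            p = p @ p
            p /= p.sum(axis=1)[:, None]
        np.testing.assert_allclose(model.stationary, p[0], atol=1e-10)

    def test_pi_is_left_eigenvector(self):
        t = T3
        model = msm.model_from_transition_matrix(t)
        np.testing.assert_allclose(model.stationary @ t, model.stationary,
                                   atol=1e-10)
        assert model.stationary.sum() == pytest.approx(1.0, abs=1e-12)


class TestImpliedTimescales:
    def test_direct_formula(self):
        t = np.array([[0.75, 0.25], [0.25, 0.75]])  # lambda2 = 0.5
        model = msm.model_from_transition_matrix(t, lag_frames=2)
        its = model.implied_timescales_frames(1)
        assert its[0] == pytest.approx(-2 / np.log(0.5), abs=1e-12)

    def test_stationary_eigenvalue_excluded(self):
        model = msm.model_from_transition_matrix(T3)
        its = model.implied_timescales_frames()
        assert len(its) == 2
        assert np.all(its < 20)   # 9.49 and 3.48, never the infinite one

    def test_exact_chain_flat_timescales(self):
        rng = np.random.default_rng(7)
        seqs = [sample_chain(T3, 20_000, rng) for _ in range(5)]
        table = msm.implied_timescales(seqs, lags=range(1, 9), n_timescales=2)
        want = -1 / np.log(0.9)
        slow = table.timescales_frames[:, 0]
        assert np.all(np.abs(slow - want) / want < 0.15)

    def test_nonpositive_eigenvalues_flagged_nan(self):
        # period-2 flipper: eigenvalues (1, -1)
        seq = np.tile([0, 1], 300)
        table = msm.implied_timescales([seq], lags=[1, 2, 3], n_timescales=1)
        assert np.isnan(table.timescales_frames[0, 0])

    def test_units_via_frame_interval(self):
        rng = np.random.default_rng(8)
        seqs = [sample_chain(T3, 5_000, rng)]
        table = msm.implied_timescales(seqs, lags=[1, 2], n_timescales=1,
                                       frame_interval=0.25)
        np.testing.assert_allclose(table.lags_ns, [0.25, 0.5])
        np.testing.assert_allclose(table.timescales_ns,
                                   table.timescales_frames * 0.25)

    def test_dataframe_export_shape(self):
        rng = np.random.default_rng(9)
        seqs = [sample_chain(T3, 3_000, rng)]
        table = msm.implied_timescales(seqs, lags=[1, 2, 4], n_timescales=2)
        df = table.to_dataframe()
        assert len(df) == 6
        assert set(df.columns) == {"lag_frames", "lag_ns", "timescale_index",
                                   "timescale_ns", "defined"}


class TestSelectLag:
    def _table(self, values):
        values = np.asarray(values, dtype=float)
        return msm.ITSTable(lags_frames=np.arange(1, len(values) + 1),
                            timescales_frames=values, frame_interval=1.0,
                            n_timescales=values.shape[1])

    def test_flat_returns_first_lag(self):
        t = np.tile([[100.0, 50.0, 25.0]], (5, 1))
        sel = msm.select_lag(self._table(t))
        assert sel.converged and sel.lag_frames == 1

    def test_exact_chain_selects_small_lag(self):
        rng = np.random.default_rng(10)
        seqs = [sample_chain(T3, 20_000, rng) for _ in range(5)]
        table = msm.implied_timescales(seqs, lags=range(1, 9), n_timescales=2)
        sel = msm.select_lag(table)
        assert sel.converged and sel.lag_frames <= 2

    def test_rising_timescales_not_converged(self):
        t = np.array([[10.0 * 1.2**i, 5.0 * 1.2**i, 2.0 * 1.2**i]
                      for i in range(6)])
        sel = msm.select_lag(self._table(t))
        assert not sel.converged
        assert sel.lag_frames is None
        assert "not converged" in sel.status

    def test_needs_three_lags(self):
        t = np.array([[10.0], [10.0]])
        with pytest.raises(ValueError):
            msm.select_lag(self._table(t))

    def test_late_convergence(self):
        t = np.array([[10.0, 5], [20, 9], [40, 12], [41, 12.5], [41.5, 12.6]])
        sel = msm.select_lag(self._table(t))
        assert sel.converged and sel.lag_frames == 3
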