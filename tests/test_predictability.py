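import numpy as np
import pytest

from spikescale.predictability import (
    EmbeddingConfig,
    RCurve,
    embed_past,
    history_dependence,
    predictability_curve,
    summarize_R,
)
from spikescale.timescales import BinnedTrain

from conftest import markov_binary


def binary_entropy(p):
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def naive_embed(a, d, kappa, T_bins):
    """Brute-force reference: recompute edges and occupancies per t."""
    w = 10.0 ** (kappa * np.arange(d))
    edges = np.round(np.concatenate([[0.0], np.cumsum(w / w.sum() * T_bins)])).astype(int)
    for i in range(1, d + 1):
        edges[i] = max(edges[i], edges[i - 1] + 1)
    edges[d] = T_bins
    for i in range(d - 1, 0, -1):
        edges[i] = min(edges[i], edges[i + 1] - 1)
    codes = []
    for t in range(T_bins, len(a)):
        code = 0
        for i in range(d):
            if np.any(a[t - edges[i + 1] : t - edges[i]]):
                code |= 1 << i
        codes.append(code)
    return np.array(codes)


class TestEmbedPast:
    def test_d1_is_previous_bin(self):
        a = np.array([1, 0, 0, 1, 1, 0], dtype=np.int8)
        b = BinnedTrain(a, 5.0, 30.0)
        codes = embed_past(b, EmbeddingConfig(d=1, kappa=0.0, T=5.0))
        np.testing.assert_array_equal(codes, a[:-1])

    def test_d2_alternating(self):
        a = np.tile([1, 0], 10).astype(np.int8)
        b = BinnedTrain(a, 5.0, 100.0)
        codes = embed_past(b, EmbeddingConfig(d=2, kappa=0.0, T=10.0))
        # past (a_{t-2}, a_{t-1}) alternates between (1,0) and (0,1);
        # nearest bin is the low bit
        assert set(codes) == {0b01, 0b10}
        assert codes[0] != codes[1]

    def test_matches_naive_loop(self, rng):
        a = (rng.random(500) < 0.3).astype(np.int8)
        b = BinnedTrain(a, 5.0, 2500.0)
        for kappa in (0.0, 0.5):
            got = embed_past(b, EmbeddingConfig(d=3, kappa=kappa, T=60.0))
            expect = naive_embed(a, 3, kappa, 12)
            np.testing.assert_array_equal(got, expect)

    def test_too_short_past_range(self):
        b = BinnedTrain(np.zeros(100, dtype=np.int8), 5.0, 500.0)
        with pytest.raises(ValueError):
            embed_past(b, EmbeddingConfig(d=5, kappa=0.0, T=10.0))

    def test_edges_partition_and_grow(self):
        cfg = EmbeddingConfig(d=5, kappa=0.4, T=500.0)
        e = cfg.bin_edges(5.0)
        widths = np.diff(e)
        assert e[0] == 0 and e[-1] == 100
        assert np.all(widths >= 1)
        assert widths[-1] > widths[0]  # stretching


class TestHistoryDependence:
    def test_iid_near_zero(self, rng):
        a = (rng.random(240_000) < 0.02).astype(np.int8)
        b = BinnedTrain(a, 5.0, len(a) * 5.0)
        R, _ = history_dependence(b, T=50.0, seed=1)
        assert R <= 0.01

    def test_deterministic_alternation_fully_predictable(self):
        a = np.tile([1, 0], 5000).astype(np.int8)
        b = BinnedTrain(a, 5.0, len(a) * 5.0)
        R, _ = history_dependence(b, T=5.0, d=1, seed=1)
        assert R == pytest.approx(1.0, abs=1e-3)

    def test_markov_chain_analytic(self, markov_train):
        """One-step Markov chain: R = 1 - H_b(0.8) at T = dt, d = 1."""
        expect = 1.0 - binary_entropy(0.8)
        R, _ = history_dependence(markov_train, T=5.0, d=1, seed=2)
        assert R == pytest.approx(expect, abs=0.02)

    def test_all_zero_train_error(self):
        b = BinnedTrain(np.zeros(1000, dtype=np.int8), 5.0, 5000.0)
        with pytest.raises(ValueError):
            history_dependence(b, T=50.0)

    def test_bias_correction_centers_iid_at_zero(self):
        """Mean corrected R over 100 i.i.d. trains stays below 0.005."""
        Rs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = (r.random(20_000) < 0.05).astype(np.int8)
            b = BinnedTrain(a, 5.0, len(a) * 5.0)
            R, _ = history_dependence(b, T=50.0, d=3, kappa_grid=(0.0,), seed=seed)
            Rs.append(R)
        assert np.mean(Rs) <= 0.005


class TestPredictabilityCurve:
    def test_markov_flat_beyond_first_point(self, markov_train):
        """One-step memory: no extra information at longer past ranges."""
        grid = np.array([30.0, 60.0, 120.0, 300.0, 1000.0])
        curve = predictability_curve(markov_train, grid, d=5, seed=3)
        assert np.all(np.abs(curve.R - curve.R[0]) < 0.02)

    def test_monotone_up_to_estimator_noise(self, markov_train):
        """Isotonic fit explains the curve to < 5% RMS (R rises then flattens)."""
        from sklearn.isotonic import IsotonicRegression

        curve = predictability_curve(markov_train, seed=4)
        iso = IsotonicRegression().fit_transform(np.arange(len(curve.R)), curve.R)
        rms = np.sqrt(np.mean((iso - curve.R) ** 2))
        assert rms < 0.05 * max(curve.R.max(), 1e-9)

    def test_nested_embedding_d5_not_worse_than_d1(self, rng):
        a = markov_binary(120_000, 0.75, 0.25, rng)
        b = BinnedTrain(a, 5.0, len(a) * 5.0)
        grid = np.geomspace(30, 1000, 8)
        r1 = summarize_R(predictability_curve(b, grid, d=1, seed=5)).R_tot
        r5 = summarize_R(predictability_curve(b, grid, d=5, seed=5)).R_tot
        assert r5 >= r1 - 0.01

    def test_all_zero_error(self):
        b = BinnedTrain(np.zeros(50_000, dtype=np.int8), 5.0, 250_000.0)
        with pytest.raises(ValueError):
            predictability_curve(b)


def make_curve(T, R):
    T = np.asarray(T, dtype=float)
    R = np.asarray(R, dtype=float)
    return RCurve(T, R, np.zeros_like(R), np.zeros_like(R),
                  np.full(len(R), 1000), 5)


class TestSummarizeR:
    def test_flat_curve(self):
        s = summarize_R(make_curve([30, 60, 120, 240, 480], [0.3] * 5))
        assert s.R_tot == pytest.approx(0.3)
        assert s.tau_R == 0.0

    def test_single_step(self):
        T = [30, 60, 120, 240, 480, 960]
        R = [0.1, 0.1, 0.1, 0.4, 0.4, 0.4]
        s = summarize_R(make_curve(T, R))
        assert s.tau_R == pytest.approx(240 - 30)

    def test_exponential_rise_recovers_tau(self):
        """Dense samples of R(T) = R_inf (1 - exp(-(T-T0)/tau)) give tau_R ~ tau."""
        tau = 150.0
        T = np.linspace(30, 5000, 2000)
        R = 0.3 * (1 - np.exp(-(T - T[0]) / tau))
        s = summarize_R(make_curve(T, R))
        assert s.tau_R == pytest.approx(tau, rel=0.05)

    def test_plateau_mean_and_invariant(self):
        T = [30, 60, 120, 240, 480]
        R = [0.1, 0.2, 0.39, 0.40, 0.38]
        s = summarize_R(make_curve(T, R))
        assert s.R_tot == pytest.approx(np.mean([0.39, 0.40, 0.38]))
        assert s.R_tot >= max(R) - 0.05 * max(R) - 1e-12

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            summarize_R(make_curve([30, 60, 120, 240], [0.1] * 4))
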