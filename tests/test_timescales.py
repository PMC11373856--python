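import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikescale.io import SpikeTrain
from spikescale.timescales import (
    AutocorrCurve,
    BinnedTrain,
    autocorrelation,
    bin_spikes,
    fit_correlation_timescale,
)


def brute_force_autocorr(a, k):
    """Literal per-lag computation: all averages over t = k..n-1."""
    a = np.asarray(a, dtype=float)
    n = len(a)
    ts = np.arange(k, n)
    cross = np.mean([a[t] * a[t - k] for t in ts])
    mean = np.mean([a[t] for t in ts])
    second = np.mean([a[t] ** 2 for t in ts])
    var = second - mean**2
    return (cross - mean**2) / var if var > 0 else np.nan


class TestBinSpikes:
    def test_basic(self):
        tr = SpikeTrain("u", [0.002, 0.003, 0.011], 0.0, 0.015)
        b = bin_spikes(tr, 5.0)
        np.testing.assert_array_equal(b.a, [1, 0, 1])

    def test_empty(self):
        b = bin_spikes(SpikeTrain("u", [], 0.0, 0.050), 5.0)
        assert b.n_bins == 10 and b.n_spikes == 0

    def test_binarized(self):
        b = bin_spikes(SpikeTrain("u", [0.001, 0.002], 0.0, 0.005), 5.0)
        np.testing.assert_array_equal(b.a, [1])

    def test_truncates_partial_bin(self):
        b = bin_spikes(SpikeTrain("u", [0.001], 0.0, 0.012), 5.0)
        assert b.n_bins == 2

    def test_bad_dt(self):
        with pytest.raises(ValueError):
            bin_spikes(SpikeTrain("u", [], 0.0, 1.0), 0.0)


class TestAutocorrelation:
    def test_alternating_perfect_anticorrelation(self):
        a = np.append(np.tile([1, 0], 100), 1)  # balanced lag-1 window
        b = BinnedTrain(a, 5.0, 1005.0)
        c = autocorrelation(b, 10.0)
        assert c.C[0] == pytest.approx(-1.0)

    def test_constant_series_error(self):
        b = BinnedTrain(np.ones(100, dtype=np.int8), 5.0, 500.0)
        with pytest.raises(ValueError):
            autocorrelation(b, 50.0)

    def test_matches_brute_force(self, rng):
        """Vectorized C(T) equals the double-loop formula to 1e-12."""
        for _ in range(50):
            a = (rng.random(200) < rng.uniform(0.1, 0.6)).astype(np.int8)
            if a.min() == a.max():
                continue
            b = BinnedTrain(a, 5.0, 1000.0)
            c = autocorrelation(b, 995.0)
            for i, k in enumerate(range(1, 200)):
                expect = brute_force_autocorr(a, k)
                if np.isnan(expect):
                    assert np.isnan(c.C[i])
                else:
                    assert c.C[i] == pytest.approx(expect, abs=1e-12)

    def test_iid_first_lag_small(self):
        """|C(dt)| of an i.i.d. Bernoulli train stays below 5/sqrt(n)."""
        n = 20_000
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = (r.random(n) < 0.05).astype(np.int8)
            b = BinnedTrain(a, 5.0, n * 5.0)
            c = autocorrelation(b, 5.0)
            hits += abs(c.C[0]) <= 5 / np.sqrt(n)
        assert hits >= 95


def synth_curve(T, params, mode="two"):
    if mode == "two":
        A1, t1, A2, t2 = params
        return A1 * np.exp(-T / t1) + A2 * np.exp(-T / t2)
    A, tau, O = params
    return A * np.exp(-T / tau) + O


def make_curve(C, T, dt=5.0):
    return AutocorrCurve(T, C, np.full(len(T), 10_000), dt)


class TestFit:
    T = np.arange(1, 2001) * 5.0

    def test_two_timescale_recovery(self):
        y = synth_curve(self.T, (0.6, 50.0, 0.2, 2000.0))
        fit = fit_correlation_timescale(make_curve(y, self.T), 30.0, 10_000.0)
        assert fit.converged
        assert fit.tau_C == pytest.approx(50.0, rel=0.01)
        assert fit.tau_sec == pytest.approx(2000.0, rel=0.01)

    def test_single_exponential_both_modes(self):
        y = synth_curve(self.T, (1.0, 100.0, 0.0), mode="single")
        for mode in ("two_timescale", "single_offset"):
            fit = fit_correlation_timescale(make_curve(y, self.T), 30.0, 10_000.0, mode)
            assert fit.tau_C == pytest.approx(100.0, rel=0.01), mode

    def test_dominant_coefficient_selection_symmetry(self):
        """Swapping the two components leaves tau_C unchanged."""
        y1 = synth_curve(self.T, (0.6, 50.0, 0.2, 2000.0))
        y2 = synth_curve(self.T, (0.2, 2000.0, 0.6, 50.0))
        np.testing.assert_allclose(y1, y2)
        f1 = fit_correlation_timescale(make_curve(y1, self.T), 30.0, 10_000.0)
        f2 = fit_correlation_timescale(make_curve(y2, self.T), 30.0, 10_000.0)
        assert f1.tau_C == pytest.approx(f2.tau_C, rel=1e-6)

    def test_tie_break_smaller_tau(self):
        y = synth_curve(self.T, (0.4, 60.0, 0.4, 3000.0))
        fit = fit_correlation_timescale(make_curve(y, self.T), 30.0, 10_000.0)
        # equal coefficients: dominant timescale is the faster decay
        assert fit.tau_C < fit.tau_sec

    def test_too_few_lags(self):
        T = np.arange(1, 6) * 5.0
        with pytest.raises(ValueError):
            fit_correlation_timescale(make_curve(np.exp(-T / 30), T), 5.0, 30.0)

    def test_short_lags_excluded(self):
        """Distorted lags below T_min must not influence the fit."""
        y = synth_curve(self.T, (0.5, 80.0, 0.05), mode="single")
        y_distorted = y.copy()
        y_distorted[self.T < 30.0] = -0.4  # refractory-like dip
        f = fit_correlation_timescale(make_curve(y_distorted, self.T), 30.0, 10_000.0,
                                      "single_offset")
        assert f.tau_C == pytest.approx(80.0, rel=0.01)

    def test_fit_range_robustness_two_timescale_vs_single_offset(self, rng):
        """On data with an added slow decay, the single-offset tau grows
        with T_max while the two-timescale tau_C stays put."""
        T = np.arange(1, 3001) * 5.0
        y = 0.5 * np.exp(-T / 60.0) + 0.15 * np.exp(-T / 4000.0)
        y = y + rng.normal(0, 0.002, len(T))
        curve = make_curve(y, T)
        single = [
            fit_correlation_timescale(curve, 30.0, tmax, "single_offset").tau_C
            for tmax in (5_000.0, 10_000.0, 15_000.0)
        ]
        assert single[0] < single[1] < single[2]
        double = [
            fit_correlation_timescale(curve, 30.0, tmax, "two_timescale").tau_C
            for tmax in (5_000.0, 10_000.0, 15_000.0)
        ]
        ref = double[1]
        assert all(abs(d - ref) <= 0.1 * ref for d in double)

    @settings(max_examples=20, deadline=None)
    @given(tau=st.floats(20.0, 500.0), A=st.floats(0.1, 0.9))
    def test_single_offset_property(self, tau, A):
        T = np.arange(1, 500) * 5.0
        y = A * np.exp(-T / tau) + 0.05
        fit = fit_correlation_timescale(make_curve(y, T), 5.0, T[-1], "single_offset")
        assert fit.tau_C == pytest.approx(tau, rel=0.02)
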