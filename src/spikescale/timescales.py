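"""Autocorrelation of binned spike trains and correlation-timescale fits.

The correlation timescale tau_C of a unit is the decay constant of the
dominant exponential component of its spike-train autocorrelation

    C(T) = ( <a_t a_{t-T}>_t - <a_t>_t^2 ) / ( <a_t^2>_t - <a_t>_t^2 ),

with all three averages over the same index set t = T, T+dt, ..., T_rec-dt.
Spiking is binarized in bins of dt = 5 ms by default.  Two fit families are
supported: a sum of two exponentials A1 e^{-T/tau1} + A2 e^{-T/tau2}, where
tau_C is the tau with the larger coefficient and the other tau becomes the
secondary timescale tau_sec (absorbing slow, possibly stimulus-driven decay);
and a single exponential with offset A e^{-T/tau} + O, appropriate when no
separate slow component exists (e.g. branching-network data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .io import SpikeTrain

FitMode = Literal["two_timescale", "single_offset"]

#: optimizer bounds (see fit_correlation_timescale)
TAU_MAX_MS = 100_000.0
A_MAX = 2.0
OFFSET_BOUNDS = (-0.1, 1.0)
N_STARTS = 10


@dataclass(frozen=True)
class BinnedTrain:
    """Binary activation sequence a_t at bin width dt (ms)."""

    a: np.ndarray
    dt: float
    T_rec: float

    def __post_init__(self):
        a = np.ascontiguousarray(self.a, dtype=np.int8)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("a must be binary")
        if len(a) != int(np.floor(self.T_rec / self.dt + 1e-9)):
            raise ValueError("length of a must equal floor(T_rec/dt)")
        object.__setattr__(self, "a", a)

    @property
    def n_bins(self) -> int:
        return len(self.a)

    @property
    def n_spikes(self) -> int:
        return int(self.a.sum())


@dataclass(frozen=True)
class AutocorrCurve:
    """Autocorrelation C(T) at lags T (ms, multiples of dt).

    C is NaN at lags where the evaluation window has zero variance.
    """

    T: np.ndarray
    C: np.ndarray
    n_terms: np.ndarray
    dt: float


@dataclass(frozen=True)
class AutocorrFit:
    mode: FitMode
    params: tuple
    tau_C: float
    tau_sec: float | None
    T_min: float
    T_max: float
    goodness: float
    converged: bool
    at_bound: bool = False
    #: dominant amplitude in units of its least-squares noise floor;
    #: low_signal marks fits indistinguishable from a flat autocorrelation
    amp_significance: float = np.inf
    low_signal: bool = False


def bin_spikes(train: SpikeTrain, dt: float = 5.0) -> BinnedTrain:
    """Binarize a spike train into bins of width dt (ms).

    a_t = 1 iff at least one spike falls in [t, t+dt); the recording span is
    truncated to whole bins.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dt_s = dt / 1000.0
    n = int(np.floor((train.duration + 1e-12) / dt_s))
    if n < 1:
        raise ValueError("recording span shorter than one bin")
    idx = np.floor((train.spike_times - train.t_start) / dt_s).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n)]
    a = np.zeros(n, dtype=np.int8)
    a[idx] = 1
    return BinnedTrain(a, dt, n * dt)


def autocorrelation(b: BinnedTrain, T_max: float) -> AutocorrCurve:
    """Autocorrelation of a binned train for lags dt..T_max.

    For each lag T the cross-product, mean and second moment are averaged
    over the common index set t in {T, ..., T_rec - dt}; the lag-dependent
    mean guards against slow drift.  Lags whose window has zero variance are
    reported as NaN; a fully constant series is an error.
    """
    a = b.a.astype(np.float64)
    n = len(a)
    if np.all(a == a[0]):
        raise ValueError("constant series has no autocorrelation")
    k_max = int(np.floor(T_max / b.dt + 1e-9))
    k_max = min(k_max, n - 1)
    if k_max < 1:
        raise ValueError("T_max must allow at least one lag")
    lags = np.arange(1, k_max + 1)
    C = np.full(k_max, np.nan)
    n_terms = (n - lags).astype(np.int64)
    # suffix cumulative sums let the lag-dependent window means come cheap
    csum = np.cumsum(a)
    csum2 = csum  # a is binary: a^2 == a
    for i, k in enumerate(lags):
        m = n - k
        mean = (csum[-1] - (csum[k - 1] if k >= 1 else 0.0)) / m  # mean a[k:]
        var = (csum2[-1] - csum2[k - 1]) / m - mean * mean
        if var <= 0:
            continue
        cross = float(a[k:] @ a[:-k]) / m
        C[i] = (cross - mean * mean) / var
    return AutocorrCurve(lags * b.dt, C, n_terms, b.dt)


def _two_exp(params, T):
    A1, tau1, A2, tau2 = params
    return A1 * np.exp(-T / tau1) + A2 * np.exp(-T / tau2)


def _single_offset(params, T):
    A, tau, O = params
    return A * np.exp(-T / tau) + O


def fit_correlation_timescale(
    c: AutocorrCurve,
    T_min: float = 30.0,
    T_max: float = 10_000.0,
    mode: FitMode = "two_timescale",
) -> AutocorrFit:
    """Fit C(T) on lags within [T_min, T_max] and select tau_C.

    Short lags (T < T_min) are excluded to suppress refractoriness/burst
    effects.  Bounded least squares with 10 multi-starts from log-spaced tau
    values; the best residual wins.  In two-timescale mode tau_C is the tau
    whose coefficient A is larger (ties break toward the smaller tau) and
    tau_sec the other one.  Fits that never converge raise no error but
    return converged=False; parameters that land at a bound set at_bound.
    """
    sel = (c.T >= T_min - 1e-9) & (c.T <= T_max + 1e-9) & np.isfinite(c.C)
    T = c.T[sel]
    y = c.C[sel]
    if len(T) < 8:
        raise ValueError(f"need >= 8 defined lags in [{T_min}, {T_max}], got {len(T)}")

    tau_lo = c.dt
    taus = np.geomspace(max(T_min, tau_lo), min(T_max, TAU_MAX_MS), N_STARTS)
    best = None
    if mode == "two_timescale":
        lb = [0.0, tau_lo, 0.0, tau_lo]
        ub = [A_MAX, TAU_MAX_MS, A_MAX, TAU_MAX_MS]
        a0 = float(np.clip(y[0], 0.01, A_MAX / 2))
        starts = [
            [a0, taus[i], a0 / 3, min(taus[i] * 20, TAU_MAX_MS)]
            for i in range(N_STARTS)
        ]
        fun = _two_exp
    elif mode == "single_offset":
        lb = [0.0, tau_lo, OFFSET_BOUNDS[0]]
        ub = [A_MAX, TAU_MAX_MS, OFFSET_BOUNDS[1]]
        a0 = float(np.clip(y[0], 0.01, A_MAX / 2))
        starts = [[a0, taus[i], 0.0] for i in range(N_STARTS)]
        fun = _single_offset
    else:
        raise ValueError(f"unknown fit mode {mode!r}")

    for x0 in starts:
        try:
            res = least_squares(
                lambda p: fun(p, T) - y, x0, bounds=(lb, ub), method="trf"
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return AutocorrFit(mode, (), np.nan, None, T_min, T_max, np.inf, False)

    p = tuple(float(v) for v in best.x)
    resid = float(np.sqrt(2 * best.cost))
    at_bound = bool(
        np.any(np.isclose(best.x, lb, rtol=1e-6, atol=1e-12))
        or np.any(np.isclose(best.x, ub, rtol=1e-6))
    )
    if mode == "two_timescale":
        A1, tau1, A2, tau2 = p
        if A1 > A2 or (A1 == A2 and tau1 <= tau2):
            A_dom, tau_C, tau_sec = A1, tau1, tau2
        else:
            A_dom, tau_C, tau_sec = A2, tau2, tau1
    else:
        A_dom, tau_C, tau_sec = p[0], p[1], None
    # detectability: LS amplitude noise floor for an exponential regressor
    # sampled every dt is sigma_C * sqrt(2 dt / tau); sigma_C ~ 1/sqrt(n)
    n_eff = float(np.mean(c.n_terms[sel])) if np.any(c.n_terms[sel] > 0) else np.inf
    sigma_A = np.sqrt(2.0 * c.dt / max(tau_C, c.dt)) / np.sqrt(n_eff)
    signif = A_dom / sigma_A if sigma_A > 0 else np.inf
    low_signal = bool(signif < 3.0)
    return AutocorrFit(mode, p, tau_C, tau_sec, T_min, T_max, resid, True,
                       at_bound, float(signif), low_signal)


def measure_tau_C(
    train: SpikeTrain,
    dt: float = 5.0,
    T_min: float = 30.0,
    T_max: float = 10_000.0,
    mode: FitMode = "two_timescale",
) -> AutocorrFit:
    """Convenience: bin, autocorrelate and fit in one call."""
    b = bin_spikes(train, dt)
    curve = autocorrelation(b, T_max)
    return fit_correlation_timescale(curve, T_min=T_min, T_max=T_max, mode=mode)
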