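"""Numba kernel for the branching-network time stepper."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_branching(
    targets,  # (N, k) int64 out-targets per sender
    weights,  # (N, k) float64, rows sum to m
    s,  # (N,) uint8 state, modified in place
    x,  # (N,) float64 OU state, modified in place
    gamma,  # float
    use_ou,  # bool
    rho,  # OU one-step decay e^{-dt/tau_ext}
    noise,  # OU innovation scale sqrt(1 - rho^2)
    sigma,  # sensitivity of the external sigmoid
    A_star,  # homeostatic target population activity
    dgamma_coef,  # dt / (tau_gamma * N)
    n_steps,
    sample_idx,  # (n_sample,) units to record (empty -> no recording)
    runaway_limit,  # abort after this many consecutive fully-active steps
    seed,
):
    """Advance the network n_steps; returns (spikes, A, gamma_trace, gamma, ok).

    Each step: recurrent activation probability p_rec,i = sum_j w_ij s_j(t-1)
    clipped at 1; external probability p_ext,i = sigmoid(x_i/sigma + gamma);
    the unit fires with the independent-union probability
    1 - (1 - p_rec)(1 - p_ext).  After the step the homeostat nudges gamma by
    dt (A* - A(t)) / (N tau_gamma) using the just-computed activity A(t).
    """
    np.random.seed(seed)
    N = s.shape[0]
    k = targets.shape[1]
    n_sample = sample_idx.shape[0]
    spikes = np.zeros((n_sample, n_steps), dtype=np.uint8)
    A_trace = np.zeros(n_steps, dtype=np.int64)
    gamma_trace = np.zeros(n_steps, dtype=np.float64)
    p_rec = np.zeros(N, dtype=np.float64)
    s_new = np.zeros(N, dtype=np.uint8)
    run_full = 0
    ok = True
    for t in range(n_steps):
        p_rec[:] = 0.0
        for j in range(N):
            if s[j] == 1:
                for e in range(k):
                    p_rec[targets[j, e]] += weights[j, e]
        if use_ou:
            xi = np.random.standard_normal(N)
            for i in range(N):
                x[i] = x[i] * rho + noise * xi[i]
        A = 0
        for i in range(N):
            p_ext = 1.0 / (1.0 + np.exp(-x[i] / sigma - gamma))
            pr = p_rec[i]
            if pr > 1.0:
                pr = 1.0
            p = 1.0 - (1.0 - pr) * (1.0 - p_ext)
            if np.random.random() < p:
                s_new[i] = 1
                A += 1
            else:
                s_new[i] = 0
        for i in range(N):
            s[i] = s_new[i]
        A_trace[t] = A
        gamma += dgamma_coef * (A_star - A)
        gamma_trace[t] = gamma
        for q in range(n_sample):
            spikes[q, t] = s[sample_idx[q]]
        if A == N:
            run_full += 1
            if run_full > runaway_limit:
                ok = False
                break
        else:
            run_full = 0
    return spikes, A_trace, gamma_trace, gamma, ok
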