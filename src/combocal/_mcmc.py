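"""Random-walk Metropolis kernel for the surface-free toxicity model.

The model parameters are K = 1 + (I-1) + (J-1) ratios in (0,1): the
baseline no-DLT probability theta at the lowest combination, the row ratios
theta_2..theta_I and the column ratios tau_2..tau_J.  The toxicity surface
is pi_ij = 1 - theta * prod(theta_2..theta_i) * prod(tau_2..tau_j), which is
monotone in both drugs by construction.  Sampling is component-wise
random-walk Metropolis on the logit scale with per-coordinate step-size
adaptation during burn-in; the kernel is numba-compiled because it runs once
per cohort inside every simulated trial.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _log_post(x, a, b, y, n, I, J):
    # x: logit ratios; returns log posterior including the logit Jacobian,
    # so the Beta(a,b) prior contributes a*log(r) + b*log(1-r).
    K = x.shape[0]
    r = np.empty(K)
    lr = np.empty(K)
    lp = 0.0
    for k in range(K):
        r[k] = 1.0 / (1.0 + np.exp(-x[k]))
        if r[k] <= 0.0 or r[k] >= 1.0:
            return -np.inf, r
        lr[k] = np.log(r[k])
        lp += a[k] * lr[k] + b[k] * np.log(1.0 - r[k])
    # log survival products: log(1 - pi_ij) = log theta + cum rows + cum cols
    rowcum = np.zeros(I)
    for i in range(1, I):
        rowcum[i] = rowcum[i - 1] + lr[i]
    colcum = np.zeros(J)
    for j in range(1, J):
        colcum[j] = colcum[j - 1] + lr[I - 1 + j]
    for i in range(I):
        for j in range(J):
            if n[i, j] == 0:
                continue
            ls = lr[0] + rowcum[i] + colcum[j]
            pij = 1.0 - np.exp(ls)
            if pij <= 0.0 or pij >= 1.0:
                return -np.inf, r
            lp += y[i, j] * np.log(pij) + (n[i, j] - y[i, j]) * ls
    return lp, r


@njit(cache=False)
def sfd_mcmc(y, n, a, b, I, J, n_iter, burn_in, seed):
    """Posterior mean pi matrix, tail probs P(pi > .) accumulator and draws.

    Returns (ratio_draws, accept_rate): ratio_draws has one row per retained
    iteration with the K ratios on the probability scale.
    """
    np.random.seed(seed)
    K = 1 + (I - 1) + (J - 1)
    # start at the prior means, logit scale
    x = np.empty(K)
    for k in range(K):
        m = a[k] / (a[k] + b[k])
        x[k] = np.log(m / (1.0 - m))
    step = np.full(K, 1.0)
    lp, r = _log_post(x, a, b, y, n, I, J)
    kept = n_iter - burn_in
    draws = np.empty((kept, K))
    accepted = 0
    proposed = 0
    acc_win = np.zeros(K)
    for it in range(n_iter):
        for k in range(K):
            x_old = x[k]
            x[k] = x_old + step[k] * np.random.normal()
            lp_new, r_new = _log_post(x, a, b, y, n, I, J)
            proposed += 1
            if np.log(np.random.random()) < lp_new - lp:
                lp = lp_new
                r = r_new
                accepted += 1
                acc_win[k] += 1.0
            else:
                x[k] = x_old
        # Robbins-Monro style step adaptation towards ~35% acceptance
        if it < burn_in and (it + 1) % 50 == 0:
            for k in range(K):
                rate = acc_win[k] / 50.0
                if rate < 0.20:
                    step[k] *= 0.8
                elif rate > 0.50:
                    step[k] *= 1.25
                acc_win[k] = 0.0
        if it >= burn_in:
            draws[it - burn_in] = r
    return draws, accepted / proposed


@njit(cache=False)
def surface_from_ratios(draws, I, J):
    """Per-draw pi matrices from ratio draws: shape (n_draws, I, J)."""
    nd = draws.shape[0]
    out = np.empty((nd, I, J))
    for t in range(nd):
        for i in range(I):
            for j in range(J):
                s = draws[t, 0]
                for ii in range(1, i + 1):
                    s *= draws[t, ii]
                for jj in range(1, j + 1):
                    s *= draws[t, I - 1 + jj]
                out[t, i, j] = 1.0 - s
    return out
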