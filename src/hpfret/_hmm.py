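"""Numba kernels for the Gaussian-emission hidden Markov model.

Scaled forward-backward (Rabiner normalization) and Viterbi over multiple
concatenated observation sequences.  Kept free of Python objects so the
Baum-Welch loop in :mod:`hpfret.kinetics` stays fast on multi-million-bin
trace sets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SQRT2PI = np.sqrt(2.0 * np.pi)
_TINY = 1e-300


@njit(cache=True)
def _emission_probs(obs, means, sds):
    t_tot = obs.size
    k = means.size
    b = np.empty((t_tot, k))
    for j in range(k):
        inv = 1.0 / (sds[j] * _SQRT2PI)
        inv2 = 0.5 / (sds[j] * sds[j])
        for t in range(t_tot):
            d = obs[t] - means[j]
            b[t, j] = inv * np.exp(-d * d * inv2) + _TINY
    return b


@njit(cache=True)
def em_step(obs, offsets, means, sds, trans, init):
    """One Baum-Welch E-step plus sufficient statistics.

    Returns (loglik, init_acc, s0, s1, s2, xi) where s0/s1/s2 are the
    zeroth/first/second posterior-weighted moments of the observations per
    state and xi the expected transition counts.
    """
    k = means.size
    n_seq = offsets.size - 1
    b = _emission_probs(obs, means, sds)

    loglik = 0.0
    init_acc = np.zeros(k)
    s0 = np.zeros(k)
    s1 = np.zeros(k)
    s2 = np.zeros(k)
    xi = np.zeros((k, k))

    for s in range(n_seq):
        lo = offsets[s]
        hi = offsets[s + 1]
        t_len = hi - lo
        alpha = np.empty((t_len, k))
        beta = np.empty((t_len, k))
        c = np.empty(t_len)

        # forward (scaled)
        tot = 0.0
        for j in range(k):
            alpha[0, j] = init[j] * b[lo, j]
            tot += alpha[0, j]
        c[0] = tot
        for j in range(k):
            alpha[0, j] /= tot
        for t in range(1, t_len):
            tot = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += alpha[t - 1, i] * trans[i, j]
                alpha[t, j] = acc * b[lo + t, j]
                tot += alpha[t, j]
            c[t] = tot
            for j in range(k):
                alpha[t, j] /= tot
        for t in range(t_len):
            loglik += np.log(c[t])

        # backward (scaled)
        for j in range(k):
            beta[t_len - 1, j] = 1.0
        for t in range(t_len - 2, -1, -1):
            for i in range(k):
                acc = 0.0
                for j in range(k):
                    acc += trans[i, j] * b[lo + t + 1, j] * beta[t + 1, j]
                beta[t, i] = acc / c[t + 1]

        # posteriors and sufficient statistics
        for t in range(t_len):
            x = obs[lo + t]
            for j in range(k):
                g = alpha[t, j] * beta[t, j]
                s0[j] += g
                s1[j] += g * x
                s2[j] += g * x * x
                if t == 0:
                    init_acc[j] += g
        for t in range(t_len - 1):
            for i in range(k):
                for j in range(k):
                    xi[i, j] += (
                        alpha[t, i]
                        * trans[i, j]
                        * b[lo + t + 1, j]
                        * beta[t + 1, j]
                        / c[t + 1]
                    )
    return loglik, init_acc, s0, s1, s2, xi


@njit(cache=True)
def log_likelihood(obs, offsets, means, sds, trans, init):
    """Forward-pass log likelihood only."""
    k = means.size
    n_seq = offsets.size - 1
    b = _emission_probs(obs, means, sds)
    loglik = 0.0
    alpha = np.empty(k)
    alpha_new = np.empty(k)
    for s in range(n_seq):
        lo = offsets[s]
        hi = offsets[s + 1]
        tot = 0.0
        for j in range(k):
            alpha[j] = init[j] * b[lo, j]
            tot += alpha[j]
        loglik += np.log(tot)
        for j in range(k):
            alpha[j] /= tot
        for t in range(lo + 1, hi):
            tot = 0.0
            for j in range(k):
                acc = 0.0
                for i in range(k):
                    acc += alpha[i] * trans[i, j]
                alpha_new[j] = acc * b[t, j]
                tot += alpha_new[j]
            loglik += np.log(tot)
            for j in range(k):
                alpha[j] = alpha_new[j] / tot
    return loglik


@njit(cache=True)
def viterbi(obs, means, sds, trans, init):
    """Most probable state path (log space); ties break to the lower index."""
    t_len = obs.size
    k = means.size
    log_b = np.log(_emission_probs(obs, means, sds))
    log_trans = np.log(trans + _TINY)
    delta = np.empty((t_len, k))
    psi = np.zeros((t_len, k), dtype=np.int64)
    for j in range(k):
        delta[0, j] = np.log(init[j] + _TINY) + log_b[0, j]
    for t in range(1, t_len):
        for j in range(k):
            best = delta[t - 1, 0] + log_trans[0, j]
            arg = 0
            for i in range(1, k):
                v = delta[t - 1, i] + log_trans[i, j]
                if v > best:  # strict: ties stay at the lower index
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    path = np.empty(t_len, dtype=np.int64)
    best = delta[t_len - 1, 0]
    arg = 0
    for j in range(1, k):
        if delta[t_len - 1, j] > best:
            best = delta[t_len - 1, j]
            arg = j
    path[t_len - 1] = arg
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
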