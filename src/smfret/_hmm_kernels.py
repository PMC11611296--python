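"""Numba-compiled Baum-Welch E-step.

Numerically identical (up to floating-point association) to the scaled
forward-backward in ``smfret.hmm``; it exists because EM over hundreds of
traces times hundreds of frames times several restarts is the hot loop of the
whole pipeline.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def estep_batch(X, startprob, transmat, means, sds):
    """One E-step over a batch of equal-length sequences X (N, T).

    Returns (loglik, xi_sum (K,K), gamma0_sum (K,), gamma_sum (K,),
    gamma_x_sum (K,), gamma_xx_sum (K,)).
    """
    N, T = X.shape
    K = means.shape[0]
    loglik = 0.0
    xi = np.zeros((K, K))
    g0 = np.zeros(K)
    gsum = np.zeros(K)
    gx = np.zeros(K)
    gxx = np.zeros(K)

    B = np.empty((T, K))
    alpha = np.empty((T, K))
    c = np.empty(T)
    beta_t = np.empty(K)
    beta_tp = np.empty(K)

    for n in range(N):
        for t in range(T):
            for k in range(K):
                z = (X[n, t] - means[k]) / sds[k]
                b = math.exp(-0.5 * z * z) / (_SQRT2PI * sds[k])
                B[t, k] = b if b > 1e-300 else 1e-300

        s = 0.0
        for k in range(K):
            a = startprob[k] * B[0, k]
            alpha[0, k] = a
            s += a
        c[0] = s
        for k in range(K):
            alpha[0, k] /= s
        for t in range(1, T):
            s = 0.0
            for k in range(K):
                a = 0.0
                for j in range(K):
                    a += alpha[t - 1, j] * transmat[j, k]
                a *= B[t, k]
                alpha[t, k] = a
                s += a
            c[t] = s
            for k in range(K):
                alpha[t, k] /= s
        for t in range(T):
            loglik += math.log(c[t])

        for k in range(K):
            beta_tp[k] = 1.0
            g = alpha[T - 1, k]
            x = X[n, T - 1]
            gsum[k] += g
            gx[k] += g * x
            gxx[k] += g * x * x
        if T == 1:
            for k in range(K):
                g0[k] += alpha[0, k]
            continue
        for t in range(T - 2, -1, -1):
            for k in range(K):
                beta_t[k] = 0.0
            for j in range(K):
                bbj = B[t + 1, j] * beta_tp[j] / c[t + 1]
                for i in range(K):
                    beta_t[i] += transmat[i, j] * bbj
                    xi[i, j] += alpha[t, i] * transmat[i, j] * bbj
            x = X[n, t]
            for k in range(K):
                g = alpha[t, k] * beta_t[k]
                gsum[k] += g
                gx[k] += g * x
                gxx[k] += g * x * x
                beta_tp[k] = beta_t[k]
        for k in range(K):
            g0[k] += alpha[0, k] * beta_t[k]
    return loglik, xi, g0, gsum, gx, gxx
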