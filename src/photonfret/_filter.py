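"""Low-level normalized filter recursions (numba-compiled hot loops).

The photon-by-photon likelihood is a long product of interphoton propagators
exp(dt * G_non) and radiative jump matrices G_rad.  Raw products underflow,
so every step renormalizes the filter and accumulates the log of the
normalizer.  The fast path works in the eigenbasis of G_non: propagation is
an elementwise complex exponential and each jump a small dense mat-vec.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["scan_eigenbasis", "scan_dense"]


@njit(cache=True)
def scan_eigenbasis(u0, eigs, w_ones, jumps, dts, channels):
    """Scaled filter recursion in the eigenbasis of the nonradiative generator.

    Parameters
    ----------
    u0 : (M,) complex — starting filter rho_start @ V.
    eigs : (M,) complex — eigenvalues of G_non.
    w_ones : (M,) complex — V^-1 @ ones; the filter mass is Re(u . w_ones).
    jumps : (C, M, M) complex — V^-1 @ G_rad[c] @ V per channel.
    dts : (K,) float — interphoton waiting times (first entry from T_start).
    channels : (K,) int64 — registration channel per photon.

    Returns (sum of log normalizers, final filter u).  Returns -inf when the
    filter mass becomes nonpositive or nonfinite (impossible observation).
    """
    m = u0.shape[0]
    u = u0.copy()
    v = np.empty(m, dtype=np.complex128)
    loglik = 0.0
    for k in range(dts.shape[0]):
        dt = dts[k]
        for i in range(m):
            u[i] = u[i] * np.exp(dt * eigs[i])
        c = channels[k]
        for j in range(m):
            s = 0.0 + 0.0j
            for i in range(m):
                s += u[i] * jumps[c, i, j]
            v[j] = s
        p = 0.0
        for i in range(m):
            p += (v[i] * w_ones[i]).real
        if not np.isfinite(p) or p <= 0.0:
            return -np.inf, u
        loglik += np.log(p)
        inv = 1.0 / p
        for i in range(m):
            u[i] = v[i] * inv
    return loglik, u


@njit(cache=True)
def scan_dense(rho0, propagators, jumps, channels):
    """Scaled filter recursion with precomputed per-gap propagators.

    ``propagators`` is (K, M, M) real — exp(dt_k * G_non) per gap — and
    ``jumps`` is (C, M, M) real.  Fallback path for generators whose
    eigendecomposition is unreliable.
    """
    k_tot, m, _ = propagators.shape
    rho = rho0.copy()
    tmp = np.empty(m)
    loglik = 0.0
    for k in range(k_tot):
        for j in range(m):
            s = 0.0
            for i in range(m):
                s += rho[i] * propagators[k, i, j]
            tmp[j] = s
        c = channels[k]
        p = 0.0
        for j in range(m):
            s = 0.0
            for i in range(m):
                s += tmp[i] * jumps[c, i, j]
            rho[j] = s
            p += s
        if not np.isfinite(p) or p <= 0.0:
            return -np.inf, rho
        loglik += np.log(p)
        for j in range(m):
            rho[j] /= p
    return loglik, rho
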