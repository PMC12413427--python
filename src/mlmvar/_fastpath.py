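"""Numba-compiled per-person likelihood for the common fast case.

Covers single-indicator models with fixed dynamic coefficients and a
shared innovation covariance on complete data — the workhorse
configuration of the recovery studies.  The vectorized numpy route in
``posterior`` remains the general implementation; equivalence of the two
is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def person_logp_single(
    y0,  # (N, T, Q) observed values (column per construct), zeros if absent
    present,  # (N, T) bool
    lag_valid,  # (N, T) bool
    Z,  # (N, K) person vectors
    E,  # (N, K) realized effects (traits in first Q columns)
    phi,  # (J,) fixed dynamic coefficients
    t_out, t_pred, t_lag, t_pred2, t_lag2,  # (J,) int term metadata; pred2 < 0 if none
    Sinv,  # (Q, Q) innovation precision
    logdet,  # scalar log|Sigma|
    Iinv,  # (Q, Q) initial-state precision (ignored if use_init False)
    Ilogdet,
    use_init,  # bool
    LOG_2PI,
):
    N, T, Q = y0.shape
    K = Z.shape[1]
    J = phi.shape[0]
    out = np.empty(N)
    eta = np.empty((T, Q))
    resid = np.empty(Q)
    for i in range(N):
        acc = -0.5 * K * LOG_2PI
        for k in range(K):
            acc -= 0.5 * Z[i, k] * Z[i, k]
        for t in range(T):
            for q in range(Q):
                if present[i, t]:
                    eta[t, q] = y0[i, t, q] - E[i, q]
                else:
                    eta[t, q] = 0.0
        for t in range(T):
            if lag_valid[i, t]:
                for q in range(Q):
                    resid[q] = eta[t, q]
                for j in range(J):
                    if t_lag[j] == 1:
                        x = eta[t - 1, t_pred[j]]
                    else:
                        x = eta[t, t_pred[j]]
                    if t_pred2[j] >= 0:
                        if t_lag2[j] == 1:
                            x *= eta[t - 1, t_pred2[j]]
                        else:
                            x *= eta[t, t_pred2[j]]
                    resid[t_out[j]] -= phi[j] * x
                quad = 0.0
                for a in range(Q):
                    for b in range(Q):
                        quad += resid[a] * Sinv[a, b] * resid[b]
                acc -= 0.5 * (quad + Q * LOG_2PI + logdet)
            elif present[i, t] and use_init:
                quad = 0.0
                for a in range(Q):
                    for b in range(Q):
                        quad += eta[t, a] * Iinv[a, b] * eta[t, b]
                acc -= 0.5 * (quad + Q * LOG_2PI + Ilogdet)
        out[i] = acc
    return out
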