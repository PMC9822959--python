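"""Gibbs sampler kernel for the Barry-Hartigan product-partition change model.

The model: observations are i.i.d. Normal within blocks of a partition of the
time axis; block means are drawn around a common level with prior variance
shrinking with block size (the Barry-Hartigan choice), the change probability
``p`` has a U(0, p0) prior and the signal-to-noise parameter
``w = sigma^2 / (sigma^2 + sigma0^2)`` has a U(0, w0) prior.  Integrating the
means, the common level and the variance analytically leaves, for a partition
with ``k`` blocks, a marginal proportional to

    [ integral_0^p0 p^(k-1) (1-p)^(n-k) dp ] *
    [ integral_0^w0 w^((k-1)/2) (W + B w)^(-(n-1)/2) dw ]

with ``W`` the within-block and ``B`` the between-block sum of squares.  Each
interior boundary indicator is resampled from its full conditional, the odds
being the ratio of the two marginals with the indicator on and off.  The two
one-dimensional integrals are evaluated by fixed-node Gauss-Legendre
quadrature in log space; block sums come from prefix sums so a single
indicator update is O(block length).

The kernel is compiled with numba when available; the identical pure-Python
path is used otherwise (slower, same results are not expected to be
bit-identical across the two paths, but each path is deterministic).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)
GL_NODES = (_GL_X + 1.0) / 2.0  # nodes on (0, 1)
GL_LOGW = np.log(_GL_W / 2.0)


@njit(cache=False)
def _log_p_integral(a, c, p0, nodes, logw):
    """log of integral_0^p0 p^a (1-p)^c dp."""
    m = -1e300
    vals = np.empty(nodes.size)
    for j in range(nodes.size):
        p = p0 * nodes[j]
        v = logw[j] + a * np.log(p) + c * np.log1p(-p)
        vals[j] = v
        if v > m:
            m = v
    s = 0.0
    for j in range(nodes.size):
        s += np.exp(vals[j] - m)
    return m + np.log(s) + np.log(p0)


@njit(cache=False)
def _log_w_integral(e, W, B, half_nm1, w0, nodes, logw):
    """log of integral_0^w0 w^e (W + B w)^(-(n-1)/2) dw."""
    m = -1e300
    vals = np.empty(nodes.size)
    for j in range(nodes.size):
        w = w0 * nodes[j]
        v = logw[j] - half_nm1 * np.log(W + B * w)
        if e > 0.0:
            v += e * np.log(w)
        vals[j] = v
        if v > m:
            m = v
    s = 0.0
    for j in range(nodes.size):
        s += np.exp(vals[j] - m)
    return m + np.log(s) + np.log(w0)


@njit(cache=False)
def gibbs_mean_change(x, p0, w0, sweeps, burnin, seed, nodes, logw):
    """Run the Gibbs sampler; return per-boundary posterior change probabilities.

    Boundary ``i`` (0-based, i = 0..n-2) sits between observations ``i`` and
    ``i+1``; the returned array has length n-1.
    """
    n = x.size
    np.random.seed(seed)
    S = np.zeros(n + 1)
    S2 = np.zeros(n + 1)
    for i in range(n):
        S[i + 1] = S[i] + x[i]
        S2[i + 1] = S2[i] + x[i] * x[i]
    St = S[n]
    S2t = S2[n]
    gterm = St * St / n
    tot_ss = S2t - gterm
    wfloor = 1e-12 * tot_ss if tot_ss > 0.0 else 1e-300
    half_nm1 = 0.5 * (n - 1)

    rho = np.zeros(n - 1, np.int64)
    nb = 1
    Q = gterm
    counts = np.zeros(n - 1)

    for sweep in range(sweeps):
        for i in range(n - 1):
            # bounds of the block(s) around boundary i given the other indicators
            j = i - 1
            while j >= 0 and rho[j] == 0:
                j -= 1
            start = j + 1
            j = i + 1
            end = n - 1
            while j <= n - 2:
                if rho[j] == 1:
                    end = j
                    break
                j += 1
            nA = i - start + 1
            nB = end - i
            SA = S[i + 1] - S[start]
            SB = S[end + 1] - S[i + 1]
            qa = SA * SA / nA + SB * SB / nB
            qm = (SA + SB) * (SA + SB) / (nA + nB)
            if rho[i] == 1:
                Q1 = Q
                Q0 = Q - qa + qm
                k = nb
            else:
                Q0 = Q
                Q1 = Q - qm + qa
                k = nb + 1
            W1 = S2t - Q1
            B1 = Q1 - gterm
            W0 = S2t - Q0
            B0 = Q0 - gterm
            if W1 < wfloor:
                W1 = wfloor
            if W0 < wfloor:
                W0 = wfloor
            if B1 < 0.0:
                B1 = 0.0
            if B0 < 0.0:
                B0 = 0.0
            log_odds = (
                _log_p_integral(k - 1.0, float(n - k), p0, nodes, logw)
                - _log_p_integral(k - 2.0, float(n - k + 1), p0, nodes, logw)
                + _log_w_integral(0.5 * (k - 1), W1, B1, half_nm1, w0, nodes, logw)
                - _log_w_integral(0.5 * (k - 2), W0, B0, half_nm1, w0, nodes, logw)
            )
            if log_odds > 50.0:
                pr1 = 1.0
            elif log_odds < -50.0:
                pr1 = 0.0
            else:
                pr1 = 1.0 / (1.0 + np.exp(-log_odds))
            new = 1 if np.random.random() < pr1 else 0
            if new != rho[i]:
                if new == 1:
                    Q = Q - qm + qa
                    nb += 1
                    rho[i] = 1
                else:
                    Q = Q - qa + qm
                    nb -= 1
                    rho[i] = 0
        if sweep >= burnin:
            for i in range(n - 1):
                counts[i] += rho[i]
    return counts / (sweeps - burnin)
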