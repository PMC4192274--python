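"""Numba kernels for the BayesB sampler.

Randomness is counter-based: every locus update at every sweep draws from
its own splitmix64 stream seeded by (chain seed, stable locus key, sweep).
Chains are therefore bit-reproducible and, because loci are visited in a
canonical order given by their keys, exactly invariant to the column order
of the genotype matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)
_KEY_MU = np.uint64(0xA5A5A5A5A5A5A5A5)
_KEY_SIGMA = np.uint64(0x5A5A5A5A5A5A5A5A)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _mix(z):
    z = (z + _GOLDEN) & _MASK
    z = ((z ^ (z >> np.uint64(30))) * _C1) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * _C2) & _MASK
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _stream_init(seed, key, sweep):
    s = _mix(np.uint64(seed) ^ _mix(key))
    return _mix(s ^ _mix(np.uint64(sweep)))


@njit(cache=True, inline="always")
def _next(state):
    state = (state + _GOLDEN) & _MASK
    z = state
    z = ((z ^ (z >> np.uint64(30))) * _C1) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * _C2) & _MASK
    z = z ^ (z >> np.uint64(31))
    return z, state


@njit(cache=True, inline="always")
def _u01(state):
    z, state = _next(state)
    # 53-bit mantissa in (0, 1); never exactly 0
    return (np.float64(z >> np.uint64(11)) + 0.5) * _INV53, state


@njit(cache=True, inline="always")
def _randn(state):
    u1, state = _u01(state)
    u2, state = _u01(state)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2), state


@njit(cache=True)
def _gamma(shape, state):
    """Marsaglia-Tsang gamma(shape, 1) draw for shape > 0."""
    boost = 1.0
    a = shape
    if a < 1.0:
        u, state = _u01(state)
        boost = u ** (1.0 / a)
        a = a + 1.0
    d = a - 1.0 / 3.0
    c = 1.0 / np.sqrt(9.0 * d)
    while True:
        x, state = _randn(state)
        v = 1.0 + c * x
        if v <= 0.0:
            continue
        v = v * v * v
        u, state = _u01(state)
        if u < 1.0 - 0.0331 * x * x * x * x:
            return boost * d * v, state
        if np.log(u) < 0.5 * x * x + d * (1.0 - v + np.log(v)):
            return boost * d * v, state


@njit(cache=True, inline="always")
def _chi2(df, state):
    g, state = _gamma(0.5 * df, state)
    return 2.0 * g, state


@njit(cache=True, inline="always")
def _locus_loglik(v, xx, xw, sigma2e):
    """Log marginal likelihood of locus variance v (effect integrated out),
    relative to the excluded (v = 0) state."""
    if v <= 0.0:
        return 0.0
    t = v * xx / sigma2e
    return -0.5 * (np.log1p(t) - v * xw * xw / (sigma2e * (sigma2e + v * xx)))


@njit(cache=True)
def bayesb_chain(
    Xt,            # (m, n) dosage matrix, SNP-major
    y,             # (n,)
    keys,          # (m,) uint64 stable locus keys
    schedule,      # (m,) visit order (indices into columns), canonical by key
    one_minus_pi,
    nu,
    s_scale,
    n_iterations,
    thin,
    mh_inner,
    seed,
    rec_a,         # (R, m) out
    rec_delta,     # (R, m) uint8 out
    rec_sigma2e,   # (R,) out
    rec_mu,        # (R,) out
    rec_loglik,    # (R,) out
):
    """Run the BayesB Gibbs/Metropolis-Hastings chain, recording every thin-th sweep.

    Returns 0 on success, 1 on a divergent (non-finite) residual variance.
    """
    m, n = Xt.shape
    pi0 = 1.0 - one_minus_pi

    a = np.zeros(m)
    delta = np.zeros(m, dtype=np.uint8)
    sigv = np.zeros(m)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    r = np.empty(n)
    vy = 0.0
    for i in range(n):
        r[i] = y[i] - mu
        vy += r[i] * r[i]
    sigma2e = vy / n
    if sigma2e <= 0.0:
        sigma2e = 1.0

    xx = np.empty(m)
    for j in range(m):
        t = 0.0
        for i in range(n):
            t += Xt[j, i] * Xt[j, i]
        xx[j] = t

    for sweep in range(n_iterations):
        for pos in range(m):
            j = schedule[pos]
            state = _stream_init(seed, keys[j], sweep)
            xr = 0.0
            for i in range(n):
                xr += Xt[j, i] * r[i]
            xw = xr + a[j] * xx[j]  # x' residual with locus j excluded
            cur_in = delta[j] == 1
            cur_v = sigv[j] if cur_in else 0.0
            ll_cur = _locus_loglik(cur_v, xx[j], xw, sigma2e)
            for _ in range(mh_inner):
                u, state = _u01(state)
                if u < pi0:
                    prop_v = 0.0
                    ll_prop = 0.0
                else:
                    c2, state = _chi2(nu, state)
                    prop_v = nu * s_scale / c2
                    ll_prop = _locus_loglik(prop_v, xx[j], xw, sigma2e)
                ua, state = _u01(state)
                # proposal equals the prior, so the MH ratio is the likelihood ratio
                if np.log(ua) < ll_prop - ll_cur:
                    cur_v = prop_v
                    ll_cur = ll_prop
            new_a = 0.0
            if cur_v > 0.0:
                prec = xx[j] / sigma2e + 1.0 / cur_v
                mean = (xw / sigma2e) / prec
                z, state = _randn(state)
                new_a = mean + z / np.sqrt(prec)
                delta[j] = 1
                sigv[j] = cur_v
            else:
                delta[j] = 0
                sigv[j] = 0.0
            da = new_a - a[j]
            if da != 0.0:
                for i in range(n):
                    r[i] -= Xt[j, i] * da
                a[j] = new_a

        # intercept: flat prior, normal full conditional
        state = _stream_init(seed, _KEY_MU, sweep)
        zbar = 0.0
        for i in range(n):
            zbar += r[i]
        zbar = zbar / n + mu
        zn, state = _randn(state)
        new_mu = zbar + zn * np.sqrt(sigma2e / n)
        dmu = new_mu - mu
        for i in range(n):
            r[i] -= dmu
        mu = new_mu

        # residual variance: flat scale prior -> scaled inv-chi2(n, SSE/n)
        state = _stream_init(seed, _KEY_SIGMA, sweep)
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        c2, state = _chi2(np.float64(n), state)
        sigma2e = sse / c2
        if not np.isfinite(sigma2e) or sigma2e <= 0.0:
            return 1

        if (sweep + 1) % thin == 0:
            rec = (sweep + 1) // thin - 1
            const = -0.5 * np.log(2.0 * np.pi * sigma2e)
            ll = 0.0
            for i in range(n):
                ll += np.abs(const - r[i] * r[i] / (2.0 * sigma2e))
            for j in range(m):
                rec_a[rec, j] = a[j]
                rec_delta[rec, j] = delta[j]
            rec_sigma2e[rec] = sigma2e
            rec_mu[rec] = mu
            rec_loglik[rec] = ll
    return 0
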