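"""Compiled hot loops for the treated-model solvers.

The Adams–Bashforth–Moulton scheme for Caputo dynamics carries the full
solution history, so a naive implementation is O(N^2) Python.  These
kernels keep the history sums in contiguous float64 arrays (with the
evaluation history stored reversed so every per-step sum is a contiguous
BLAS dot) and evaluate the treated right-hand side in scalar code.

If numba is unavailable the module degrades to pure Python with identical
semantics; everything here is deliberately free of Python objects.

Law codes: 0 = exponential, 1 = logistic, 2 = exponential-linear.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _growth(law: int, a: float, K: float, lam0: float, lam1: float, psi: float, v: float) -> float:
    if law == 0:
        return a * v
    if law == 1:
        return a * v * (1.0 - v / K)
    if v <= 0.0:
        # exponential continuation keeps the rhs continuous if the state
        # transiently dips non-positive
        return lam0 * v
    # exponential-linear, evaluated in log space to stay finite at large v
    x = psi * math.log(lam0 * v / lam1)
    if x > 0.0:
        log_bracket = x + math.log1p(math.exp(-x))
    else:
        log_bracket = math.log1p(math.exp(x))
    return lam0 * v * math.exp(-log_bracket / psi)


@njit(cache=True)
def _window_train(t: float, taus: np.ndarray, tw: float, eps: float, cutoff: float) -> float:
    s = 0.0
    for i in range(taus.shape[0]):
        dt = t - taus[i]
        if dt < -cutoff or dt > tw + cutoff:
            continue
        s += 0.5 * (math.tanh(dt / eps) - math.tanh((dt - tw) / eps))
    return s / tw


@njit(cache=True)
def _rhs(
    law: int,
    a: float,
    K: float,
    lam0: float,
    lam1: float,
    psi: float,
    kill: float,
    taus: np.ndarray,
    tw: float,
    eps: float,
    cutoff: float,
    t: float,
    v: float,
) -> float:
    g = _growth(law, a, K, lam0, lam1, psi, v)
    if kill == 0.0 or taus.shape[0] == 0 or v <= 0.0:
        return g
    return g - v * kill * _window_train(t, taus, tw, eps, cutoff)


@njit(cache=True)
def _abm_treated(
    law: int,
    a: float,
    K: float,
    lam0: float,
    lam1: float,
    psi: float,
    kill: float,
    taus: np.ndarray,
    tw: float,
    eps: float,
    cutoff: float,
    v0: float,
    mu: float,
    h: float,
    n_steps: int,
    corrector_iterations: int,
):
    """Fixed-step predictor–corrector for D^mu v = rhs(t, v), v(0) = v0.

    Returns (states, ok, bad_index).  Predictor uses rectangle weights
    b_{j,n+1} = (h^mu/mu)((n+1-j)^mu - (n-j)^mu); the corrector uses the
    trapezoid-type weights with a_{0,n+1} = (n^{mu+1} - (n-mu)(n+1)^mu),
    second-difference interior weights and a_{n+1,n+1} = 1, all scaled by
    h^mu/Gamma(mu+2).  At mu = 1 this is the classical one-step AB/AM pair
    and is computed with O(N) running sums instead of history dots.
    """
    N = n_steps
    v = np.empty(N + 1)
    v[0] = v0
    # evaluation history stored reversed: frev[N - j] = f(t_j, v_j)
    frev = np.empty(N + 1)
    f0 = _rhs(law, a, K, lam0, lam1, psi, kill, taus, tw, eps, cutoff, 0.0, v0)
    frev[N] = f0

    if mu == 1.0:
        rect = f0  # running rectangle sum of f_0..f_n
        trap = 0.0  # running sum f_1 + ... + f_n
        for n in range(N):
            t1 = (n + 1) * h
            pred = v0 + h * rect
            fp = _rhs(law, a, K, lam0, lam1, psi, kill, taus, tw, eps, cutoff, t1, pred)
            vn1 = pred
            for _ in range(corrector_iterations):
                vn1 = v0 + h * (0.5 * f0 + trap + 0.5 * fp)
                fp = _rhs(law, a, K, lam0, lam1, psi, kill, taus, tw, eps, cutoff, t1, vn1)
            if not math.isfinite(vn1):
                return v, False, n + 1
            v[n + 1] = vn1
            fn1 = fp
            frev[N - (n + 1)] = fn1
            rect += fn1
            trap += fn1
        return v, True, -1

    gamma_mu1 = math.gamma(mu + 1.0)
    gamma_mu2 = math.gamma(mu + 2.0)
    hb = h**mu / gamma_mu1
    hc = h**mu / gamma_mu2
    # predictor convolution weights cb[k] = (k+1)^mu - k^mu
    cb = np.empty(N + 1)
    # corrector interior weights e[k] = (k+1)^{mu+1} - 2 k^{mu+1} + (k-1)^{mu+1}
    ce = np.empty(N + 1)
    for k in range(N + 1):
        cb[k] = (k + 1.0) ** mu - float(k) ** mu
        if k >= 1:
            ce[k] = (k + 1.0) ** (mu + 1.0) - 2.0 * float(k) ** (mu + 1.0) + (k - 1.0) ** (mu + 1.0)
    ce[0] = 1.0  # unused slot

    for n in range(N):
        t1 = (n + 1) * h
        # sum_{j=0}^{n} cb[n-j] f_j  ==  dot(cb[0:n+1], frev[N-n : N+1])
        hist_p = np.dot(cb[: n + 1], frev[N - n : N + 1])
        pred = v0 + hb * hist_p
        fp = _rhs(law, a, K, lam0, lam1, psi, kill, taus, tw, eps, cutoff, t1, pred)
        vn1 = pred
        if corrector_iterations > 0:
            a0 = float(n) ** (mu + 1.0) - (n - mu) * (n + 1.0) ** mu
            # sum_{j=1}^{n} ce[n+1-j] f_j  ==  dot(ce[1:n+1], frev[N-n : N])
            hist_c = np.dot(ce[1 : n + 1], frev[N - n : N]) if n >= 1 else 0.0
            for _ in range(corrector_iterations):
                vn1 = v0 + hc * (a0 * f0 + hist_c + fp)
                fp = _rhs(law, a, K, lam0, lam1, psi, kill, taus, tw, eps, cutoff, t1, vn1)
        if not math.isfinite(vn1):
            return v, False, n + 1
        v[n + 1] = vn1
        frev[N - (n + 1)] = fp
    return v, True, -1
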