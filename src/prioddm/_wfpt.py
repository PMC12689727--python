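"""Numba kernels for the two-boundary Wiener first-passage-time density.

The defective density of absorption at the *lower* boundary at decision
time ``tau = t - t0`` for a diffusion with drift ``v``, boundary
separation ``a``, relative start point ``w`` and unit diffusion scale is

    f_lower(tau) = (1/a^2) * exp(-v*a*w - v^2*tau/2) * f1(tau/a^2, w)

where ``f1(u, w)`` is the standardised (a=1, v=0) density.  ``f1`` has
two series representations — one converging quickly for small ``u``
(image/reflection sum) and one for large ``u`` (spectral sine series) —
and the number of terms needed for a requested absolute error has a
closed-form bound for each.  The kernel evaluates whichever series needs
fewer terms.  The upper-boundary density follows by the reflection
``(v, w) -> (-v, 1-w)``.

Everything here is ``nopython`` compiled; the public API lives in
:mod:`prioddm.wiener`.
"""

import math

import numpy as np
from numba import njit

# log-density floor: keeps MCMC proposals comparable instead of -inf
LOGP_FLOOR = -700.0

# mode selectors for the standardised density
MODE_AUTO = 0
MODE_SMALL = 1
MODE_LARGE = 2


@njit(cache=True)
def _n_terms_small(u, eps):
    """Term count bound for the small-time series at absolute error eps."""
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        lo = math.sqrt(u) + 1.0
        if ks < lo:
            ks = lo
    else:
        ks = 2.0
    return int(math.ceil(ks))


@njit(cache=True)
def _n_terms_large(u, eps):
    """Term count bound for the large-time series at absolute error eps."""
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        lo = 1.0 / (math.pi * math.sqrt(u))
        if kl < lo:
            kl = lo
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    return int(math.ceil(kl))


@njit(cache=True)
def _f1(u, w, eps, mode):
    """Standardised lower-boundary FPT density at scaled time u, start w."""
    if u <= 0.0:
        return 0.0
    ks = _n_terms_small(u, eps)
    kl = _n_terms_large(u, eps)
    use_small = ks < kl
    if mode == MODE_SMALL:
        use_small = True
    elif mode == MODE_LARGE:
        use_small = False
    if use_small:
        acc = 0.0
        # sum k = -K..K of (w + 2k) * phi-like kernel
        K = ks
        for k in range(-K, K + 1):
            z = w + 2.0 * k
            acc += z * math.exp(-z * z / (2.0 * u))
        return acc / math.sqrt(2.0 * math.pi * u * u * u)
    acc = 0.0
    for k in range(1, kl + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return math.pi * acc


@njit(cache=True)
def wfpt_pdf(t, upper, v, a, w, t0, eps, mode):
    """Defective FPT density at clock time t for the stated boundary.

    upper: 1 for the upper (correct) boundary, 0 for the lower.
    eps is the absolute truncation error target on the returned density.
    """
    tau = t - t0
    if tau <= 0.0 or not math.isfinite(tau):
        return 0.0
    if upper:
        vv = -v
        ww = 1.0 - w
    else:
        vv = v
        ww = w
    u = tau / (a * a)
    expo = -vv * a * ww - vv * vv * tau / 2.0
    scale = math.exp(expo) / (a * a)
    if scale <= 0.0:
        return 0.0
    eps1 = eps / scale
    if eps1 < 1e-30:
        eps1 = 1e-30
    f1 = _f1(u, ww, eps1, mode)
    if f1 <= 0.0:
        return 0.0
    return scale * f1


@njit(cache=True)
def wfpt_logpdf(t, upper, v, a, w, t0):
    """Floored log of wfpt_pdf at the default 1e-7 accuracy target."""
    p = wfpt_pdf(t, upper, v, a, w, t0, 1e-7, MODE_AUTO)
    if p <= 0.0:
        return LOGP_FLOOR
    lp = math.log(p)
    if lp < LOGP_FLOOR:
        return LOGP_FLOOR
    return lp


@njit(cache=True)
def pdf_grid(taus, upper, v, a, w):
    """Density over a grid of decision times (t0 = 0)."""
    out = np.empty(taus.shape[0])
    for i in range(taus.shape[0]):
        out[i] = wfpt_pdf(taus[i], upper, v, a, w, 0.0, 1e-9, MODE_AUTO)
    return out


@njit(cache=True)
def loglik_trials(rt, upper, v, a, t0):
    """Sum of floored trial log-densities with per-trial parameter arrays."""
    s = 0.0
    for i in range(rt.shape[0]):
        s += wfpt_logpdf(rt[i], upper[i], v[i], a[i], 0.5, t0[i])
    return s
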