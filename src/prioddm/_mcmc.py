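"""Numba Metropolis-within-Gibbs kernel for the hierarchical DDM.

Model targeted, for subject s and parameter column p (of P = n_v + n_a +
n_t columns; boundary and non-decision columns live on the log scale):

    theta[s, p] ~ Normal(mu[p], sigma[p])          (sampling scale)
    mu[p]       ~ Normal(prior_m[p], prior_s[p])
    sigma[p]    ~ HalfNormal(sd_scale[p])

with the Wiener FPT likelihood of each subject's trials evaluated at the
natural-scale parameters.  Updates per iteration:

* each (subject, column) scalar by random-walk Metropolis, touching only
  the trials mapped to that column (cached per-trial log-densities);
* each group mean by its conjugate normal Gibbs draw;
* each group SD by random-walk Metropolis on log sigma.

Proposal scales adapt toward ~44% acceptance during burn-in only and are
frozen afterwards, so the post-burn-in kernel satisfies detailed
balance.  The recorded deviance is -2 times the subject-level
log-likelihood only (group-level densities excluded).
"""

import math

import numpy as np
from numba import njit

from ._wfpt import wfpt_logpdf

ADAPT_WINDOW = 50
ADAPT_TARGET = 0.44


@njit(cache=True)
def _trial_logp(theta_s, vix_i, aix_i, tix_i, rt_i, up_i):
    v = theta_s[vix_i]
    a = math.exp(theta_s[aix_i])
    t0 = math.exp(theta_s[tix_i])
    return wfpt_logpdf(rt_i, up_i, v, a, 0.5, t0)


@njit(cache=True)
def dataset_loglik(rt, up, sidx, vix, aix, tix, theta):
    """Subject-level log-likelihood of all trials at one theta matrix."""
    s = 0.0
    for i in range(rt.shape[0]):
        s += _trial_logp(theta[sidx[i]], vix[i], aix[i], tix[i], rt[i], up[i])
    return s


@njit(cache=True)
def deviance_per_draw(rt, up, sidx, vix, aix, tix, theta_draws):
    """-2 log-likelihood for each draw in (n_draws, S, P) theta_draws."""
    n = theta_draws.shape[0]
    out = np.empty(n)
    for d in range(n):
        out[d] = -2.0 * dataset_loglik(rt, up, sidx, vix, aix, tix, theta_draws[d])
    return out


@njit(cache=True)
def run_chain(
    rt,
    up,
    sidx,
    vix,
    aix,
    tix,
    group_trials,
    group_off,
    fam,
    prior_m,
    prior_s,
    sd_scale,
    theta,
    mu,
    sig,
    n_iter,
    burn_in,
    seed,
):
    """One MCMC chain; returns post-burn-in draws and acceptance rates."""
    np.random.seed(seed)
    n = rt.shape[0]
    S, P = theta.shape
    keep = n_iter - burn_in

    mu_draws = np.empty((keep, P))
    sig_draws = np.empty((keep, P))
    theta_draws = np.empty((keep, S, P))
    dev_draws = np.empty(keep)

    cur_ll = np.empty(n)
    for i in range(n):
        cur_ll[i] = _trial_logp(theta[sidx[i]], vix[i], aix[i], tix[i], rt[i], up[i])

    # proposal scales by family: drift natural, boundary/t0 on log scale
    th_step = np.empty((S, P))
    for p in range(P):
        s0 = 0.25 if fam[p] == 0 else (0.08 if fam[p] == 1 else 0.05)
        for s in range(S):
            th_step[s, p] = s0
    sig_step = np.full(P, 0.3)

    th_acc = np.zeros((S, P))
    th_try = np.zeros((S, P))
    sig_acc = np.zeros(P)
    sig_try = np.zeros(P)

    maxg = 0
    for g in range(group_off.shape[0] - 1):
        L = group_off[g + 1] - group_off[g]
        if L > maxg:
            maxg = L
    tmp_ll = np.empty(maxg)

    for it in range(n_iter):
        # --- subject-level scalar Metropolis sweeps -----------------------
        for s in range(S):
            for p in range(P):
                g = s * P + p
                i0 = group_off[g]
                i1 = group_off[g + 1]
                old = theta[s, p]
                prop = old + th_step[s, p] * np.random.normal()
                sg2 = sig[p] * sig[p]
                d = -0.5 * ((prop - mu[p]) ** 2 - (old - mu[p]) ** 2) / sg2
                for k in range(i0, i1):
                    i = group_trials[k]
                    v = theta[s, vix[i]]
                    la = theta[s, aix[i]]
                    lt = theta[s, tix[i]]
                    if fam[p] == 0:
                        v = prop
                    elif fam[p] == 1:
                        la = prop
                    else:
                        lt = prop
                    nl = wfpt_logpdf(rt[i], up[i], v, math.exp(la), 0.5, math.exp(lt))
                    tmp_ll[k - i0] = nl
                    d += nl - cur_ll[i]
                th_try[s, p] += 1.0
                if math.log(np.random.random()) < d:
                    theta[s, p] = prop
                    for k in range(i0, i1):
                        cur_ll[group_trials[k]] = tmp_ll[k - i0]
                    th_acc[s, p] += 1.0

        # --- group means: conjugate Gibbs --------------------------------
        for p in range(P):
            sg2 = sig[p] * sig[p]
            prec = 1.0 / (prior_s[p] * prior_s[p]) + S / sg2
            tsum = 0.0
            for s in range(S):
                tsum += theta[s, p]
            mean = (prior_m[p] / (prior_s[p] * prior_s[p]) + tsum / sg2) / prec
            mu[p] = mean + np.random.normal() / math.sqrt(prec)

        # --- group SDs: Metropolis on log sigma --------------------------
        for p in range(P):
            ls = math.log(sig[p])
            lsp = ls + sig_step[p] * np.random.normal()
            sp = math.exp(lsp)
            ssq = 0.0
            for s in range(S):
                dlt = theta[s, p] - mu[p]
                ssq += dlt * dlt
            d = -S * (lsp - ls)
            d += -0.5 * ssq * (1.0 / (sp * sp) - 1.0 / (sig[p] * sig[p]))
            d += -(sp * sp - sig[p] * sig[p]) / (2.0 * sd_scale[p] * sd_scale[p])
            d += lsp - ls  # log-scale Jacobian
            sig_try[p] += 1.0
            if math.log(np.random.random()) < d:
                sig[p] = sp
                sig_acc[p] += 1.0

        # --- proposal adaptation, burn-in only ---------------------------
        if it < burn_in and (it + 1) % ADAPT_WINDOW == 0:
            for s in range(S):
                for p in range(P):
                    if th_try[s, p] > 0:
                        rate = th_acc[s, p] / th_try[s, p]
                        th_step[s, p] *= math.exp(1.5 * (rate - ADAPT_TARGET))
                        if th_step[s, p] < 1e-4:
                            th_step[s, p] = 1e-4
                        elif th_step[s, p] > 10.0:
                            th_step[s, p] = 10.0
                    th_acc[s, p] = 0.0
                    th_try[s, p] = 0.0
            for p in range(P):
                if sig_try[p] > 0:
                    rate = sig_acc[p] / sig_try[p]
                    sig_step[p] *= math.exp(1.5 * (rate - ADAPT_TARGET))
                    if sig_step[p] < 1e-4:
                        sig_step[p] = 1e-4
                    elif sig_step[p] > 10.0:
                        sig_step[p] = 10.0
                sig_acc[p] = 0.0
                sig_try[p] = 0.0

        if it >= burn_in:
            j = it - burn_in
            for p in range(P):
                mu_draws[j, p] = mu[p]
                sig_draws[j, p] = sig[p]
            for s in range(S):
                for p in range(P):
                    theta_draws[j, s, p] = theta[s, p]
            dev = 0.0
            for i in range(n):
                dev += cur_ll[i]
            dev_draws[j] = -2.0 * dev

    return mu_draws, sig_draws, theta_draws, dev_draws
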