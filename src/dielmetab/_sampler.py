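"""Numba kernels: Kalman marginal likelihood and adaptive Metropolis chain.

The state-space model for one day is linear-Gaussian conditional on the
parameters, so the latent DO states are integrated out exactly by a
scalar Kalman filter; MCMC then runs on the low-dimensional parameter
vector ``theta = (I, rho20, K20, o2_init, sigma_p, sigma_o)``.

Transition between grid slots i and i+1 (explicit Euler, one step per
30-min interval; drivers indexed at the departing slot):

    a_i = 1 - K20 * scfac_i * step_h
    b_i = I*qp_i - rho20*resp_i + K20*scfac_i*step_h * osat_i
    x_{i+1} = a_i x_i + b_i + N(0, sigma_p^2)

where ``resp_i = theta_T^(T_i-20)`` and ``scfac_i = sqrt(Sc(20)/Sc(T_i))``
de-standardises K20 to in-situ temperature. Observations are
``y_i = x_i + N(0, sigma_o^2)`` wherever ``obs_i`` is true. The first
state is the parameter ``o2_init`` (zero initial variance).
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_2PI = float(np.log(2.0 * np.pi))

# parameter indices
I_, RHO_, K20_, O2INIT_, SIGP_, SIGO_ = 0, 1, 2, 3, 4, 5
NPAR = 6


@njit(cache=True)
def kalman_loglik(theta, y, obs, qp, resp, osat, scfac, step_h):
    """Exact marginal log-likelihood of one day's observations."""
    I = theta[I_]
    rho = theta[RHO_]
    k20 = theta[K20_]
    sp2 = theta[SIGP_] * theta[SIGP_]
    so2 = theta[SIGO_] * theta[SIGO_]
    n = y.shape[0]
    m = theta[O2INIT_]
    P = 0.0
    ll = 0.0
    for i in range(n):
        if obs[i]:
            S = P + so2
            if S <= 0.0:
                return -np.inf
            r = y[i] - m
            ll += -0.5 * (LOG_2PI + np.log(S) + r * r / S)
            g = P / S
            m = m + g * r
            P = P * (1.0 - g)
        if i < n - 1:
            kT = k20 * scfac[i] * step_h
            a = 1.0 - kT
            b = I * qp[i] - rho * resp[i] + kT * osat[i]
            m = a * m + b
            P = a * a * P + sp2
    return ll


@njit(cache=True)
def _log_post(theta, y, obs, qp, resp, osat, scfac, step_h,
              lo, hi, k20_normal, k20_mu, k20_sd):
    for j in range(NPAR):
        if theta[j] < lo[j] or theta[j] > hi[j]:
            return -np.inf
    lp = 0.0
    if k20_normal:
        z = (theta[K20_] - k20_mu) / k20_sd
        lp += -0.5 * z * z
    return lp + kalman_loglik(theta, y, obs, qp, resp, osat, scfac, step_h)


@njit(cache=True)
def run_chain(x0, n_iter, y, obs, qp, resp, osat, scfac, step_h,
              lo, hi, k20_normal, k20_mu, k20_sd,
              scales0, update_mask, adapt_until, seed):
    """Adaptive random-walk Metropolis with covariance learning.

    Warm-up runs component-wise updates with per-parameter scales
    adapting toward 0.44 acceptance; once enough samples accumulate the
    proposal switches to a joint Gaussian whose covariance is the
    running empirical covariance of the chain (Haario-style, scaled by
    2.38²/d and tuned toward 0.234 acceptance), which follows the
    strong GPP–ER–K₂₀ posterior ridge. All adaptation stops at
    ``adapt_until`` (the burn-in) so retained draws form a valid Markov
    chain. Returns the full chain, shape (n_iter, NPAR).
    """
    np.random.seed(seed)
    chain = np.empty((n_iter, NPAR))
    theta = x0.copy()
    scales = scales0.copy()
    lp = _log_post(theta, y, obs, qp, resp, osat, scfac, step_h,
                   lo, hi, k20_normal, k20_mu, k20_sd)

    act = np.empty(NPAR, dtype=np.int64)
    d = 0
    for j in range(NPAR):
        if update_mask[j]:
            act[d] = j
            d += 1
    act = act[:d]

    phase1 = min(1500, adapt_until // 2)
    mean = np.zeros(d)
    m2 = np.zeros((d, d))
    count = 0
    L = np.eye(d)
    have_l = False
    log_s = 0.0
    base_s = 2.38 / np.sqrt(d)
    acc_c = np.zeros(NPAR)
    acc_j = 0.0
    cbatch = 0
    jbatch = 0

    for it in range(n_iter):
        if it < phase1 or not have_l:
            # component-wise warm-up
            for jj in range(d):
                j = act[jj]
                old = theta[j]
                theta[j] = old + scales[j] * np.random.normal()
                lp_new = _log_post(theta, y, obs, qp, resp, osat, scfac, step_h,
                                   lo, hi, k20_normal, k20_mu, k20_sd)
                if np.log(np.random.random()) < lp_new - lp:
                    lp = lp_new
                    acc_c[j] += 1.0
                else:
                    theta[j] = old
            if it < adapt_until and (it + 1) % 50 == 0:
                cbatch += 1
                delta = min(0.25, 1.0 / np.sqrt(cbatch))
                for jj in range(d):
                    j = act[jj]
                    if acc_c[j] / 50.0 > 0.44:
                        scales[j] *= np.exp(delta)
                    else:
                        scales[j] *= np.exp(-delta)
                    acc_c[j] = 0.0
        else:
            # joint proposal along the learned covariance
            z = np.empty(d)
            for jj in range(d):
                z[jj] = np.random.normal()
            step = base_s * np.exp(log_s) * (L @ z)
            prop = theta.copy()
            for jj in range(d):
                prop[act[jj]] = theta[act[jj]] + step[jj]
            lp_new = _log_post(prop, y, obs, qp, resp, osat, scfac, step_h,
                               lo, hi, k20_normal, k20_mu, k20_sd)
            if np.log(np.random.random()) < lp_new - lp:
                theta = prop
                lp = lp_new
                acc_j += 1.0
            if it < adapt_until and (it + 1) % 100 == 0:
                jbatch += 1
                delta = min(0.25, 1.0 / np.sqrt(jbatch))
                if acc_j / 100.0 > 0.234:
                    log_s += delta
                else:
                    log_s -= delta
                acc_j = 0.0

        # running covariance of the chain (adaptation phase only)
        if it < adapt_until and it >= phase1 // 2:
            count += 1
            delta_old = np.empty(d)
            for jj in range(d):
                delta_old[jj] = theta[act[jj]] - mean[jj]
                mean[jj] += delta_old[jj] / count
            for jj in range(d):
                dn_j = theta[act[jj]] - mean[jj]
                for kk in range(d):
                    m2[jj, kk] += delta_old[kk] * dn_j
            if count >= 200 and (it + 1) % 200 == 0:
                cov = m2 / (count - 1)
                cov = 0.5 * (cov + cov.T)
                tr = 0.0
                for jj in range(d):
                    tr += cov[jj, jj]
                eps = 1e-12 + 1e-8 * tr / d
                for jj in range(d):
                    cov[jj, jj] += eps
                L = np.linalg.cholesky(cov)
                have_l = True

        chain[it] = theta
    return chain
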