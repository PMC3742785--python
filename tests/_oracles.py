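"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's filtering/aggregation code paths:
the state-space marginal likelihood is reproduced by dense numerical
quadrature over the latent states, and the correlation statistics by
textbook O(n^2) formulas.
"""

import numpy as np

from dielmetab.gas_exchange import SC_O2_20, o2_saturation, schmidt_o2


def transition_coefficients(params, temp, qp, step_h=0.5):
    """Per-step affine transition x' = a x + b implied by the oxygen model."""
    kT = params.K20 * np.sqrt(SC_O2_20 / schmidt_o2(np.asarray(temp))) * step_h
    a = 1.0 - kT
    b = (params.I * np.asarray(qp)
         - params.rho20 * params.theta ** (np.asarray(temp) - 20.0)
         + kT * o2_saturation(np.asarray(temp)))
    return a, b


def quadrature_loglik(params, noise, y, temp, qp, step_h=0.5, n_grid=1201, width=10.0):
    """Marginal log-likelihood by trapezoid quadrature over latent states.

    Works for short days (the latent dimension is len(y) - 1). NaN
    entries of ``y`` are treated as missing observations. The state at
    slot 0 is the parameter ``o2_init`` exactly.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    a, b = transition_coefficients(params, temp, qp, step_h)
    sp, so = noise.sigma_p, noise.sigma_o

    def logn(x, mu, sd):
        return -0.5 * (np.log(2 * np.pi) + 2 * np.log(sd) + ((x - mu) / sd) ** 2)

    # deterministic path to center the grids
    det = np.empty(n)
    det[0] = params.o2_init
    for i in range(n - 1):
        det[i + 1] = a[i] * det[i] + b[i]
    half = width * (sp * np.sqrt(n) + so + 0.1)
    grids = [np.linspace(det[i] - half, det[i] + half, n_grid) for i in range(n)]

    # forward pass over discretized states x_1 .. x_{n-1}
    ll0 = logn(y[0], params.o2_init, so) if not np.isnan(y[0]) else 0.0
    # density over x_1
    log_w = logn(grids[1], a[0] * params.o2_init + b[0], sp)
    if not np.isnan(y[1]):
        log_w = log_w + logn(y[1], grids[1], so)
    for i in range(2, n):
        xprev, xcur = grids[i - 1], grids[i]
        trans = logn(xcur[None, :], a[i - 1] * xprev[:, None] + b[i - 1], sp)
        mx = log_w.max()
        w = np.exp(log_w - mx)
        dx = xprev[1] - xprev[0]
        integ = np.trapezoid(w[:, None] * np.exp(trans), dx=dx, axis=0)
        with np.errstate(divide="ignore"):
            log_w = mx + np.log(integ)
        if not np.isnan(y[i]):
            log_w = log_w + logn(y[i], xcur, so)
    mx = log_w.max()
    dx = grids[-1][1] - grids[-1][0]
    return ll0 + mx + np.log(np.trapezoid(np.exp(log_w - mx), dx=dx))


def pearson_brute(x, y):
    """Textbook sample correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def kendall_tau_b_brute(x, y):
    """O(n^2) concordant/discordant count with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (nc - nd) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2))
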