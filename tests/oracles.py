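"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form solver: concentrations
come from stiff ODE integration of the compartmental mass-balance system,
and marginal likelihoods from adaptive Gauss-Hermite quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import roots_hermite


def ode_profile(params, dose_nmol, dose_times, t_eval, rtol=1e-10):
    """Central concentration (and amounts) by piecewise LSODA integration.

    Returns (conc, amounts) where amounts is an (4, len(t_eval)) array of
    (depot, central, peripheral, eliminated) in nmol.  Integration is split
    at every input discontinuity (dose + lag, end of zero-order release).
    """
    k10 = params.cl_f / params.vc_f
    k12 = params.q_f / params.vc_f
    k21 = params.q_f / params.vp_f
    ka, d1, alag = params.ka, params.d1, params.alag1
    dose_times = np.atleast_1d(np.asarray(dose_times, dtype=float))

    def in_rate(t):
        r = 0.0
        for td in dose_times:
            if d1 > 0:
                if td + alag <= t < td + alag + d1:
                    r += dose_nmol / d1
        return r

    def rhs(t, x):
        dep, cen, per, elim = x
        return [
            in_rate(t) - ka * dep,
            ka * dep - (k10 + k12) * cen + k21 * per,
            k12 * cen - k21 * per,
            k10 * cen,
        ]

    t_eval = np.asarray(t_eval, dtype=float)
    breaks = set()
    for td in dose_times:
        breaks.add(td + alag)
        breaks.add(td + alag + d1)
    breaks = sorted(b for b in breaks if 0.0 < b < t_eval[-1])
    edges = [0.0] + breaks + [t_eval[-1]]

    x = np.zeros(4)
    conc = np.empty_like(t_eval)
    amounts = np.empty((4, t_eval.size))
    done = np.zeros(t_eval.size, dtype=bool)
    if d1 == 0:
        raise ValueError("oracle assumes zero-order release (d1 > 0)")
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (~done) & (t_eval >= lo) & (t_eval <= hi + 1e-12)
        pts = t_eval[sel]
        # always evaluate the segment end so the carried state is at `hi`
        ts = np.unique(np.concatenate([pts, [hi]]))
        sol = solve_ivp(rhs, (lo, hi), x, t_eval=ts,
                        rtol=rtol, atol=1e-8, method="LSODA", max_step=(hi - lo) / 10)
        if pts.size:
            idx = np.searchsorted(ts, pts)
            conc[sel] = sol.y[1, idx] / params.vc_f
            amounts[:, sel] = sol.y[:, idx]
            done |= sel
        x = sol.y[:, -1]
    return conc, amounts


def gh_marginal_ofv(y, times, theta_typ, cl_index, omega2_cl, sigma2, tau, dose_nmol,
                    n_nodes=60):
    """-2 log marginal likelihood by adaptive 1-D Gauss-Hermite quadrature
    for a model whose only random effect is on clearance.

    ``theta_typ`` is an (n_subjects, 7) array of typical individual
    parameters; the integral over eta_CL is centred and scaled at the
    per-subject mode (found by dense scan plus golden refinement).
    """
    from empabridge.model import conc_once_daily
    from scipy.optimize import minimize_scalar

    nodes, weights = roots_hermite(n_nodes)
    total = 0.0
    for i in range(theta_typ.shape[0]):
        t_i = np.asarray(times[i], dtype=float)
        y_i = np.asarray(y[i], dtype=float)

        def neg_log_joint(eta):
            th = theta_typ[i].copy()
            th[cl_index] *= np.exp(eta)
            f = conc_once_daily(th, t_i, tau, dose_nmol)
            f = np.maximum(f, 1e-12)
            var = sigma2 * f * f
            ll = -0.5 * np.sum((y_i - f) ** 2 / var + np.log(2 * np.pi * var))
            lp = -0.5 * (eta**2 / omega2_cl + np.log(2 * np.pi * omega2_cl))
            return -(ll + lp)

        res = minimize_scalar(neg_log_joint, bounds=(-4, 4), method="bounded",
                              options={"xatol": 1e-10})
        mode = res.x
        h = 1e-4
        hess = (neg_log_joint(mode + h) - 2 * neg_log_joint(mode) + neg_log_joint(mode - h)) / h**2
        scale = 1.0 / np.sqrt(max(hess, 1e-8))
        etas = mode + np.sqrt(2.0) * scale * nodes
        vals = np.array([-neg_log_joint(e) for e in etas])
        # log sum of w_k exp(vals + nodes^2) * sqrt(2) * scale
        logterms = vals + nodes**2 + np.log(weights) + 0.5 * np.log(2.0) + np.log(scale)
        m = logterms.max()
        log_l = m + np.log(np.sum(np.exp(logterms - m)))
        total += -2.0 * log_l
    return total
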