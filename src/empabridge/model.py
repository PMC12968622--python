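"""Two-compartment oral PK model with sequential zero-/first-order absorption.

The structural model is the disposition model identified for empagliflozin in
adults: the dose is released at a constant (zero-order) rate over a duration
``d1`` into an absorption depot, starting after a lag ``alag1``; the depot
empties into the central compartment by first-order absorption (``ka``); the
central compartment exchanges with a peripheral compartment (``q_f``,
``vp_f``) and is cleared by first-order elimination (``cl_f``).

The central concentration is evaluated in closed form.  For a unit amount
delivered as a bolus into the depot the central concentration is a sum of
three exponentials with rates (alpha, beta, ka); the zero-order release is
its exact convolution with a rectangular input, and repeated dosing is
handled by superposition (finite sums for a finite dose history, geometric
series for steady state).  All core routines broadcast over leading axes of
the parameter array, so whole virtual cohorts are evaluated in one call.
"""

from __future__ import annotations

import numpy as np

from .params import (
    ConcentrationProfile,
    DosingRegimen,
    ExposureMetrics,
    PKParameters,
    ValidationError,
)

__all__ = [
    "predict_concentration",
    "steady_state_profile",
    "exposure_metrics",
    "terminal_half_life",
    "conc_after_doses",
    "conc_steady_state",
    "disposition_rates",
]

# Relative eigenvalue separation below which ka is nudged off a disposition
# rate; the tri-exponential coefficients are singular at exact coincidence.
_DEGENERACY_TOL = 1e-9
_KA_NUDGE = 3.16e-6


def _theta(params) -> np.ndarray:
    if isinstance(params, PKParameters):
        return params.as_array()
    arr = np.asarray(params, dtype=float)
    if arr.shape[-1] != 7:
        raise ValidationError(f"parameter array must have last dimension 7, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("non-finite PK parameter")
    if np.any(arr[..., :5] <= 0) or np.any(arr[..., 5:] < 0):
        raise ValidationError("invalid PK parameter (cl, vc, vp, q, ka > 0; d1, alag1 >= 0)")
    return arr


def disposition_rates(params) -> tuple[np.ndarray, np.ndarray]:
    """Macro rate constants (alpha, beta) of the two-compartment disposition.

    alpha > beta > 0 are the roots of ``s^2 + (k10+k12+k21) s + k10 k21``.
    """
    th = _theta(params)
    cl, vc, vp, q = th[..., 0], th[..., 1], th[..., 2], th[..., 3]
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    # beta via the product identity: avoids cancellation when beta << alpha
    beta = (k10 * k21) / alpha
    return alpha, beta


def _exp_system(th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rates ``lam`` and coefficients ``coef`` (each shape (..., 3)) such that
    a unit bolus into the depot yields central concentration
    ``sum_i coef_i * exp(-lam_i * t)``."""
    alpha, beta = disposition_rates(th)
    vc, vp, q, ka = th[..., 1], th[..., 2], th[..., 3], np.array(th[..., 4], copy=True)
    k21 = q / vp
    # nudge ka away from coincident disposition rates (coefficients blow up)
    for lam in (alpha, beta):
        close = np.abs(ka - lam) < _DEGENERACY_TOL * np.maximum(ka, lam)
        if np.any(close):
            ka = np.where(close, ka * (1.0 + _KA_NUDGE), ka)
    a_al = (ka / vc) * (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    a_be = (ka / vc) * (k21 - beta) / ((ka - beta) * (alpha - beta))
    a_ka = (ka / vc) * (k21 - ka) / ((alpha - ka) * (beta - ka))
    lam = np.stack([alpha, beta, ka], axis=-1)
    coef = np.stack([a_al, a_be, a_ka], axis=-1)
    return lam, coef


def _single_dose_terms(th: np.ndarray, tp: np.ndarray) -> np.ndarray:
    """Concentration per unit dose (nmol -> nmol/L) at time-after-dose-start
    ``tp`` measured from the administration (lag included).

    ``th`` has shape (..., 7); ``tp`` must broadcast against ``(...,) + tp``.
    Returns the concentration with shape broadcast(th[..., 0], tp).
    """
    lam, coef = _exp_system(th)  # batch + (3,)
    t = np.asarray(tp, dtype=float)
    if t.ndim == 0:
        t = t[None]
    batch = th.shape[:-1]
    # give the parameter arrays singleton axes for every time dimension
    pshape = batch + (1,) * t.ndim
    return _conv_kernel(
        lam.reshape(pshape + (3,)),
        coef.reshape(pshape + (3,)),
        th[..., 5].reshape(pshape),
        th[..., 6].reshape(pshape),
        t,
    )


def _conv_kernel(lam, coef, d1, alag, tp) -> np.ndarray:
    """Unit-dose central concentration at time-after-administration ``tp``.

    ``lam``/``coef`` carry a trailing axis of 3 exponential terms; all other
    arguments broadcast together.  Zero-order release of a unit amount over
    ``d1`` (after lag ``alag``) convolved with the tri-exponential bolus
    response:

        (1/d1) * sum_i (coef_i/lam_i) * expm1(lam_i*u) * exp(-lam_i*te)

    with ``te = max(tp - alag, 0)`` and ``u = min(te, d1)``; tends to the
    pure first-order bolus response as d1 -> 0.
    """
    te = np.maximum(tp - alag, 0.0)
    u = np.minimum(te, d1)
    body = np.sum(
        (coef / lam) * np.expm1(lam * u[..., None]) * np.exp(-lam * te[..., None]),
        axis=-1,
    )
    bolus = np.sum(coef * np.exp(-lam * te[..., None]), axis=-1)
    safe_d1 = np.where(d1 > 0, d1, 1.0)
    out = np.where(d1 > 0, body / safe_d1, bolus)
    return np.where(te > 0, out, 0.0)


def conc_history_batch(theta, times, dose_times, dose_amounts_nmol) -> np.ndarray:
    """Concentrations for per-subject time vectors under a shared dose history.

    ``theta`` is (n, 7); ``times`` is (n, m) (pad unused slots with any value
    <= 0 and mask downstream); ``dose_times``/``dose_amounts_nmol`` are (k,)
    shared by all rows.  Doses after a row's last observation contribute
    nothing, so one history covering the longest schedule serves all rows.
    Returns (n, m).
    """
    th = _theta(theta)
    t = np.asarray(times, dtype=float)
    dt = np.asarray(dose_times, dtype=float)
    amt = np.broadcast_to(np.asarray(dose_amounts_nmol, dtype=float), dt.shape)
    lam, coef = _exp_system(th)
    lead = th.shape[:-1]
    tp = t[..., None] - dt  # lead + (m, k)
    c = _conv_kernel(
        lam.reshape(lead + (1, 1, 3)),
        coef.reshape(lead + (1, 1, 3)),
        th[..., 5].reshape(lead + (1, 1)),
        th[..., 6].reshape(lead + (1, 1)),
        tp,
    )
    return c @ amt


def conc_after_doses(params, times, dose_times, dose_amounts_nmol) -> np.ndarray:
    """Central concentration (nmol/L) under an explicit dose history.

    Parameters
    ----------
    params : PKParameters or array (..., 7)
    times : array (m,) — observation times, h since the first dose.
    dose_times : array (k,) — administration times, h.
    dose_amounts_nmol : scalar or array (k,) — amounts in nmol.

    Returns array of shape (..., m).
    """
    th = _theta(params)
    t = np.atleast_1d(np.asarray(times, dtype=float))
    dt = np.atleast_1d(np.asarray(dose_times, dtype=float))
    amt = np.broadcast_to(np.asarray(dose_amounts_nmol, dtype=float), dt.shape)
    tp = t[:, None] - dt[None, :]  # (m, k)
    c = _single_dose_terms(th, tp)  # (..., m, k)
    return np.sum(c * amt, axis=-1)


def conc_once_daily(theta, times, tau, dose_nmol) -> np.ndarray:
    """Concentration under uninterrupted once-``tau`` dosing from t = 0.

    Equivalent to superposing doses at 0, tau, 2*tau, ... <= t, but the
    completed-absorption doses are collapsed into a geometric partial sum,
    so the cost is independent of how long dosing has been running.
    Requires ``tau > alag1 + d1``.  ``times`` must broadcast against
    ``theta.shape[:-1] + (m,)``; negative times yield 0.
    """
    th = _theta(theta)
    tau = float(tau)
    if np.any(th[..., 5] + th[..., 6] >= tau):
        raise ValidationError("once-daily superposition requires alag1 + d1 < tau")
    lam, coef = _exp_system(th)
    lead = th.shape[:-1]
    lam = lam.reshape(lead + (1, 3))
    coef = coef.reshape(lead + (1, 3))
    d1 = th[..., 5].reshape(lead + (1,))
    alag = th[..., 6].reshape(lead + (1,))
    t = np.maximum(np.asarray(times, dtype=float), 0.0)
    k_last = np.floor(t / tau)
    s = t - k_last * tau  # time since the most recent dose, in [0, tau)
    current = _conv_kernel(lam, coef, d1, alag, s) * dose_nmol
    # all k_last earlier doses are past absorption: terminal coefficients
    lam_d1 = lam * d1[..., None]
    h = np.where(d1[..., None] > 0, np.expm1(lam_d1) / np.where(lam_d1 > 0, lam_d1, 1.0), 1.0)
    b = dose_nmol * coef * h
    r = np.exp(-lam * tau)
    # sum_{p=1..k} exp(-lam (s + p tau - alag)) = e^{-lam(s-alag)} r (1-r^k)/(1-r)
    geo = r * (1.0 - np.exp(-lam * tau * k_last[..., None])) / (1.0 - r)
    tail = np.sum(b * np.exp(-lam * (s[..., None] - alag[..., None])) * geo, axis=-1)
    return current + tail


try:  # optional JIT acceleration of the hot once-daily kernel
    from numba import njit as _njit

    @_njit(cache=False)
    def _once_daily_jit(lam, coef, d1, alag, times, tau, dose):  # pragma: no cover
        b, m = times.shape
        out = np.empty((b, m))
        for ib in range(b):
            for j in range(m):
                t = times[ib, j]
                if t < 0.0:
                    t = 0.0
                k = np.floor(t / tau)
                s = t - k * tau
                x = s - alag[ib]
                acc = 0.0
                for i in range(3):
                    li = lam[ib, i]
                    ci = coef[ib, i]
                    ld = li * d1[ib]
                    h = np.expm1(ld) / ld if ld > 0.0 else 1.0
                    bi = dose * ci * h
                    r = np.exp(-li * tau)
                    w = bi * r * (1.0 - np.exp(-li * tau * k)) / (1.0 - r)
                    if x >= d1[ib]:
                        w += bi
                    elif x > 0.0:
                        w += (dose / d1[ib]) * (ci / li) * np.expm1(li * x)
                    acc += np.exp(-li * x) * w
                out[ib, j] = acc
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def conc_once_daily_fast(theta, times, tau, dose_nmol) -> np.ndarray:
    """JIT-compiled :func:`conc_once_daily` over a flat (b, 7)/(b, m) batch;
    falls back to the numpy implementation when numba is unavailable."""
    th = _theta(theta)
    t = np.ascontiguousarray(np.broadcast_to(times, th.shape[:-1] + np.shape(times)[-1:]), dtype=float)
    if not _HAVE_NUMBA:
        return conc_once_daily(th, t, tau, dose_nmol)
    if np.any(th[..., 5] + th[..., 6] >= tau):
        raise ValidationError("once-daily superposition requires alag1 + d1 < tau")
    flat = th.reshape(-1, 7)
    lam, coef = _exp_system(flat)
    out = _once_daily_jit(
        np.ascontiguousarray(lam),
        np.ascontiguousarray(coef),
        np.ascontiguousarray(flat[:, 5]),
        np.ascontiguousarray(flat[:, 6]),
        t.reshape(-1, t.shape[-1]),
        float(tau),
        float(dose_nmol),
    )
    return out.reshape(t.shape)


def conc_steady_state(params, times, tau, dose_nmol) -> np.ndarray:
    """Steady-state central concentration on ``times`` in [0, tau].

    Exact geometric-series superposition of infinitely many ``tau``-spaced
    doses; requires ``tau > alag1 + d1`` so that absorption from one dose is
    complete (as a piecewise expression) before the next interval's formula
    applies.
    """
    th = _theta(params)
    d1, alag = th[..., 5], th[..., 6]
    tau = float(tau)
    if np.any(alag + d1 >= tau):
        raise ValidationError("steady-state superposition requires alag1 + d1 < tau")
    t = np.atleast_1d(np.asarray(times, dtype=float))

    current = _single_dose_terms(th, t) * dose_nmol  # (..., m)

    lam, coef = _exp_system(th)  # (..., 3)
    with np.errstate(over="ignore"):
        h = np.where(
            d1[..., None] > 0,
            np.expm1(lam * d1[..., None]) / np.where(d1[..., None] > 0, lam * d1[..., None], 1.0),
            1.0,
        )
    b = dose_nmol * coef * h  # terminal-phase coefficients of one dose
    r = np.exp(-lam * tau)
    geo = r / (1.0 - r)
    # tail of all earlier doses: sum_i b_i geo_i exp(-lam_i (t - alag))
    expo = np.exp(-lam[..., None, :] * (t[:, None] - alag[..., None, None]))
    tail = np.sum(b[..., None, :] * geo[..., None, :] * expo, axis=-1)
    return current + tail


def predict_concentration(params: PKParameters, regimen: DosingRegimen, times) -> ConcentrationProfile:
    """Concentration-time profile under repeated dosing, by superposition.

    ``times`` are hours since the first administration (non-negative,
    strictly increasing).  The profile is linear in dose.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("times must be a non-empty 1-D array")
    if np.any(t < 0):
        raise ValidationError("times must be non-negative")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValidationError("times must be strictly increasing")
    dose_times = np.arange(regimen.n_doses) * regimen.tau
    c = conc_after_doses(params, t, dose_times, regimen.dose_nmol)
    return ConcentrationProfile(times=t, concentrations=c)


class ConvergenceError(RuntimeError):
    """Accumulation to steady state did not converge."""


def steady_state_profile(
    params: PKParameters,
    regimen: DosingRegimen,
    grid_step: float = 0.05,
    method: str = "analytic",
    max_intervals: int = 60,
    rel_tol: float = 1e-6,
) -> ConcentrationProfile:
    """Steady-state profile over one dosing interval [0, tau].

    ``method='analytic'`` uses the exact geometric-series superposition;
    ``method='simulate'`` accumulates once-daily doses (28 by default, up to
    ``max_intervals``) until the trough changes by less than ``rel_tol``
    relative between successive doses, and returns the interval after the
    last administered dose.  The time origin is the dose defining the
    interval.
    """
    if grid_step > 0.1:
        raise ValidationError(f"grid_step must be <= 0.1 h, got {grid_step}")
    tau = regimen.tau
    n_grid = int(round(tau / grid_step))
    t = np.linspace(0.0, tau, n_grid + 1)
    if method == "analytic":
        c = conc_steady_state(params, t, tau, regimen.dose_nmol)
        return ConcentrationProfile(times=t, concentrations=c)
    if method != "simulate":
        raise ValidationError(f"unknown method {method!r}")
    # troughs after k doses: T_k = sum_{j=1..k} S(j*tau) for unit superposition
    k = np.arange(1, max_intervals + 1)
    s = conc_after_doses(params, k * tau, np.array([0.0]), regimen.dose_nmol)
    troughs = np.cumsum(s)
    rel = np.abs(np.diff(troughs)) / np.maximum(np.abs(troughs[1:]), 1e-300)
    # number of doses: at least 28 (once daily for 28 days), more if needed
    ok = np.nonzero(rel < rel_tol)[0]
    if ok.size == 0:
        raise ConvergenceError(
            f"trough not converged within {max_intervals} intervals; "
            f"achieved relative change {rel[-1]:.3e} (tolerance {rel_tol:.1e})"
        )
    n_doses = max(28, int(ok[0]) + 2)
    if n_doses > max_intervals:
        raise ConvergenceError(f"required {n_doses} intervals exceeds cap {max_intervals}")
    dose_times = np.arange(n_doses) * tau
    c = conc_after_doses(params, t + (n_doses - 1) * tau, dose_times, regimen.dose_nmol)
    return ConcentrationProfile(times=t, concentrations=c)


def exposure_metrics(profile: ConcentrationProfile, tau: float = 24.0) -> ExposureMetrics:
    """AUC (trapezoidal), Cmax/Tmax (grid maximum, earliest tie) and Css over
    one dosing interval of a steady-state profile covering [0, tau]."""
    t = profile.times
    c = profile.concentrations
    if t[0] > 1e-12 or t[-1] < tau - 1e-9:
        raise ValidationError(f"profile must span [0, {tau}] h, got [{t[0]}, {t[-1]}]")
    step = np.max(np.diff(t))
    if step > 0.05 + 1e-12:
        raise ValidationError(f"profile grid step must be <= 0.05 h, got {step:.4g}")
    mask = t <= tau + 1e-9
    auc = float(np.trapezoid(c[mask], t[mask]))
    i = int(np.argmax(c[mask]))  # argmax returns the first maximum
    return ExposureMetrics(auc_0_24=auc, cmax=float(c[i]), tmax=float(t[i]), css=auc / tau)


def steady_state_metrics_batch(
    theta,
    dose_mg: float,
    tau: float = 24.0,
    grid_step: float = 0.05,
    chunk: int = 2000,
) -> dict:
    """Steady-state exposure metrics for a batch of parameter sets.

    ``theta`` is an (n, 7) array of individual parameters; returns a dict of
    arrays ``auc`` (trapezoidal AUC over [0, tau]), ``cmax``, ``tmax``
    (grid maximum, earliest tie) and ``css``.  Evaluation is chunked to keep
    the (n, n_grid) concentration matrix within a modest memory footprint.
    """
    from .params import mg_to_nmol

    th = _theta(theta)
    if th.ndim != 2:
        th = th.reshape(-1, 7)
    n = th.shape[0]
    dose_nmol = mg_to_nmol(dose_mg)
    t = np.linspace(0.0, tau, int(round(tau / grid_step)) + 1)
    auc = np.empty(n)
    cmax = np.empty(n)
    tmax = np.empty(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        c = conc_steady_state(th[lo:hi], t, tau, dose_nmol)
        auc[lo:hi] = np.trapezoid(c, t, axis=-1)
        idx = np.argmax(c, axis=-1)
        cmax[lo:hi] = np.take_along_axis(c, idx[:, None], axis=-1)[:, 0]
        tmax[lo:hi] = t[idx]
    return {"auc": auc, "cmax": cmax, "tmax": tmax, "css": auc / tau}


def terminal_half_life(params) -> float | np.ndarray:
    """Terminal half-life of the observable disposition phase.

    ln2 / beta for a genuine two-compartment system; when the slow (beta)
    phase carries negligible amplitude (the one-compartment limit q -> 0,
    where beta -> 0 but its coefficient vanishes), the alpha phase is the
    observable terminal slope and is used instead.
    """
    th = _theta(params)
    alpha, beta = disposition_rates(th)
    k21 = th[..., 3] / th[..., 2]
    # amplitude fraction of the beta phase for an IV bolus: (k21-beta)/(alpha-beta)
    frac_beta = (k21 - beta) / (alpha - beta)
    lam_z = np.where(frac_beta > 1e-8, beta, alpha)
    out = np.log(2.0) / lam_z
    return float(out) if np.ndim(out) == 0 else out
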