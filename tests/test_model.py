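"""Structural PK model: closed-form solver vs identities and ODE oracle."""

import numpy as np
import pytest

from empabridge import (
    ConcentrationProfile,
    DosingRegimen,
    PKParameters,
    ValidationError,
    exposure_metrics,
    predict_concentration,
    steady_state_profile,
    terminal_half_life,
)
from empabridge.params import mg_to_nmol
from empabridge.model import conc_once_daily, conc_once_daily_fast, conc_steady_state

from conftest import random_params
from oracles import ode_profile


def test_no_drug_before_lag(simple_params):
    reg = DosingRegimen(dose_mg=25, n_doses=1)
    prof = predict_concentration(simple_params, reg, np.array([0.0, 0.25, 0.49]))
    assert np.all(prof.concentrations == 0.0)
    later = predict_concentration(simple_params, reg, np.array([0.6, 1.0]))
    assert np.all(later.concentrations > 0.0)


def test_dose_linearity(simple_params):
    t = np.linspace(0.1, 72, 200)
    c25 = predict_concentration(simple_params, DosingRegimen(25, 24, 3), t).concentrations
    c50 = predict_concentration(simple_params, DosingRegimen(50, 24, 3), t).concentrations
    np.testing.assert_allclose(c50, 2.0 * c25, rtol=1e-10)


def test_single_dose_auc_identity():
    # total area under the full curve equals dose_nmol / CL
    p = PKParameters(cl_f=10.083, vc_f=30, vp_f=60, q_f=10, ka=1.5, d1=1.5, alag1=0.5)
    t = np.arange(0.0, 500.0001, 0.02)
    prof = predict_concentration(p, DosingRegimen(25, 24, 1), t)
    auc = np.trapezoid(prof.concentrations, prof.times)
    expected = mg_to_nmol(25) / p.cl_f  # = 5499 * 25mg-to-nmol rounding => ~5500
    assert abs(auc - expected) / expected < 0.005


def test_steady_state_auc_identity_random_params():
    rng = np.random.default_rng(42)
    for p in random_params(rng, 100):
        reg = DosingRegimen(25, 24, 28)
        prof = steady_state_profile(p, reg, grid_step=0.05)
        m = exposure_metrics(prof)
        expected = mg_to_nmol(25) / p.cl_f
        assert abs(m.auc_0_24 - expected) / expected < 0.005


def test_one_compartment_accumulation_ratio():
    # q -> 0 with half-life 8 h: trough accumulation follows the geometric
    # series factor 1/(1 - 2^(-tau/t_half))
    t_half, tau = 8.0, 24.0
    vc = 57.7
    cl = np.log(2) / t_half * vc
    p = PKParameters(cl_f=cl, vc_f=vc, vp_f=60.0, q_f=1e-9, ka=1.2, d1=0.5, alag1=0.2)
    single = predict_concentration(p, DosingRegimen(10, tau, 1), np.array([tau]))
    ss = conc_steady_state(p.as_array(), np.array([tau]), tau, mg_to_nmol(10))
    accumulation = ss[0] / single.concentrations[0]
    expected = 1.0 / (1.0 - 2.0 ** (-tau / t_half))
    assert abs(accumulation - expected) / expected < 1e-3


def test_steady_state_simulate_matches_analytic(simple_params):
    reg = DosingRegimen(25, 24, 28)
    a = steady_state_profile(simple_params, reg, 0.05, method="analytic")
    s = steady_state_profile(simple_params, reg, 0.05, method="simulate")
    np.testing.assert_allclose(s.concentrations, a.concentrations, rtol=1e-5)
    # trough at t=0 equals trough at t=tau (definition of steady state)
    assert abs(a.concentrations[0] - a.concentrations[-1]) <= 1e-6 * a.concentrations[0]


def test_single_dose_profile_is_degenerate_steady_state(simple_params):
    t = np.arange(0, 24.0001, 0.05)
    reg1 = DosingRegimen(25, 24, 1)
    direct = predict_concentration(simple_params, reg1, t)
    # one administration: superposition over one dose must equal the plain profile
    ss = conc_once_daily(simple_params.as_array(), t, 1e9, mg_to_nmol(25))
    np.testing.assert_allclose(ss, direct.concentrations, rtol=1e-9, atol=1e-12)


def test_exposure_metrics_rectangle():
    t = np.arange(0, 24.0001, 0.05)
    prof = ConcentrationProfile(times=t, concentrations=np.full_like(t, 100.0))
    m = exposure_metrics(prof)
    assert m.auc_0_24 == pytest.approx(2400.0)
    assert m.cmax == 100.0
    assert m.css == pytest.approx(100.0)
    assert m.tmax == 0.0  # earliest tie wins


def test_exposure_metrics_rejects_bad_grid(simple_params):
    t = np.arange(0, 24.1, 0.2)
    prof = ConcentrationProfile(times=t, concentrations=np.ones_like(t))
    with pytest.raises(ValidationError):
        exposure_metrics(prof)
    short = ConcentrationProfile(times=np.arange(0, 12, 0.05), concentrations=np.ones(240))
    with pytest.raises(ValidationError):
        exposure_metrics(short)


def test_fixture_exposure_anchors(fixture):
    prof = steady_state_profile(fixture.parameters, DosingRegimen(25, 24, 28), 0.05)
    m = exposure_metrics(prof)
    assert 1.0 <= m.tmax <= 2.0
    assert m.cmax >= m.css
    assert 7.0 <= terminal_half_life(fixture.parameters) <= 12.0


def test_half_life_one_compartment_limits():
    p = PKParameters(cl_f=5.0, vc_f=57.7, vp_f=60.0, q_f=1e-9, ka=1.0, d1=0.5, alag1=0.0)
    assert terminal_half_life(p) == pytest.approx(np.log(2) / (5.0 / 57.7), rel=1e-3)
    # degenerate peripheral compartment with q fixed: matches 1-compartment
    p2 = PKParameters(cl_f=5.0, vc_f=57.7, vp_f=1e-4, q_f=8.0, ka=1.0, d1=0.5, alag1=0.0)
    assert terminal_half_life(p2) == pytest.approx(np.log(2) / (5.0 / 57.7), rel=0.01)


def test_agrees_with_ode_oracle():
    rng = np.random.default_rng(7)
    t = np.linspace(0.05, 48, 160)
    for p in random_params(rng, 20):
        reg = DosingRegimen(25, 24, 2)
        closed = predict_concentration(p, reg, t).concentrations
        ode, _ = ode_profile(p, mg_to_nmol(25), [0.0, 24.0], t)
        assert np.max(np.abs(closed - ode)) <= 1e-3 * np.max(ode)


def test_mass_balance_single_dose():
    rng = np.random.default_rng(11)
    t = np.linspace(0.25, 36, 40)
    for p in random_params(rng, 5):
        dose = mg_to_nmol(25)
        _, amounts = ode_profile(p, dose, [0.0], t)
        released = np.clip(t - p.alag1, 0.0, p.d1) / p.d1 * dose
        unreleased = dose - released
        total = unreleased + amounts.sum(axis=0)
        np.testing.assert_allclose(total, dose, rtol=1e-3)


def test_fast_kernel_matches_reference(population):
    rng = np.random.default_rng(3)
    th = population.reference.as_array() * np.exp(rng.normal(0, 0.25, (6, 7)))
    th[:, 5] = np.clip(th[:, 5], 0.1, 3)
    th[:, 6] = np.clip(th[:, 6], 0.0, 1)
    t = np.broadcast_to(np.array([0.5, 1.4, 4.0, 8.0, 168.0, 507.0]), (6, 6))
    a = conc_once_daily(th, t, 24.0, 1e5)
    b = conc_once_daily_fast(th, t, 24.0, 1e5)
    np.testing.assert_allclose(b, a, rtol=1e-12)


def test_parameter_validation():
    with pytest.raises(ValidationError):
        PKParameters(cl_f=-1, vc_f=30, vp_f=60, q_f=10, ka=1.5, d1=1.5, alag1=0.5)
    with pytest.raises(ValidationError):
        PKParameters(cl_f=np.nan, vc_f=30, vp_f=60, q_f=10, ka=1.5, d1=1.5, alag1=0.5)
    with pytest.raises(ValidationError):
        DosingRegimen(dose_mg=0)
    p = PKParameters(cl_f=10, vc_f=30, vp_f=60, q_f=10, ka=1.5, d1=1.5, alag1=0.5)
    with pytest.raises(ValidationError):
        predict_concentration(p, DosingRegimen(25), np.array([2.0, 1.0]))
    with pytest.raises(ValidationError):
        steady_state_profile(p, DosingRegimen(25), grid_step=0.5)
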