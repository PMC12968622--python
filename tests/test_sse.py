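"""Simulation-re-estimation: dataset handling, Laplace fit, replicates."""

import numpy as np
import pandas as pd
import pytest

from empabridge import PopulationSpec, ValidationError, load_scenario
from empabridge.fixtures import SamplingGroup
from empabridge.model import conc_after_doses
from empabridge.params import OmegaSpec, PKParameters, ResidualSpec, mg_to_nmol
from empabridge.sse import (
    FitOptions,
    PriorSpec,
    TrialDataset,
    fit_model,
    laplace_ofv,
    read_nonmem_csv,
    run_sse,
    simulate_trial,
    summarise_sse,
    write_nonmem_csv,
)

from oracles import gh_marginal_ofv


def _noise_free_population(fixture, sigma=1e-3):
    return PopulationSpec(reference=fixture.parameters, allometry=fixture.allometry,
                         omega=OmegaSpec(), residual=ResidualSpec(sigma))


def test_simulate_noise_free_equals_typical(fixture):
    pop = PopulationSpec(reference=fixture.parameters, allometry=fixture.allometry,
                        omega=OmegaSpec(), residual=ResidualSpec(0.0))
    design = load_scenario("3")
    data = simulate_trial(design, pop, cohort_seed=1, residual_seed=2)
    obs = data.frame[data.frame["EVID"] == 0]
    times = np.array(design.groups[0].times)
    from empabridge.cohort import scale_parameter_array

    for sid, grp in obs.groupby("ID"):
        theta = scale_parameter_array(pop.reference, np.array([grp["WT"].iloc[0]]), pop.allometry)
        doses = np.arange(int(times.max() // 24) + 1) * 24.0
        f = conc_after_doses(theta, times, doses, mg_to_nmol(design.dose_mg))[0]
        np.testing.assert_allclose(grp["DV"].to_numpy(), f, rtol=1e-10)


def test_simulate_scenario6_structure(population):
    data = simulate_trial(load_scenario("6"), population, cohort_seed=3, residual_seed=4)
    obs = data.frame[data.frame["EVID"] == 0]
    counts = obs.groupby("ID").size().to_numpy()
    # 6 samples at Visit 1 plus Visit 2 for everyone; Visit 3 in half
    v1 = obs[obs["TIME"] <= 8.0].groupby("ID").size()
    assert (v1 == 6).all()
    assert (counts == 8).sum() == 6 and (counts == 7).sum() == 6
    v3 = obs[obs["TIME"] > 400].groupby("ID").size()
    assert len(v3) == 6


def test_simulate_reproducible_bitwise(population):
    a = simulate_trial(load_scenario("4"), population, cohort_seed=10, residual_seed=20)
    b = simulate_trial(load_scenario("4"), population, cohort_seed=10, residual_seed=20)
    pd.testing.assert_frame_equal(a.frame, b.frame)


def test_nonmem_csv_round_trip(population, tmp_path):
    data = simulate_trial(load_scenario("6"), population, cohort_seed=5, residual_seed=6)
    path = tmp_path / "trial.csv"
    write_nonmem_csv(data, path)
    back = read_nonmem_csv(path)
    pd.testing.assert_frame_equal(back.frame, data.frame[list(back.frame.columns)])
    # bit-exact DV round trip
    assert np.array_equal(back.frame["DV"].to_numpy(), data.frame["DV"].to_numpy())


def test_dataset_validation():
    bad = pd.DataFrame({
        "ID": [1, 1], "TIME": [0.0, 1.0], "EVID": [0, 1], "AMT": [0.0, 10.0],
        "DV": [5.0, 0.0], "MDV": [0, 1], "WT": [40.0, 40.0],
    })
    with pytest.raises(ValidationError, match="dose record"):
        TrialDataset(bad)
    with pytest.raises(ValidationError, match="columns"):
        TrialDataset(pd.DataFrame({"ID": [1]}))


def test_fit_recovers_noise_free_truth(fixture):
    # no IIV, near-zero residual noise, rich design: fixed effects to < 1%
    pop = _noise_free_population(fixture)
    design = load_scenario("1")
    data = simulate_trial(design, pop, cohort_seed=7, residual_seed=8)
    init = PopulationSpec(
        reference=fixture.parameters.replace(cl_f=fixture.parameters.cl_f * 1.3,
                                             vc_f=fixture.parameters.vc_f * 0.8),
        allometry=fixture.allometry, omega=OmegaSpec(), residual=ResidualSpec(1e-3),
    )
    fit = fit_model(data, init, options=FitOptions(estimate_omega=()))
    true = pop.reference.as_array()
    for i, name in enumerate(("cl_f", "vc_f", "vp_f", "q_f")):
        assert fit.fixed_effects[name] == pytest.approx(true[i], rel=0.01), name


def test_informative_prior_dominates_sparse_data(fixture, population):
    design = load_scenario("3")
    data = simulate_trial(design, population, cohort_seed=9, residual_seed=10)
    center = {n: getattr(population.reference, n) * 1.15 for n in ("cl_f", "vc_f", "vp_f", "q_f")}
    prior = PriorSpec(mode="informative", center=center,
                      sd={n: 1e-3 for n in center})
    fit = fit_model(data, population, prior=prior)
    for name, c in center.items():
        assert fit.fixed_effects[name] == pytest.approx(c, rel=0.01)


def test_prior_continuity_to_noninformative(fixture, population):
    design = load_scenario("3")
    small = design.with_groups([SamplingGroup(4, design.groups[0].times)])
    data = simulate_trial(small, population, cohort_seed=13, residual_seed=14)
    loose = PriorSpec(mode="informative", default_sd=1e4)
    f_loose = fit_model(data, population, prior=loose)
    f_non = fit_model(data, population)
    # subtract the (negligible) penalty at the optimum before comparing
    assert abs(f_loose.ofv - f_non.ofv) < 0.1


def test_laplace_matches_gauss_hermite_on_1cpt_reduction(fixture):
    # near one-compartment truth, IIV on CL only: Laplace vs adaptive GH
    ref = PKParameters(cl_f=10.0, vc_f=50.0, vp_f=0.5, q_f=0.05, ka=1.5, d1=1.0, alag1=0.25)
    pop = PopulationSpec(reference=ref, allometry=fixture.allometry,
                        omega=OmegaSpec(cl_f=0.0625), residual=ResidualSpec(0.15))
    design = load_scenario("3").with_groups(
        [SamplingGroup(2, (1.0, 4.0, 8.0, 24.0))]
    )
    data = simulate_trial(design, pop, cohort_seed=15, residual_seed=16)
    options = FitOptions()
    ofv_laplace = laplace_ofv(data, pop, options=options)

    obs = data.frame[data.frame["EVID"] == 0]
    from empabridge.cohort import scale_parameter_array

    times, ys, thetas = [], [], []
    for sid, grp in obs.groupby("ID"):
        times.append(grp["TIME"].to_numpy())
        ys.append(grp["DV"].to_numpy())
        thetas.append(scale_parameter_array(ref, np.array([grp["WT"].iloc[0]]), pop.allometry)[0])
    ofv_gh = gh_marginal_ofv(ys, times, np.array(thetas), cl_index=0,
                             omega2_cl=0.0625, sigma2=0.15**2, tau=24.0,
                             dose_nmol=mg_to_nmol(design.dose_mg))
    assert abs(ofv_laplace - ofv_gh) < 0.5


def test_run_sse_deterministic_and_deterministic_limit(population, fixture):
    design = load_scenario("3").with_groups([SamplingGroup(3, load_scenario("3").groups[0].times)])
    a = run_sse(design, population, n_replicates=2, base_seed=77)
    b = run_sse(design, population, n_replicates=2, base_seed=77)
    pd.testing.assert_frame_equal(a.replicates, b.replicates)

    # sigma ~ 0, omega = 0, rich design, one replicate: ratios ~ 1
    pop0 = _noise_free_population(fixture)
    rich = load_scenario("1").with_groups([SamplingGroup(4, load_scenario("1").groups[0].times)])
    res = run_sse(rich, pop0, n_replicates=1, base_seed=5,
                  options=FitOptions(estimate_omega=()))
    assert res.n_converged == 1
    vals = res.replicates.iloc[0]
    for col in ("ratio_cl_f", "ratio_vc_f", "ratio_vp_f", "ratio_q_f", "ratio_auc"):
        assert vals[col] == pytest.approx(1.0, abs=0.01), col


def test_smaller_sample_size_widens_iqr(population, sse_scenario6):
    # scenario 6 reduced to 4 subjects (1 per sampling group): IQRs widen
    s6 = load_scenario("6")
    reduced = s6.with_groups([SamplingGroup(1, g.times) for g in s6.groups])
    small = run_sse(reduced, population, n_replicates=30, base_seed=20240303)
    full_summary = sse_scenario6.summary.set_index("quantity")
    small_summary = small.summary.set_index("quantity")
    wider = 0
    for q in full_summary.index:
        iqr_small = small_summary.loc[q, "q75"] - small_summary.loc[q, "q25"]
        iqr_full = full_summary.loc[q, "q75"] - full_summary.loc[q, "q25"]
        wider += iqr_small > iqr_full
    assert wider >= 1  # precision degrades with fewer subjects


def test_summarise_sse_single_and_ranking(sse_scenario6):
    table = summarise_sse([sse_scenario6])
    med = table.set_index("quantity")["median"]
    ref = sse_scenario6.summary.set_index("quantity")["median"]
    pd.testing.assert_series_equal(med, ref, check_names=False)
    # identical results twice: deterministic ranking, tie broken by id
    two = summarise_sse([sse_scenario6, sse_scenario6])
    assert set(two["rank"]) == {1}  # same id -> same rank key
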