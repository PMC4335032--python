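import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erfcx

from matchnet import meanfield as mf
from matchnet import load_parameters

P = load_parameters()
LIF_ARGS = dict(tau_m=P.tau_E, theta=P.theta, V_R=P.V_R, tau_arp=P.tau_arp)


# --------------------------------------------------------------------------
# Transfer function
# --------------------------------------------------------------------------

def test_phi_saturates_at_inverse_refractory_period():
    assert mf.phi_transfer(1e7, 0.75, **LIF_ARGS) == pytest.approx(400.0, rel=1e-3)
    assert mf.phi_transfer(0.0, 0.75, **LIF_ARGS) < 1e-12


def test_phi_matches_adaptive_quadrature():
    for mu in (15.0, 18.0, 21.0, 25.0, 40.0):
        a, b = (P.theta - mu) / 0.75, (P.V_R - mu) / 0.75
        integral, _ = quad(lambda u: np.sqrt(np.pi) * erfcx(-u), b, a, limit=200)
        ref = 1.0 / (P.tau_arp + P.tau_E * integral)
        assert mf.phi_transfer(mu, 0.75, **LIF_ARGS) == pytest.approx(ref, rel=1e-12)


@given(st.floats(-5, 35), st.floats(0.01, 20.0))
@settings(max_examples=60, deadline=None)
def test_phi_strictly_increasing_and_bounded(mu, dmu):
    lo = mf.phi_transfer(mu, 0.75, **LIF_ARGS)
    hi = mf.phi_transfer(mu + dmu, 0.75, **LIF_ARGS)
    assert 0.0 <= lo <= hi <= 400.0
    if hi > 1e-10:          # both representable: strictly increasing
        assert lo < hi


def test_phi_rejects_nonpositive_sigma():
    with pytest.raises(ValueError):
        mf.phi_transfer(20.0, 0.0, **LIF_ARGS)


# --------------------------------------------------------------------------
# Quenched averaging
# --------------------------------------------------------------------------

def test_quenched_average_degenerates_without_background_spread():
    a = mf.quenched_average_rate(-2.0, 21.0, 0.0, 0.75, **LIF_ARGS)
    b = mf.phi_transfer(19.0, 0.75, **LIF_ARGS)
    assert a == pytest.approx(b, rel=1e-14)


@pytest.mark.parametrize("mu_rec, mu_ext", [(-2.4, 19.87), (0.0, 18.0), (2.0, 17.0)])
def test_quenched_average_matches_adaptive_quadrature(mu_rec, mu_ext):
    def integrand(x):
        return (np.exp(-(x - mu_ext) ** 2 / 2.0) / np.sqrt(2 * np.pi)
                * mf.phi_transfer(mu_rec + x, 0.75, **LIF_ARGS))

    ref, _ = quad(integrand, mu_ext - 12, mu_ext + 12, limit=400,
                  epsabs=1e-14, epsrel=1e-13)
    ours = mf.quenched_average_rate(mu_rec, mu_ext, 1.0, 0.75, **LIF_ARGS)
    assert ours == pytest.approx(ref, abs=1e-10)


def test_phibar_table_matches_direct_quadrature(cal):
    tab = mf.PhiBarTable(cal, cal.tau_E, lo=-5.0, hi=40.0)
    mus = np.linspace(-4.0, 39.0, 301)
    direct = mf.quenched_average_rate(0.0, mus, cal.sigma_BG, cal.sigma,
                                      cal.tau_E, cal.theta, cal.V_R, cal.tau_arp)
    assert np.max(np.abs(tab(mus) - direct)) < 1e-7
    # out-of-range inputs fall back to direct quadrature
    assert tab(50.0) == pytest.approx(
        mf.quenched_average_rate(0.0, 50.0, cal.sigma_BG, cal.sigma,
                                 cal.tau_E, cal.theta, cal.V_R, cal.tau_arp))


# --------------------------------------------------------------------------
# Recurrent currents
# --------------------------------------------------------------------------

def test_recurrent_currents_vanish_at_zero_rates(params):
    rates = np.zeros(params.p + 2)
    assert np.allclose(mf.recurrent_currents_spontaneous(rates, params), 0.0)
    assert np.allclose(mf.recurrent_currents_delay(np.zeros(4), params), 0.0)


def test_selective_vs_nonselective_current_identity(params):
    """With all excitatory rates equal to nu, the selective and non-selective
    currents differ by (g+ - g-) * f * N_E * J_EE * tau_E * nu * 0 — i.e. are
    equal, by the balance constraint. With distinct rates the difference is
    (g+ - g-) * f * N_E * J_EE * tau_E * (nu_k - weighted background)."""
    nu = 1.3
    rates = np.array([nu] * (params.p + 1) + [5.0])
    mu = mf.recurrent_currents_spontaneous(rates, params)
    assert mu[0] == pytest.approx(mu[params.p], rel=1e-12)
    # asymmetric case: direct algebraic evaluation
    sel = np.array([3.0, 1.0, 1.0, 1.0, 1.0, 1.0])
    rates = np.concatenate([sel, [1.0, 5.0]])
    mu = mf.recurrent_currents_spontaneous(rates, params)
    k = params.N_E * params.J_EE * params.tau_E
    expected0 = k * (params.f * params.g_plus * 3.0
                     + params.f * params.g_minus * 5.0
                     + (1 - params.p * params.f) * params.g_minus * 1.0) \
        - params.N_I * params.J_EI * params.tau_E * 5.0
    assert mu[0] == pytest.approx(expected0, rel=1e-12)


def test_delay_foreground_current_formula(params):
    rates = np.array([40.0, 0.5, 0.7, 9.0])
    mu = mf.recurrent_currents_delay(rates, params, gamma=1)
    q = params
    k = q.N_E * q.J_EE * q.tau_E
    expected_sf = k * (q.f * 40.0 * q.g_plus + q.f * 0.5 * (q.p - 1) * q.g_minus
                       + (1 - q.p * q.f) * q.g_minus * 0.7) \
        - q.N_I * q.J_EI * q.tau_E * 9.0
    assert mu[0] == pytest.approx(expected_sf, rel=1e-12)


def test_delay_structure_consistent_with_full_structure(params):
    """The 4-population delay currents are the p+2 currents with the
    selective rates grouped as (sf, sb, ..., sb)."""
    sf, sb, ns, inh = 40.0, 0.4, 0.8, 9.0
    delay = mf.recurrent_currents_delay(np.array([sf, sb, ns, inh]), params)
    full = mf.recurrent_currents_spontaneous(
        np.array([sf] + [sb] * (params.p - 1) + [ns, inh]), params)
    assert delay[0] == pytest.approx(full[0], rel=1e-12)
    assert delay[1] == pytest.approx(full[1], rel=1e-12)
    assert delay[2:] == pytest.approx(full[params.p:], rel=1e-12)


# --------------------------------------------------------------------------
# Calibration and fixed points
# --------------------------------------------------------------------------

def test_calibration_hits_target_rates(cal):
    sol = mf.solve_spontaneous(cal)
    rates = sol.rate_vector()
    assert np.allclose(rates[:-1], cal.nu_E_sp, atol=1e-6)
    assert rates[-1] == pytest.approx(cal.nu_I_sp, abs=1e-6)
    assert sol.residual_norm < 1e-8
    assert sol.stable


def test_calibration_invariant_under_j_plus(params, cal):
    """The balance constraint keeps the spontaneous calibration independent
    of the potentiation level."""
    for jp in (0.05, 0.10, 0.156):
        mu_E, mu_I = mf.calibrate_external_currents(params.replace(J_plus=jp))
        assert mu_E == pytest.approx(cal.mu_ext_E, abs=1e-6)
        assert mu_I == pytest.approx(cal.mu_ext_I, abs=1e-6)


def test_calibration_inverts_transfer_function_without_spread(params):
    """With sigma_BG = 0 the calibrated current solves Phi(mu_rec + mu) =
    target; cross-check by direct bracketing inversion."""
    q = params.replace(sigma_BG=0.0)
    mu_E, mu_I = mf.calibrate_external_currents(q)
    rates = np.array([q.nu_E_sp] * (q.p + 1) + [q.nu_I_sp])
    mu_rec = mf.recurrent_currents_spontaneous(rates, q)

    ref_E = brentq(lambda x: mf.phi_transfer(mu_rec[0] + x, q.sigma, **LIF_ARGS)
                   - q.nu_E_sp, 10.0, 30.0, xtol=1e-12)
    ref_I = brentq(lambda x: mf.phi_transfer(
        mu_rec[-1] + x, q.sigma, q.tau_I, q.theta, q.V_R, q.tau_arp)
        - q.nu_I_sp, 10.0, 30.0, xtol=1e-12)
    assert mu_E == pytest.approx(ref_E, abs=1e-8)
    assert mu_I == pytest.approx(ref_I, abs=1e-8)


def test_uncalibrated_parameters_raise(params):
    with pytest.raises(mf.SolverError, match="uncalibrated"):
        mf.solve_spontaneous(params)


def test_memory_state_exists_at_canonical_potentiation(cal):
    sol = mf.solve_delay_state(cal)
    assert sol.branch == "memory"
    assert sol.rates["sf"] > 20.0
    assert sol.rates["sb"] < cal.nu_E_sp
    assert sol.residual_norm < 1e-8


def test_unstructured_network_has_no_memory_state(cal):
    sol = mf.solve_delay_state(cal.replace(J_plus=cal.J_EE))
    assert sol.branch == "spontaneous"
    assert sol.rates["sf"] == pytest.approx(cal.nu_E_sp, abs=1e-5)


def test_spontaneous_solution_consistent_across_parameterizations(cal):
    """The delay-system spontaneous fixed point (sf = sb) equals the p+2
    spontaneous solution."""
    full = mf.solve_spontaneous(cal)
    four = mf.solve_delay_state(
        cal, initial_guess=np.array([cal.nu_E_sp] * 3 + [cal.nu_I_sp]))
    assert four.rates["sf"] == pytest.approx(four.rates["sb"], abs=1e-8)
    assert four.rates["sf"] == pytest.approx(full.rates["sel_1"], abs=1e-6)
    assert four.rates["inh"] == pytest.approx(full.rates["inh"], abs=1e-6)


def test_converged_solutions_satisfy_self_consistency_independently(cal):
    """Re-evaluate the fixed-point map from scratch at the solver's output."""
    for sol in (mf.solve_spontaneous(cal), mf.solve_delay_state(cal)):
        rates = sol.rate_vector()
        if len(rates) == 4:
            mu_rec = mf.recurrent_currents_delay(rates, cal)
            mu_ext = np.array([cal.mu_ext_E] * 3 + [cal.mu_ext_I])
        else:
            mu_rec = mf.recurrent_currents_spontaneous(rates, cal)
            mu_ext = np.array([cal.mu_ext_E] * (cal.p + 1) + [cal.mu_ext_I])
        again = mf.population_rates(cal, mu_rec, mu_ext)
        assert np.max(np.abs(again - rates)) < 1e-8


def test_critical_j_plus_bisection_matches_grid_scan(cal):
    jc = mf.find_critical_j_plus(cal, tol=1e-5)
    assert cal.J_EE < jc < cal.J_plus
    # dense grid around the bisection result: memory absent below, present above
    grid = np.arange(jc - 5e-4, jc + 5e-4, 1e-4)
    present = [mf._memory_solution(cal.replace(J_plus=float(j))) is not None
               for j in grid]
    assert present == sorted(present)         # single transition
    lo = max(j for j, ok in zip(grid, present) if not ok)
    hi = min(j for j, ok in zip(grid, present) if ok)
    assert lo < jc <= hi + 1e-4


def test_bifurcation_scan_branch_structure(cal, bifurcation):
    branch = bifurcation
    mem = branch.memory_rates()
    have = ~np.isnan(mem)
    # memory branch appears above a critical potentiation inside the grid
    assert not have[0] and have[-1]
    assert branch.critical_j_plus == pytest.approx(0.1419, abs=2e-3)
    # foreground memory rate increases with J_plus
    rates = mem[have]
    assert np.all(np.diff(rates) > 0)
    # inhibitory rate on the memory branch exceeds its spontaneous value
    for s, m in zip(branch.spontaneous, branch.memory):
        if m is not None:
            assert m.rates["inh"] > s.rates["inh"]
    # where found, the unstable solution lies between the stable branches
    n_unstable = 0
    for m, u, s in zip(branch.memory, branch.unstable, branch.spontaneous):
        if u is not None:
            n_unstable += 1
            assert not u.stable
            assert s.rates["sf"] < u.rates["sf"] < m.rates["sf"]
    assert n_unstable > 0
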