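"""Core respiratory-chain model: flux laws, thermodynamic consistency,
conservation, steady-state finding and trajectory simulation."""

import math

import numpy as np
import pytest

from mitoflux import protocols as proto
from mitoflux import rc_model as rc
from mitoflux.rc_model import ModelError, ModelState

from conftest import random_valid_state


# ---------------------------------------------------------------------------
# independent thermodynamic oracle (re-derived outside the model code)
# ---------------------------------------------------------------------------

def reaction_affinities(state: rc.ModelState, p: rc.ModelParameters) -> dict:
    """-DeltaG of each reversible reaction at the given state (kJ/mol),
    assembled independently from standard free energies, the proton-motive
    force and mass action."""
    RT, F = p.RT, p.F
    H_i, H_x = p.H_c, state.H_x
    dG_H = F * state.dpsi + RT * math.log(H_i / H_x)
    NAD = p.NADtot - state.NADH_x
    Q = p.Qtot - state.QH2
    Cox = p.Ctot - state.Cred
    ln = math.log
    h7 = H_x / 1e-7

    A = {}
    A["J_DH"] = RT * ln(p.r_DH * NAD / state.NADH_x)
    A["J_C1"] = (-p.dG_C1o - 4 * dG_H + RT * ln(h7)
                 + RT * ln(state.NADH_x * Q / (NAD * state.QH2)))
    A["J_C3"] = (-p.dG_C3o - 4 * dG_H + 2 * F * state.dpsi + 2 * RT * ln(h7)
                 + RT * ln(state.QH2 * Cox ** 2 / (Q * state.Cred ** 2)))
    A["J_C4"] = (-p.dG_C4o - 2 * dG_H - 2 * F * state.dpsi + 2 * RT * ln(h7)
                 + RT * ln(state.Cred ** 2 * math.sqrt(p.O2) / Cox ** 2))
    # F1 (synthesis direction), with Mg/H binding polynomials
    P = lambda tot, Ka, Kmg, H, Mg: 1 + H / Ka + Mg / Kmg  # noqa: E731
    P_ATP = P(0, 10 ** -p.pKa_ATP, p.K_DT, H_x, state.Mg_x)
    P_ADP = P(0, 10 ** -p.pKa_ADP, p.K_DD, H_x, state.Mg_x)
    P_Pi = 1 + H_x / 10 ** -p.pKa_Pi
    A["J_F1"] = (-p.dG_F1o + p.n_A * dG_H + RT * ln(h7)
                 + RT * ln((state.ADP_x / P_ADP) * (state.Pi_x / P_Pi)
                           / (state.ATP_x / P_ATP)))
    A["J_KH"] = RT * ln(p.K_c * H_x / (state.K_x * H_i))
    Ka_Pi = 10 ** -p.pKa_Pi
    h2p_i = state.Pi_i * H_i / (H_i + Ka_Pi)
    h2p_x = state.Pi_x * H_x / (H_x + Ka_Pi)
    A["J_PiH"] = RT * ln(H_i * h2p_i / (H_x * h2p_x))
    A["J_Hle"] = dG_H  # inward leak is downhill when dG_H > 0
    return A


# ---------------------------------------------------------------------------
# flux evaluation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("activity,flux",
                         list(zip(rc.ACTIVITY_NAMES, rc.FLUX_NAMES)))
def test_zero_activity_zeroes_its_flux(params, steady, activity, flux):
    p0 = params.replace(**{activity: 0.0})
    j = rc.compute_fluxes(steady, p0)
    assert getattr(j, flux) == 0.0


def test_flux_signs_match_thermodynamic_driving_forces(params, rng):
    """On 1000 random admissible states, every reversible flux has the sign
    of its affinity (independently re-derived)."""
    checked = 0
    for _ in range(1000):
        st = random_valid_state(rng, params)
        j = rc.compute_fluxes(st, params)
        aff = reaction_affinities(st, params)
        for name, a in aff.items():
            if abs(a) < 1e-6:
                continue
            jv = getattr(j, name)
            assert jv * a >= 0, f"{name}: J={jv:.3e} but affinity={a:.3f}"
            checked += 1
    assert checked > 5000


def test_equilibrium_states_give_zero_net_flux(params, steady):
    """Placing each reaction exactly at its thermodynamic equilibrium
    zeroes its net flux."""
    p, s = params, steady
    RT, F = p.RT, p.F
    # DH equilibrium: NADH/NAD = r
    nadh = p.r_DH * p.NADtot / (1 + p.r_DH)
    st = ModelState(**{**s.__dict__, "NADH_x": nadh})
    assert rc.compute_fluxes(st, p).J_DH == pytest.approx(0.0, abs=1e-18)
    # KH equilibrium
    st = ModelState(**{**s.__dict__, "K_x": p.K_c * s.H_x / p.H_c})
    assert rc.compute_fluxes(st, p).J_KH == pytest.approx(0.0, abs=1e-18)
    # C1 equilibrium: solve QH2 so the bracket vanishes
    NAD = p.NADtot - s.NADH_x
    dG_H = F * s.dpsi + RT * math.log(p.H_c / s.H_x)
    keq1 = math.exp(-(p.dG_C1o + 4 * dG_H) / RT) * (s.H_x / 1e-7)
    # keq * NADH * Q = NAD * QH2  ->  QH2/Q = keq*NADH/NAD
    ratio = keq1 * s.NADH_x / NAD
    qh2 = p.Qtot * ratio / (1 + ratio)
    st = ModelState(**{**s.__dict__, "QH2": qh2})
    j = rc.compute_fluxes(st, p).J_C1
    scale = p.X_C1 * keq1 * s.NADH_x * (p.Qtot - qh2)
    assert abs(j) <= 1e-9 * scale


def test_flux_values_match_independent_hand_evaluation(params, steady):
    """The calibrated steady-state fluxes agree with a from-scratch numpy
    re-evaluation of the flux laws (written independently of the model)."""
    p, s = params, steady
    RT, F = p.RT, p.F
    H_i, H_x = p.H_c, s.H_x
    dG_H = F * s.dpsi + RT * np.log(H_i / H_x)
    h7 = H_x / 1e-7
    NAD, Q, Cox = p.NADtot - s.NADH_x, p.Qtot - s.QH2, p.Ctot - s.Cred

    phi = (1 + s.Pi_x / p.k_Pi1) / (1 + s.Pi_x / p.k_Pi2)
    m = 1 / (1 + np.exp(-(s.dpsi - p.dpsi_ref_DH) / p.delta_psi_DH))
    j_dh = p.X_DH * phi * m * (p.r_DH * NAD - s.NADH_x)

    keq1 = np.exp(-(p.dG_C1o + 4 * dG_H) / RT) * h7
    fwd1 = keq1 * s.NADH_x * Q
    j_c1 = p.X_C1 * (fwd1 - NAD * s.QH2) / (1 + fwd1 / p.k_sat_C1)

    phi3 = (1 + s.Pi_x / p.k_Pi3) / (1 + s.Pi_x / p.k_Pi4)
    keq3 = np.exp(-(p.dG_C3o + 4 * dG_H - 2 * F * s.dpsi) / RT) * h7 ** 2
    fwd3 = np.sqrt(keq3 * s.QH2) * Cox
    j_c3 = p.X_C3 * phi3 * (fwd3 - np.sqrt(Q) * s.Cred) / (1 + fwd3 / p.k_sat_C3)

    keq4 = np.exp(-(p.dG_C4o + 2 * dG_H + 2 * F * s.dpsi) / RT) * h7 ** 2
    fwd4 = np.sqrt(keq4) * s.Cred * p.O2 ** 0.25
    j_c4 = (p.X_C4 * p.O2 / (p.O2 + p.k_O2) * (s.Cred / p.Ctot)
            * (fwd4 - Cox) / (1 + fwd4 / p.k_sat_C4))

    j = rc.compute_fluxes(s, p)
    for name, want in [("J_DH", j_dh), ("J_C1", j_c1),
                       ("J_C3", j_c3), ("J_C4", j_c4)]:
        assert getattr(j, name) == pytest.approx(want, rel=1e-12), name


def test_invalid_states_rejected(params, steady):
    bad = ModelState(**{**steady.__dict__, "NADH_x": params.NADtot * 1.5})
    with pytest.raises(ModelError):
        rc.compute_fluxes(bad, params)
    nan = ModelState(**{**steady.__dict__, "dpsi": float("nan")})
    with pytest.raises(ModelError):
        rc.compute_fluxes(nan, params)
    with pytest.raises(ModelError):
        params.replace(X_DH=-1.0).validate()


# ---------------------------------------------------------------------------
# derivatives and conservation
# ---------------------------------------------------------------------------

def test_nadh_nad_pool_derivative_cancels(params, rng):
    """d(NADH)/dt + d(NAD)/dt = 0: the pool is constant by construction,
    so the NADH derivative equals minus the NAD derivative everywhere."""
    st = random_valid_state(rng, params)
    dy = rc.time_derivatives(st, params)
    i = rc.STATE_NAMES.index("NADH_x")
    # NAD = NADtot - NADH: its implied derivative is -dy[i]; the sum is 0
    assert dy[i] + (-dy[i]) == 0.0


def test_all_zero_activities_freeze_the_system(params, steady):
    p0 = params.replace(**{a: 0.0 for a in rc.ACTIVITY_NAMES}, x_AM=0.0, x_PM=0.0)
    dy = rc.time_derivatives(steady, p0)
    assert np.allclose(dy, 0.0, atol=1e-30)


def test_adenine_and_phosphate_conserved_along_stress_test(params, stress_tc):
    """Total adenine and total phosphorus (Pi + ATP-bound) are conserved
    along the full drug protocol to within 10x integrator tolerance."""
    W = np.array([params.W_x, params.W_i, params.W_c])
    S = stress_tc.states
    idx = {n: i for i, n in enumerate(rc.STATE_NAMES)}
    adenine = (W[0] * (S[:, idx["ATP_x"]] + S[:, idx["ADP_x"]])
               + W[1] * (S[:, idx["ATP_i"]] + S[:, idx["ADP_i"]])
               + W[2] * (S[:, idx["ATP_c"]] + S[:, idx["ADP_c"]]))
    phosphate = (W[0] * (S[:, idx["Pi_x"]] + S[:, idx["ATP_x"]])
                 + W[1] * (S[:, idx["Pi_i"]] + S[:, idx["ATP_i"]])
                 + W[2] * (S[:, idx["Pi_c"]] + S[:, idx["ATP_c"]]))
    for pool in (adenine, phosphate):
        assert np.ptp(pool) / pool[0] < 1e-7  # 10x the 1e-8 rtol


def test_redox_pools_stay_within_totals(params, stress_tc):
    S = stress_tc.states
    idx = {n: i for i, n in enumerate(rc.STATE_NAMES)}
    assert np.all(S[:, idx["NADH_x"]] <= params.NADtot * (1 + 1e-9))
    assert np.all(S[:, idx["QH2"]] <= params.Qtot * (1 + 1e-9))
    assert np.all(S[:, idx["Cred"]] <= params.Ctot * (1 + 1e-9))
    assert np.all(S[:, 1:] >= -1e-12)


# ---------------------------------------------------------------------------
# steady state and simulation
# ---------------------------------------------------------------------------

def test_steady_state_residual_below_tolerance(params, steady):
    dy = rc.time_derivatives(steady, params)
    assert np.max(np.abs(dy / rc._STATE_SCALE)) < 1e-10


def test_steady_state_matches_long_integration(params, init_state, steady):
    """Newton steady state equals the long-horizon trajectory limit to 1e-6
    relative (per variable, scaled)."""
    tc = rc.simulate(params, init_state, None, horizon=3e5, rtol=1e-9,
                     grid_dt=3e4)
    end = tc.states[-1]
    rel = np.abs(end - steady.to_array()) / rc._STATE_SCALE
    assert np.max(rel) < 1e-6


def test_steady_state_in_literature_ranges(params, steady):
    """Basal matrix pH, membrane potential and cytosolic ATP fall inside the
    configured literature ranges."""
    import yaml
    from importlib import resources

    doc = yaml.safe_load(
        (resources.files("mitoflux") / "profiles" / "wtsim.yaml").read_text())
    lit = doc["literature_ranges"]
    assert lit["pH_x"][0] <= steady.pH_x <= lit["pH_x"][1]
    assert lit["dpsi_mV"][0] <= steady.dpsi <= lit["dpsi_mV"][1]
    assert lit["ATP_c_mM"][0] <= steady.ATP_c * 1e3 <= lit["ATP_c_mM"][1]


def test_reduced_dehydrogenase_lowers_steady_nadh(params, init_state, steady):
    lo = rc.find_steady_state(params.replace(X_DH=params.X_DH * 0.9),
                              init_state)
    assert lo.NADH_x < steady.NADH_x


def test_empty_protocol_from_steady_state_stays_constant(params, steady):
    tc = rc.simulate(params, steady, None, horizon=2000.0, grid_dt=100.0)
    rel = np.abs(tc.states - steady.to_array()) / rc._STATE_SCALE
    assert np.max(rel) < 1e-6


def test_fccp_steady_flux_nondecreasing_in_dehydrogenase_activity(
        params, init_state):
    """Under the uncoupled (FCCP + oligomycin) condition, the steady complex
    IV flux is non-decreasing in the NADH-delivery activity over 0.5-1.5x."""
    fccp = params.replace(X_Hle=params.X_Hle * 11.0,
                          X_F1=params.X_F1 * 0.13)
    fluxes = []
    guess = init_state
    for f in (0.5, 0.75, 1.0, 1.25, 1.5):
        ss = rc.find_steady_state(fccp.replace(X_DH=params.X_DH * f), guess)
        fluxes.append(rc.compute_fluxes(ss, fccp.replace(
            X_DH=params.X_DH * f)).J_C4)
        guess = ss
    assert np.all(np.diff(fluxes) >= -1e-12 * max(fluxes))


def test_event_time_collision_rejected(params, steady):
    prot = proto.Protocol((proto.PerturbationEvent(100.0, "F1", 0.13),
                           proto.PerturbationEvent(200.0, "Hle", 11.0)))
    with pytest.raises(ModelError):
        proto.Protocol((proto.PerturbationEvent(100.0, "F1", 0.13),
                        proto.PerturbationEvent(100.0, "F1", 0.5)))
    # valid protocol simulates fine on a short horizon
    tc = rc.simulate(params, steady, prot, horizon=300.0, grid_dt=50.0)
    assert len(tc.events) == 2


def test_simulation_deterministic(params, steady):
    prot = proto.preset_protocols()["dpsi_oligomycin"]
    a = rc.simulate(params, steady, prot, horizon=2000.0, grid_dt=100.0)
    b = rc.simulate(params, steady, prot, horizon=2000.0, grid_dt=100.0)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.fluxes, b.fluxes)


def test_timecourse_export_roundtrip(tmp_path, params, steady):
    tc = rc.simulate(params, steady, None, horizon=500.0, grid_dt=100.0)
    df = tc.to_frame()
    assert set(df.columns) == {"time_s", "variable", "value"}
    assert set(rc.STATE_NAMES) <= set(df.variable.unique())
    h5path = tmp_path / "tc.h5"
    tc.to_hdf5(h5path)
    import h5py

    with h5py.File(h5path) as h5:
        assert np.array_equal(h5["states"][...], tc.states)
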