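"""Ionic model: currents, reversal potentials, gates, channel scaling."""

from dataclasses import replace

import numpy as np
import pytest

from cardiomech.ionic import (CurrentSet, InvalidStateError, IonicState,
                              compute_currents, ionic_rhs)
from cardiomech.parameters import (CHANNELS, IonicParameters,
                                   apply_channel_scaling)
from cardiomech.states import cold_start_state


@pytest.fixture
def state():
    return IonicState.from_vector(cold_start_state())


def test_zero_conductance_zero_currents(state):
    p = replace(IonicParameters(), g_Na=0.0, g_NaL=0.0, g_CaL=0.0, g_f=0.0,
                g_K1=0.0, g_Kr=0.0, g_Ks=0.0, g_to=0.0, kNaCa=0.0, PNaK=0.0,
                g_PCa=0.0, g_b_Na=0.0, g_b_Ca=0.0)
    cur = compute_currents(state, p)
    for name, val in cur.__dict__.items():
        assert val == 0.0, name


def test_ik1_zero_at_k_reversal(state):
    p = IonicParameters()
    E_K = 8.314472 * p.T / 96485.3415 * np.log(p.Ko / p.Ki)
    state.Vm = E_K
    cur = compute_currents(state, p)
    assert cur.I_K1 == pytest.approx(0.0, abs=1e-12)
    # and I_Kr, I_to share the same reversal
    assert cur.I_Kr == pytest.approx(0.0, abs=1e-12)
    assert cur.I_to == pytest.approx(0.0, abs=1e-12)


def test_currents_finite_for_valid_state(state):
    cur = compute_currents(state)
    for name, val in cur.__dict__.items():
        assert np.isfinite(val), name


def test_invalid_state_error_names_component(state):
    state.Cai = -1e-5
    with pytest.raises(InvalidStateError, match="Cai"):
        compute_currents(state)
    state.Cai = 1e-5
    state.m = float("nan")
    with pytest.raises(InvalidStateError, match="m"):
        compute_currents(state)


def test_total_current_matches_dvdt(state):
    """C dV/dt = -(sum of currents - I_stim): the RHS and CurrentSet agree."""
    cur = compute_currents(state, I_stim=0.0)
    dy = ionic_rhs(0.0, state)
    assert dy[0] == pytest.approx(-cur.total(), rel=1e-9)


def test_ionic_rhs_external_flux_changes_only_cai(state):
    d0 = ionic_rhs(0.0, state, J_myofilament=0.0)
    d1 = ionic_rhs(0.0, state, J_myofilament=0.05)
    diff = d1 - d0
    assert diff[2] < 0  # flux toward the myofilament lowers dCai/dt
    mask = np.ones(22, bool)
    mask[2] = False
    assert diff[mask] == pytest.approx(np.zeros(21), abs=1e-15)


def test_ionic_rhs_gate_fixed_point():
    """Gates at their V-clamped steady values have zero derivatives."""
    from scipy.optimize import brentq
    p = IonicParameters()
    st = IonicState.from_vector(cold_start_state())
    # settle the gates by short relaxation at clamped V (concentrations fixed)
    from scipy.integrate import solve_ivp

    gate_idx = [3, 4, 5, 7, 8, 9, 10, 11, 12, 14, 15, 19, 20, 21]

    def rhs(t, y):
        s = IonicState.from_vector(y)
        d = ionic_rhs(t, s, p)
        d[[0, 1, 2, 13]] = 0.0          # clamp V and concentrations
        d[[16, 17, 18]] = 0.0           # clamp SR-release states
        d[6] = 0.0                      # fCa has a V-dependent lock; clamp
        return d

    sol = solve_ivp(rhs, (0, 50), st.to_vector(), method="LSODA",
                    rtol=1e-10, atol=1e-12)
    d_end = rhs(0.0, sol.y[:, -1])
    assert np.max(np.abs(d_end[gate_idx])) < 1e-7


def test_gates_remain_in_unit_interval_along_trajectory():
    from cardiomech.engine import full_rhs
    from cardiomech.parameters import ModelParameters, pack
    from scipy.integrate import solve_ivp
    P = pack(ModelParameters(coupling="weak"))
    y0 = cold_start_state()
    sol = solve_ivp(full_rhs, (0, 10.0), y0, method="LSODA", rtol=1e-6,
                    atol=1e-9, args=(P,), t_eval=np.linspace(0, 10, 500))
    from cardiomech.ionic import GATES, IONIC_FIELDS
    for g in GATES:
        i = IONIC_FIELDS.index(g)
        assert sol.y[i].min() > -1e-6 and sol.y[i].max() < 1 + 1e-6, g
    # concentrations strictly positive
    for name in ("Cai", "CaSR", "Nai"):
        i = IONIC_FIELDS.index(name)
        assert sol.y[i].min() > 0, name


# ---------------------------------------------------------------------------
# channel scaling

def test_scaling_identity():
    p = IonicParameters()
    q = apply_channel_scaling(p, {ch: 1.0 for ch in CHANNELS})
    assert q == p


def test_scaling_95_percent_block():
    p = apply_channel_scaling(IonicParameters(), {"I_Kr": 0.05})
    assert p.s_Kr == pytest.approx(0.05)


def test_scaling_composition():
    p = IonicParameters()
    ab = apply_channel_scaling(apply_channel_scaling(p, {"I_CaL": 1.5}),
                               {"I_CaL": 0.8})
    direct = apply_channel_scaling(p, {"I_CaL": 1.2})
    assert ab.s_CaL == pytest.approx(direct.s_CaL, rel=1e-14)


def test_scaling_unknown_channel():
    with pytest.raises(KeyError):
        apply_channel_scaling(IonicParameters(), {"I_bogus": 1.0})


def test_scaling_invalid_factor():
    with pytest.raises(ValueError):
        apply_channel_scaling(IonicParameters(), {"I_Kr": 0.0})


def test_multiplier_scales_current_linearly(state):
    base = compute_currents(state).I_Na
    doubled = compute_currents(state, apply_channel_scaling(
        IonicParameters(), {"I_Na": 2.0})).I_Na
    assert doubled == pytest.approx(2 * base, rel=1e-12)
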