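"""Contractile element: geometry, passive force, tension, steady-state oracle."""

import math

import numpy as np
import pytest

from cardiomech.contractile import (
    CEState,
    active_tension,
    collagen_force,
    driven_twitch,
    passive_force,
    resting_ce_state,
    skinned_tension_sl_curve,
    sl_dynamics,
    steady_state_force,
    thin_filament_overlap,
    titin_force,
    _pack_ce,
)
from cardiomech.engine import ce_outputs_driven, ce_rhs_driven
from cardiomech.parameters import CEParameters, PassiveForceConfig


# ---------------------------------------------------------------------------
# thin-filament overlap

def hand_overlap(SL, p):
    """Direct evaluation of the piecewise-linear overlap formula."""
    sovr_ze = min(p.len_thick / 2, SL / 2)
    sovr_cle = max(p.len_thin - SL / 2, p.len_hbare / 2)
    return (sovr_ze - sovr_cle) / p.len_thin


def test_overlap_matches_hand_formula():
    p = CEParameters()
    for SL in (1.9, 2.2):
        assert thin_filament_overlap(SL, p) == pytest.approx(hand_overlap(SL, p),
                                                             rel=1e-12)


def test_overlap_hand_values():
    # len_thick 1.65, len_hbare 0.1, len_thin 1.2
    assert thin_filament_overlap(1.9) == pytest.approx(0.575 / 1.2, rel=1e-12)
    assert thin_filament_overlap(2.2) == pytest.approx(0.725 / 1.2, rel=1e-12)


def test_overlap_monotone_on_ascending_limb():
    grid = np.linspace(1.5, 2.2, 30)
    vals = [thin_filament_overlap(s) for s in grid]
    assert np.all(np.diff(vals) > 0)


def test_overlap_domain_error():
    with pytest.raises(ValueError):
        thin_filament_overlap(1.0)
    with pytest.raises(ValueError):
        thin_filament_overlap(2.6)


# ---------------------------------------------------------------------------
# passive force

def test_passive_force_zero_at_rest_length_pure_cm():
    assert passive_force(1.9, PassiveForceConfig(ctn=100.0)) == 0.0


def test_passive_force_pure_cm_is_titin_only():
    p = CEParameters()
    for SL in (1.7, 1.9, 2.1, 2.3):
        assert passive_force(SL, PassiveForceConfig(100.0), p) == pytest.approx(
            titin_force(SL, p), rel=1e-12)


def test_passive_force_branch_hand_evaluation():
    p = CEParameters()
    SL = 2.3
    base = titin_force(SL, p) + collagen_force(SL, p)
    for ctn in (70.0, 71.0, 99.0):
        c = ctn / 100.0
        expect = 10.54 * (4.66 * math.exp(-3.05 * c ** 4.9)) * base
        assert passive_force(SL, PassiveForceConfig(ctn), p) == pytest.approx(
            expect, rel=1e-12)
    for ctn in (69.9, 40.0, 10.0):
        c = ctn / 100.0
        expect = (6.0 * math.exp(-6.17 * c ** 2.91)) * base
        assert passive_force(SL, PassiveForceConfig(ctn), p) == pytest.approx(
            expect, rel=1e-12)


def test_passive_force_ctn_boundary_uses_upper_branch():
    p = CEParameters()
    v70 = passive_force(2.2, PassiveForceConfig(70.0), p)
    c = 0.70
    base = titin_force(2.2, p) + collagen_force(2.2, p)
    assert v70 == pytest.approx(10.54 * (4.66 * math.exp(-3.05 * c ** 4.9)) * base)


def test_passive_force_monotone_above_rest():
    grid = np.linspace(1.9, 2.35, 40)
    for ctn in (100.0, 85.0, 50.0):
        vals = [passive_force(s, PassiveForceConfig(ctn)) for s in grid]
        assert np.all(np.diff(vals) >= 0)


def test_passive_force_ctn_domain_error():
    with pytest.raises(ValueError):
        PassiveForceConfig(0.0)
    with pytest.raises(ValueError):
        PassiveForceConfig(101.0)


def test_engine_passive_force_matches_module():
    """The compiled core and the Python formula agree."""
    p = CEParameters()
    for ctn in (100.0, 80.0, 50.0):
        P = _pack_ce(p, PassiveForceConfig(ctn), True)
        for SL in (1.8, 2.0, 2.3):
            y = resting_ce_state(p).to_vector()
            y[8] = SL
            out = ce_outputs_driven(y, 1e-4, P)
            assert out["F_passive"] == pytest.approx(
                passive_force(SL, PassiveForceConfig(ctn), p), rel=1e-10)


# ---------------------------------------------------------------------------
# active tension

def test_active_tension_zero_when_no_crossbridges():
    p = CEParameters()
    st = resting_ce_state(p)
    st.XB_prer = 0.0
    st.XB_postr = 0.0
    assert active_tension(st, p) == pytest.approx(0.0, abs=1e-12)


def test_active_tension_linear_in_kxb():
    from dataclasses import replace
    p = CEParameters()
    st = resting_ce_state(p)
    st.XB_prer, st.XB_postr = 0.05, 0.10
    t1 = active_tension(st, p)
    t2 = active_tension(st, replace(p, kxb=2 * p.kxb))
    assert t2 == pytest.approx(2 * t1, rel=1e-12)
    assert t1 > 0


# ---------------------------------------------------------------------------
# sarcomere-length dynamics

def test_sl_dynamics_rest_fixed_point():
    p = CEParameters()
    st = resting_ce_state(p)
    st.SL = p.SL_set
    st.intf = 0.0
    assert sl_dynamics(st, p) == 0.0


def test_sl_dynamics_linear_in_inverse_mass():
    from dataclasses import replace
    p = CEParameters()
    st = resting_ce_state(p)
    st.intf = -0.01
    d1 = sl_dynamics(st, p)
    d2 = sl_dynamics(st, replace(p, mass=p.mass / 2))
    assert d2 == pytest.approx(2 * d1, rel=1e-12)


def test_sl_dynamics_mass_zero_error():
    from dataclasses import replace
    with pytest.raises(ValueError):
        sl_dynamics(resting_ce_state(), replace(CEParameters(), mass=0.0))


# ---------------------------------------------------------------------------
# steady-state oracle vs dynamic relaxation

@pytest.mark.parametrize("Ca,SL", [(2e-4, 1.9), (5e-4, 2.2), (1e-3, 2.0)])
def test_algebraic_steady_state_matches_dynamic_core(Ca, SL):
    p = CEParameters()
    oracle = steady_state_force(Ca, SL, p)
    P = _pack_ce(p, None, True)
    y0 = resting_ce_state(p).to_vector()
    y0[8] = SL
    from scipy.integrate import solve_ivp
    sol = solve_ivp(ce_rhs_driven, (0, 10), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12, args=(Ca, P))
    dyn = ce_outputs_driven(sol.y[:, -1], Ca, P)
    assert oracle["Tension"] == pytest.approx(dyn["Tension"], rel=1e-6)
    assert sol.y[0, -1] == pytest.approx(oracle["N"], abs=1e-7)
    assert sol.y[2, -1] == pytest.approx(oracle["XB_postr"], abs=1e-7)


def test_steady_state_force_ca_saturation():
    p = CEParameters()
    lo = steady_state_force(1e-5, 2.2, p)
    hi = steady_state_force(1.0, 2.2, p)  # Ca >> KoffL*Koffmod/Kon = 1.6e-3 mM
    assert hi["TropL"] > 0.99 and hi["TropH"] > 0.99
    assert hi["Tension"] > lo["Tension"]


def test_force_ca_curve_sigmoidal_and_nperm_steepness():
    """Effective Hill coefficient increases with nperm."""
    from dataclasses import replace
    p = CEParameters()

    def hill_coeff(params):
        cas = np.logspace(-4.6, -2.6, 25)
        f = np.array([steady_state_force(c, 2.2, params)["F_active"]
                      for c in cas])
        f = f / f.max()
        # slope of the logit vs log-Ca at half activation
        i = int(np.argmin(np.abs(f - 0.5)))
        sel = slice(max(i - 3, 1), min(i + 4, len(f) - 1))
        y = np.log(f[sel] / (1 - f[sel] + 1e-12))
        x = np.log(cas[sel])
        return np.polyfit(x, y, 1)[0]

    n_base = hill_coeff(p)
    n_steep = hill_coeff(replace(p, nperm=p.nperm * 1.1))
    assert n_steep > n_base > 1.0


# ---------------------------------------------------------------------------
# tension-SL curve

def test_skinned_curve_normalized_and_monotone_ascending():
    grid = np.array([1.6, 1.8, 2.0, 2.2])
    curve = skinned_tension_sl_curve(3e-4, grid, use_oracle=True)
    assert curve.max() == pytest.approx(1.0)
    assert np.all(np.diff(curve) > 0)


def test_skinned_curve_dynamic_agrees_with_oracle():
    grid = np.array([1.7, 1.9, 2.2])
    a = skinned_tension_sl_curve(3e-4, grid, settle=8.0, use_oracle=False)
    b = skinned_tension_sl_curve(3e-4, grid, use_oracle=True)
    assert a == pytest.approx(b, rel=1e-4)


# ---------------------------------------------------------------------------
# regulatory-unit conservation and twitch behaviour

def test_driven_twitch_conservation_and_shortening():
    from cardiomech.synth import SyntheticCaT, generate_cat_waveform
    w = generate_cat_waveform(SyntheticCaT(), 4.0, 5e-4)
    df = driven_twitch(w["t"].to_numpy(), w["Cai"].to_numpy())
    # occupancies stay in [0, 1]; P = 1 - N - XBprer - XBpostr stays valid
    P = 1.0 - df["N"] - df["XB_prer"] - df["XB_postr"]
    assert ((P > -1e-6) & (P < 1 + 1e-6)).all()
    assert ((df["TropL"] >= 0) & (df["TropL"] <= 1)).all()
    # the cell shortens below rest length then recovers toward it
    assert df["SL"].min() < 1.9 - 1e-3
    assert abs(df["SL"].iloc[-1] - df["SL"].iloc[0]) < 0.2


def test_driven_twitch_isosarcometric_clamps_sl():
    from cardiomech.synth import SyntheticCaT, generate_cat_waveform
    w = generate_cat_waveform(SyntheticCaT(), 2.0, 1e-3)
    df = driven_twitch(w["t"].to_numpy(), w["Cai"].to_numpy(),
                       isosarcometric=True)
    assert df["SL"].std() == pytest.approx(0.0, abs=1e-12)
    assert df["Tension"].max() > 0


def test_ce_state_round_trip_and_validation():
    st = resting_ce_state()
    st2 = CEState.from_vector(st.to_vector())
    assert st2 == st
    st2.N = 1.5
    with pytest.raises(ValueError):
        st2.validate()
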