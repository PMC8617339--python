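"""Protocols: validation, determinism, pacing, coupling and ctn effects."""

import numpy as np
import pytest

from cardiomech.protocols import (EXAMPLE_EAD_SETS, ProtocolConfig,
                                  SCALABLE_CHANNELS, ead_protocol, run)
from cardiomech.states import cold_start_state


def short_cfg(**kw):
    base = dict(mode="spontaneous", settle=0.0, record=6.0, record_dt=1e-3)
    base.update(kw)
    return ProtocolConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        ProtocolConfig(mode="banana")
    with pytest.raises(ValueError):
        ProtocolConfig(record=-1.0)
    with pytest.raises(ValueError):
        ProtocolConfig(mode="paced", frequency_hz=0.0)


def test_ead_protocol_input_validation():
    with pytest.raises(KeyError):
        ead_protocol({"I_bogus": 1.0})
    with pytest.raises(ValueError):
        ead_protocol({"I_CaL": 3.0})
    with pytest.raises(ValueError):
        ead_protocol({"I_CaL": 1.0}, ikr_block=1.5)


def test_example_sets_are_within_range():
    for name, s in EXAMPLE_EAD_SETS.items():
        for ch, f in s.items():
            assert ch in SCALABLE_CHANNELS, (name, ch)
            assert 0.5 <= f <= 2.0, (name, ch)


def test_run_deterministic():
    y0 = cold_start_state()
    a = run(short_cfg(), initial=y0)
    b = run(short_cfg(), initial=y0)
    assert np.array_equal(a.data.to_numpy(), b.data.to_numpy())


def test_spontaneous_run_beats_and_records_outputs():
    res = run(short_cfg(record=8.0), initial=cold_start_state())
    assert not res.quiescent
    assert res.upstrokes.size >= 3
    for col in ("V", "Cai", "SL", "Tension", "INa", "JCaBMyo"):
        assert col in res.data.columns
    assert res["Tension"].max() > 0
    # V in plausible physiologic band (mV)
    assert -100 < res["V"].min() < -50
    assert 0 < res["V"].max() < 60


def test_paced_run_captures_stimulus():
    # a cold start needs ~20 s of pacing before the automaticity transient
    # dies out and the stimulus overdrives the intrinsic rhythm
    cfg = ProtocolConfig(mode="paced", frequency_hz=1.0, settle=20.0,
                         record=4.0, record_dt=1e-3)
    res = run(cfg, initial=cold_start_state())
    # stimulated upstrokes lock to the pacing period
    assert res.upstrokes.size >= 3
    cl = np.diff(res.upstrokes)
    assert np.allclose(cl, 1.0, atol=0.05)
    # the recorded stimulus trace contains the rectangular pulses
    assert res["Istim"].max() > 0
    frac_on = np.mean(res["Istim"] > 0)
    assert 0.001 < frac_on < 0.05  # ~5 ms per 1000 ms


def synthetic_ap_with_bump(bump_amp=0.0, bump_center=0.25, n_beats=4, cl=1.2):
    """AP train with an optional depolarizing bump mid-repolarization.

    Always includes a realistic slow phase-4 pacemaker depolarization,
    which must never be counted as an EAD.
    """
    dt = 5e-4
    t = np.arange(0.0, n_beats * cl, dt)
    phase = np.mod(t, cl)
    mdp, peak = -75.0, 28.0
    amp = peak - mdp
    up = 0.004
    T_rep = 0.45
    V = np.full_like(t, mdp)
    rising = phase < up
    V[rising] = mdp + amp * phase[rising] / up
    fall = (phase >= up) & (phase < up + T_rep)
    x = (phase[fall] - up) / T_rep
    V[fall] = mdp + amp * 0.5 * (1 + np.cos(np.pi * x))
    # phase-4: slow linear depolarization from MDP toward threshold
    dia = phase >= up + T_rep
    V[dia] = mdp + 8.0 * (phase[dia] - up - T_rep) / (cl - up - T_rep)
    if bump_amp > 0:
        # narrow enough that its upslope beats the repolarization downslope
        bump = bump_amp * np.exp(-((phase - bump_center) / 0.015) ** 2)
        V = V + np.where((phase > up) & (phase < up + T_rep), bump, 0.0)
    return t, V


def test_ead_detector_ignores_pacemaker_depolarization():
    from cardiomech.protocols import _detect_eads
    from cardiomech.biomarkers import detect_upstrokes
    t, V = synthetic_ap_with_bump(bump_amp=0.0)
    ups = detect_upstrokes(t, V)
    lvl30 = 28.0 - 0.30 * 103.0
    lvl90 = 28.0 - 0.90 * 103.0
    count, _ = _detect_eads(t, V, ups, lvl30, lvl90)
    assert count == 0


def test_ead_detector_counts_repolarization_bump():
    from cardiomech.protocols import _detect_eads
    from cardiomech.biomarkers import detect_upstrokes
    t, V = synthetic_ap_with_bump(bump_amp=18.0, bump_center=0.25)
    ups = detect_upstrokes(t, V)
    lvl30 = 28.0 - 0.30 * 103.0
    lvl90 = 28.0 - 0.90 * 103.0
    count, times = _detect_eads(t, V, ups, lvl30, lvl90)
    # one bump per fully-bracketed beat
    assert count == len(ups) - 1
    assert all(0.15 < (ti % 1.2) < 0.35 for ti in times)


def test_aftercontraction_detector_on_synthetic_twitch():
    from cardiomech.protocols import _detect_aftercontractions
    dt = 5e-4
    cl = 1.2
    t = np.arange(0.0, 4 * cl, dt)
    phase = np.mod(t, cl)
    main = np.where(phase < 0.15, 0.5 * (1 - np.cos(np.pi * phase / 0.15)),
                    np.exp(-(phase - 0.15) / 0.1))
    clean = 0.06 * main
    bump = 0.02 * np.exp(-((phase - 0.45) / 0.03) ** 2)
    ups = np.arange(0.0, 4 * cl, cl)
    n_clean, _ = _detect_aftercontractions(t, clean, ups)
    n_bumped, times = _detect_aftercontractions(t, clean + bump, ups)
    assert n_clean == 0
    assert n_bumped == 3  # one per fully-bracketed beat
    assert all(0.4 < (ti % cl) < 0.5 for ti in times)
    # a small but genuine secondary peak (1% of the twitch, late in the
    # relaxation where aftercontractions actually occur) is detected ...
    small = 0.0006 * np.exp(-((phase - 0.7) / 0.03) ** 2)
    n_small, _ = _detect_aftercontractions(t, clean + small, ups)
    assert n_small == 3
    # ... while sub-floor ripple (0.1%) is not
    ripple = 0.00006 * np.exp(-((phase - 0.7) / 0.03) ** 2)
    n_ripple, _ = _detect_aftercontractions(t, clean + ripple, ups)
    assert n_ripple == 0


def test_weak_coupling_changes_cai_dynamics():
    y0 = cold_start_state()
    strong = run(short_cfg(coupling="strong"), initial=y0)
    weak = run(short_cfg(coupling="weak"), initial=y0)
    # identical configs except the feedback flag must diverge
    assert not np.allclose(strong["Cai"], weak["Cai"])
    # weak coupling still drives the CE (feed-forward)
    assert weak["Tension"].max() > 0


def test_ctn_scales_passive_force():
    y0 = cold_start_state()
    pure = run(short_cfg(record=3.0, ctn=100.0), initial=y0)
    eht = run(short_cfg(record=3.0, ctn=80.0), initial=y0)
    # with non-myocytes present the passive force at stretched lengths grows
    sl_hi = pure["SL"] > 1.905
    if sl_hi.any():
        assert np.max(np.abs(eht["F_passive"])) != pytest.approx(
            np.max(np.abs(pure["F_passive"])))
    # both still beat
    assert not pure.quiescent and not eht.quiescent


def test_solver_refinement_stability():
    """APD90 drifts by < 0.5 ms when the solver tolerances are halved."""
    from dataclasses import replace
    y0 = cold_start_state()
    cfg = ProtocolConfig(mode="spontaneous", settle=10.0, record=12.0,
                         record_dt=1e-3)
    a = run(cfg, initial=y0).biomarkers()
    b = run(replace(cfg, rtol=5e-7, atol=5e-10), initial=y0).biomarkers()
    assert abs(a.APD90 - b.APD90) < 0.5


def test_isosarcometric_clamps_sl():
    res = run(short_cfg(record=3.0, isosarcometric=True),
              initial=cold_start_state())
    assert np.ptp(res["SL"]) == pytest.approx(0.0, abs=1e-12)


def test_ce_inactive_freezes_contractile_states():
    res = run(short_cfg(record=3.0, ce_active=False),
              initial=cold_start_state())
    assert np.ptp(res["SL"]) == 0.0
    assert np.all(res["Tension"] == 0.0)
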