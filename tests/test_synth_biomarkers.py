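"""Synthetic waveform generator and biomarker extraction round trips."""

import math

import numpy as np
import pytest

from cardiomech.biomarkers import (InsufficientBeatsError, ap_biomarkers,
                                   cat_biomarkers, detect_upstrokes,
                                   mech_biomarkers)
from cardiomech.synth import SyntheticCaT, generate_cat_waveform


# ---------------------------------------------------------------------------
# generator

def test_waveform_peak_by_construction():
    spec = SyntheticCaT(diastolic=2e-5, amplitude=3e-4, time_to_peak=60.0,
                        tau_decay=150.0, frequency_hz=1.0)
    df = generate_cat_waveform(spec, 3.0, 1e-3)
    # peak occurs at time_to_peak of each cycle with value dia + amp
    assert df["Cai"].max() == pytest.approx(2e-5 + 3e-4, rel=1e-6)
    k = df["Cai"].idxmax()
    assert math.fmod(df["t"][k], 1.0) == pytest.approx(0.060, abs=2e-3)
    assert df["Cai"].min() == pytest.approx(2e-5, rel=1e-6)


def test_waveform_zero_amplitude_constant():
    spec = SyntheticCaT(amplitude=0.0)
    df = generate_cat_waveform(spec, 1.0, 1e-3)
    assert df["Cai"].std() == 0.0


def test_waveform_validation():
    with pytest.raises(ValueError):
        generate_cat_waveform(SyntheticCaT(diastolic=0.0), 1.0, 1e-3)
    with pytest.raises(ValueError):
        generate_cat_waveform(SyntheticCaT(time_to_peak=-5.0), 1.0, 1e-3)
    with pytest.raises(ValueError):
        # 2 Hz cycle is 500 ms; ttp 600 ms impossible
        generate_cat_waveform(SyntheticCaT(time_to_peak=600.0,
                                           frequency_hz=2.0), 1.0, 1e-3)
    with pytest.raises(ValueError):  # dt too coarse
        generate_cat_waveform(SyntheticCaT(time_to_peak=50.0), 1.0, 2e-2)


def test_cat_biomarkers_recover_specified_kinetics():
    """Round trip: extraction matches the analytic shape constants."""
    ttp, tau = 80.0, 180.0
    spec = SyntheticCaT(time_to_peak=ttp, tau_decay=tau)
    df = generate_cat_waveform(spec, 6.0, 2e-4)
    cb = cat_biomarkers(df["t"].to_numpy(), df["Cai"].to_numpy())
    # half-cosine rise: 10% level at ttp*acos(0.8)/pi from cycle start
    t10 = ttp * math.acos(1 - 2 * 0.1) / math.pi
    assert cb.tRise10_peak == pytest.approx(ttp - t10, abs=1.0)
    # monoexponential decay: t(90->10) = tau * ln 9
    assert cb.tDecay90_10 == pytest.approx(tau * math.log(9.0), abs=2.0)
    assert cb.n_beats_used == 3


def test_cat_biomarkers_scale_invariance():
    df = generate_cat_waveform(SyntheticCaT(), 6.0, 5e-4)
    t, ca = df["t"].to_numpy(), df["Cai"].to_numpy()
    a = cat_biomarkers(t, ca)
    b = cat_biomarkers(t, 7.3 * ca)
    for k in ("CaT_duration", "tRise10_peak", "tDecay90_10"):
        assert getattr(a, k) == pytest.approx(getattr(b, k), rel=1e-9)


def test_cat_biomarkers_insufficient_beats():
    df = generate_cat_waveform(SyntheticCaT(), 1.5, 1e-3)
    with pytest.raises(InsufficientBeatsError):
        cat_biomarkers(df["t"].to_numpy(), df["Cai"].to_numpy())


# ---------------------------------------------------------------------------
# synthetic action potential

def synthetic_ap(n_beats=6, cl=1.0, dt=2e-4, mdp=-75.0, peak=27.0,
                 apd90_s=0.40):
    """Idealized AP train with known MDP/peak and controllable APD."""
    t = np.arange(0.0, n_beats * cl + 0.05, dt)
    phase = np.mod(t - 0.1, cl)  # diastolic lead-in before the first beat
    V = np.full_like(t, mdp)
    up = 0.004      # upstroke duration
    amp = peak - mdp
    rising = phase < up
    V[rising] = mdp + amp * (phase[rising] / up)
    # plateau + repolarization: cosine fall over [up, up + T_rep]
    T_rep = apd90_s * 1.08
    fall = (phase >= up) & (phase < up + T_rep)
    x = (phase[fall] - up) / T_rep
    V[fall] = mdp + amp * 0.5 * (1 + np.cos(np.pi * x ** 1.5))
    return t, V


def test_ap_biomarkers_on_synthetic_train():
    t, V = synthetic_ap()
    ap = ap_biomarkers(t, V)
    assert ap.APA == pytest.approx(102.0, abs=0.5)
    assert ap.MDP == pytest.approx(-75.0, abs=0.5)
    assert ap.CL == pytest.approx(1000.0, abs=2.0)
    # dVdt_max = amp/up = 102/4 mV/ms = 25.5 V/s
    assert ap.dVdt_max == pytest.approx(25.5, rel=0.05)
    assert 0 < ap.APD10 < ap.APD30 < ap.APD90
    assert ap.AP_tri == pytest.approx(
        (ap.APD90 - ap.APD10) / (ap.APD90 - ap.APD30))


def test_detect_upstrokes_counts_beats():
    t, V = synthetic_ap(n_beats=5)
    ups = detect_upstrokes(t, V)
    assert len(ups) == 5
    assert np.diff(ups) == pytest.approx(np.full(4, 1.0), abs=1e-3)


def test_ap_biomarkers_insufficient():
    t, V = synthetic_ap(n_beats=2)
    with pytest.raises(InsufficientBeatsError):
        ap_biomarkers(t, V, n_beats=3)


# ---------------------------------------------------------------------------
# mechanics

def synthetic_twitch(n=5, cl=1.0, dt=5e-4, sl0=1.90, depth=0.05,
                     ttp=0.15, tau=0.12):
    t = np.arange(0.0, n * cl, dt)
    phase = np.mod(t, cl)
    short = np.where(phase < ttp,
                     0.5 * (1 - np.cos(np.pi * phase / ttp)),
                     np.exp(-(phase - ttp) / tau))
    SL = sl0 - depth * short
    tension = 0.06 * short
    return t, SL, tension


def test_mech_biomarkers_on_synthetic_twitch():
    t, SL, ten = synthetic_twitch()
    mb = mech_biomarkers(t, SL, ten)
    assert mb.frac_shortening == pytest.approx(0.05 / 1.90 * 100.0, rel=0.02)
    assert mb.peak_tension == pytest.approx(0.06, rel=0.02)
    # RT50 of a monoexponential recovery: tau*ln 2
    assert mb.RT50 == pytest.approx(0.12 * math.log(2.0) * 1000.0, abs=4.0)
    assert mb.RT25 < mb.RT50 < mb.RT80


def test_mech_biomarkers_flat_trace_warns():
    t = np.linspace(0, 5, 1000)
    SL = np.full_like(t, 1.9)
    with pytest.warns(UserWarning):
        mb = mech_biomarkers(t, SL, np.zeros_like(t))
    assert mb.frac_shortening == 0.0
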