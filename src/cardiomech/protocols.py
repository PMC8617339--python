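"""Executable experiment protocols and the ODE integration engine.

Protocols wrap the compiled core with the configurations used throughout
the study: spontaneous steady state, paced runs, the strong-vs-weak
coupling-feedback comparison, rapid-delayed-rectifier-block arrhythmia
runs on conductance-scaled variants, tissue-composition sweeps, and drug
applications.  Every protocol is deterministic: identical configuration
and initial state give identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import biomarkers as bm
from .engine import full_rhs, full_outputs
from .layout import (NSTATE, OUT_FIELDS, PARAM_INDEX, STATE_FIELDS,
                     STATE_INDEX)
from .parameters import (IonicParameters, ModelParameters, PassiveForceConfig,
                         apply_channel_scaling, pack)
from .states import default_state

__all__ = [
    "ProtocolConfig", "SimulationResult", "IntegrationError",
    "run", "ead_protocol", "ctn_sweep", "coupling_feedback_study",
    "find_ead_variants", "EXAMPLE_EAD_SETS", "SCALABLE_CHANNELS",
]

#: channels whose maximal conductances/currents the variant protocols scale
SCALABLE_CHANNELS = ("I_Na", "I_NaL", "I_CaL", "I_f", "I_to", "I_Kr",
                     "I_Ks", "I_K1", "I_NaCa", "I_NaK", "I_pCa")


class IntegrationError(RuntimeError):
    """Stiff-solver failure; carries the last valid time reached."""

    def __init__(self, message: str, t_last: float):
        super().__init__(f"{message} (last valid time {t_last:.6g} s)")
        self.t_last = t_last


@dataclass
class ProtocolConfig:
    """One executable experiment definition."""

    mode: str = "spontaneous"           # "spontaneous" | "paced"
    frequency_hz: float = 1.0           # pacing rate (paced mode)
    stim_amplitude: float = 5.5e-10     # A (rectangular pulse)
    stim_duration: float = 0.005        # s
    settle: float = 30.0                # integration before the recording (s)
    record: float = 12.0                # recorded window (s)
    record_dt: float = 2e-4             # output sampling step (s)
    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = math.inf
    coupling: str = "strong"            # "strong" | "weak"
    ctn: float = 100.0
    isosarcometric: bool = False
    ce_active: bool = True
    n_beats: int = 3                    # beats averaged for biomarkers
    steady_apd_tol: float = 1.0         # ms, consecutive-beat APD90 change
    steady_cat_tol: float = 1.0         # %, consecutive-beat CaT-peak change
    channel_scaling: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("spontaneous", "paced"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.record <= 0 or self.settle < 0:
            raise ValueError("durations must be positive")
        if self.mode == "paced" and self.frequency_hz <= 0:
            raise ValueError("pacing frequency must be > 0")

    def build_params(self, base: ModelParameters | None = None) -> ModelParameters:
        p = base if base is not None else ModelParameters()
        ionic = apply_channel_scaling(p.ionic, self.channel_scaling) \
            if self.channel_scaling else p.ionic
        return ModelParameters(
            ionic=ionic, ce=p.ce, tissue=PassiveForceConfig(ctn=self.ctn),
            coupling=self.coupling, isosarcometric=self.isosarcometric,
            ce_active=self.ce_active)


@dataclass
class SimulationResult:
    """Uniformly sampled time series of one protocol run."""

    data: pd.DataFrame                  # t plus all state/output columns
    config: ProtocolConfig
    params: ModelParameters
    upstrokes: np.ndarray = field(default_factory=lambda: np.array([]))
    quiescent: bool = False
    steady: bool = True
    ead_count: int = 0
    aftercontraction_count: int = 0
    events: dict = field(default_factory=dict)

    @property
    def t(self):
        return self.data["t"].to_numpy()

    def __getitem__(self, key):
        return self.data[key].to_numpy()

    def biomarkers(self, n_beats: int | None = None) -> bm.BiomarkerSet:
        n = n_beats or self.config.n_beats
        out = bm.BiomarkerSet()
        if not self.quiescent:
            out = out.merge(bm.ap_biomarkers(self.t, self["V"], n_beats=n))
            out = out.merge(bm.cat_biomarkers(self.t, self["Cai"], n_beats=n))
        if self.params.ce_active and not self.quiescent:
            out = out.merge(bm.mech_biomarkers(
                self.t, self["SL"], self["Tension"], n_beats=n))
        return out

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")


def _integrate(y0, P, t0, t1, cfg, t_eval=None):
    if t1 <= t0:
        return np.empty(0), np.empty((NSTATE, 0)), y0
    sol = solve_ivp(full_rhs, (t0, t1), y0, method=cfg.method,
                    t_eval=t_eval, rtol=cfg.rtol, atol=cfg.atol,
                    max_step=cfg.max_step, args=(P,), dense_output=False)
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else t0)
    return sol.t, sol.y, sol.y[:, -1].copy()


def _paced_segments(y, P, t0, t1, cfg, record_times=None):
    """Integrate a paced interval as stimulus-on/off sub-segments."""
    period = 1.0 / cfg.frequency_hz
    amp = cfg.stim_amplitude / P[PARAM_INDEX["Cm"]]  # A -> A/F
    ts, ys = [], []
    n0 = int(math.floor(t0 / period + 1e-9))
    t = t0
    for k in range(n0, int(math.ceil(t1 / period)) + 1):
        beat_start = k * period
        stim_end = beat_start + cfg.stim_duration
        for (a, b, on) in ((beat_start, min(stim_end, t1), True),
                           (min(stim_end, t1), min((k + 1) * period, t1), False)):
            a = max(a, t0)
            if b <= a:
                continue
            P[PARAM_INDEX["I_stim"]] = amp if on else 0.0
            te = None
            if record_times is not None:
                te = record_times[(record_times >= a) & (record_times <= b)]
                te = np.concatenate(([a], te, [b]))
                te = np.unique(te)
            tt, yy, y = _integrate(y, P, a, b, cfg, t_eval=te)
            if record_times is not None and tt.size:
                ts.append(tt)
                ys.append(yy)
            t = b
        if t >= t1:
            break
    P[PARAM_INDEX["I_stim"]] = 0.0
    if record_times is None:
        return None, None, y
    tt = np.concatenate(ts)
    yy = np.concatenate(ys, axis=1)
    # segment boundaries are shared between adjacent sub-integrations;
    # keep one sample per time point
    keep = np.concatenate(([True], np.diff(tt) > 0))
    return tt[keep], yy[:, keep], y


def _detect_eads(t, V, upstrokes, apd30_level, apd90_level,
                 dvdt_thresh=0.01, min_dur=0.005):
    """Count depolarizing deflections during phase-2/3 repolarization.

    A deflection qualifies when dV/dt exceeds ``dvdt_thresh`` (V/s) for at
    least ``min_dur`` seconds while V lies between the 90%- and
    30%-repolarization levels, after the AP peak and before repolarization
    completes (first crossing below the 90% level) — the slow phase-4
    pacemaker depolarization that follows is not an EAD.
    """
    dvdt = np.gradient(V, t) / 1000.0
    count = 0
    events = []
    for u0, u1 in zip(upstrokes[:-1], upstrokes[1:]):
        i0, i1 = np.searchsorted(t, (u0, u1))
        if i1 - i0 < 4:
            continue
        k_peak = i0 + int(np.argmax(V[i0:i1]))
        # end of repolarization: first sample at/below the 90% level
        below = np.nonzero(V[k_peak + 1:i1] <= apd90_level)[0]
        k_end = k_peak + 1 + int(below[0]) if below.size else i1
        win = slice(k_peak + 1, k_end)
        mask = ((dvdt[win] > dvdt_thresh)
                & (V[win] < apd30_level) & (V[win] > apd90_level))
        # contiguous runs of sustained depolarization
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        splits = np.nonzero(np.diff(idx) > 1)[0]
        runs = np.split(idx, splits + 1)
        for run_ in runs:
            if t[win.start + run_[-1]] - t[win.start + run_[0]] >= min_dur:
                count += 1
                events.append(float(t[win.start + run_[0]]))
    return count, events


def _detect_aftercontractions(t, tension, upstrokes,
                              rel_prominence=0.005):
    """Secondary tension peaks before 90% relaxation of the main twitch.

    ``rel_prominence`` is a noise floor relative to the twitch amplitude.
    Simulated traces are noiseless, so the default only needs to reject
    solver ripple (~1e-4 relative); raise it for experimental recordings.
    """
    from scipy.signal import find_peaks
    count = 0
    events = []
    for u0, u1 in zip(upstrokes[:-1], upstrokes[1:]):
        i0, i1 = np.searchsorted(t, (u0, u1))
        if i1 - i0 < 4:
            continue
        seg = tension[i0:i1]
        base = float(np.min(seg))
        amp = float(np.max(seg)) - base
        if amp <= 0:
            continue
        k_main = int(np.argmax(seg))
        peaks, props = find_peaks(seg, prominence=rel_prominence * amp)
        for p in peaks:
            if p > k_main:
                count += 1
                events.append(float(t[i0 + p]))
    return count, events


def run(config: ProtocolConfig,
        initial: np.ndarray | None = None,
        base_params: ModelParameters | None = None) -> SimulationResult:
    """Integrate one protocol and return the recorded window.

    ``initial`` defaults to the shipped pre-equilibrated state matching the
    protocol mode and coupling.  The recording starts after ``settle``
    seconds; the steady-state criterion (consecutive-beat APD90 and
    CaT-peak changes below tolerance) is evaluated on the recording and
    reported in ``SimulationResult.steady``.
    """
    params = config.build_params(base_params)
    P = pack(params)
    if initial is None:
        name = ("spontaneous" if config.mode == "spontaneous"
                else f"paced{config.frequency_hz:g}hz")
        initial = default_state(f"{name}_{config.coupling}")
    y = np.array(initial, float)

    t_rec0 = config.settle
    t_end = config.settle + config.record
    rec_times = np.round(
        np.arange(t_rec0, t_end + config.record_dt / 2, config.record_dt), 12)

    if config.mode == "spontaneous":
        P[PARAM_INDEX["I_stim"]] = 0.0
        _, _, y = _integrate(y, P, 0.0, t_rec0, config,
                             t_eval=np.array([t_rec0]) if t_rec0 > 0 else None)
        tt, yy, y = _integrate(y, P, t_rec0, t_end, config, t_eval=rec_times)
    else:
        _, _, y = _paced_segments(y, P, 0.0, t_rec0, config)
        tt, yy, y = _paced_segments(y, P, t_rec0, t_end, config,
                                    record_times=rec_times)

    # derived outputs along the recording (restore the stimulus value that
    # was active at each recorded sample)
    outs = np.empty((len(OUT_FIELDS), tt.size))
    stim_P = P.copy()
    if config.mode == "paced":
        period = 1.0 / config.frequency_hz
        amp = config.stim_amplitude / P[PARAM_INDEX["Cm"]]
        phase = np.mod(tt + 1e-12, period)
        stim_on = phase < config.stim_duration
    else:
        stim_on = np.zeros(tt.size, dtype=bool)
        amp = 0.0
    for k in range(tt.size):
        stim_P[PARAM_INDEX["I_stim"]] = amp if stim_on[k] else 0.0
        outs[:, k] = full_outputs(tt[k], yy[:, k], stim_P)

    df = pd.DataFrame({"t": tt})
    df["V"] = yy[STATE_INDEX["Vm"]] * 1000.0  # mV
    for name in ("Cai", "CaSR", "Nai", "SL", "intf"):
        df[name] = yy[STATE_INDEX[name]]
    for name in ("N", "XBprer", "XBpostr", "TRPNCaL", "TRPNCaH"):
        df[name] = yy[STATE_INDEX[name]]
    for i, name in enumerate(OUT_FIELDS):
        df[name] = outs[i]

    res = SimulationResult(data=df, config=config, params=params)
    V = df["V"].to_numpy()
    ups = bm.detect_upstrokes(tt, V)
    res.upstrokes = ups
    if ups.size < 2:
        res.quiescent = True
        res.steady = False
        return res

    # steady-state criterion on the recorded beats
    try:
        many = max(config.n_beats + 1, min(6, ups.size - 1))
        apd90s = []
        capeaks = []
        Ca = df["Cai"].to_numpy()
        for u0, u1 in zip(ups[-many - 1:-1], ups[-many:]):
            i0, i1 = np.searchsorted(tt, (u0, u1))
            one = bm.ap_biomarkers(tt[max(i0 - 5, 0):i1 + 5],
                                   V[max(i0 - 5, 0):i1 + 5], n_beats=1)
            apd90s.append(one.APD90)
            capeaks.append(float(np.max(Ca[i0:i1])))
        d_apd = np.abs(np.diff(apd90s))
        d_cat = np.abs(np.diff(capeaks)) / np.asarray(capeaks[:-1]) * 100.0
        res.steady = bool(np.all(d_apd < config.steady_apd_tol)
                          and np.all(d_cat < config.steady_cat_tol))
        res.events["apd90_per_beat"] = [float(a) for a in apd90s]
        res.events["cat_peak_per_beat"] = capeaks
    except bm.InsufficientBeatsError:
        res.steady = False

    # arrhythmia annotations
    try:
        ap = bm.ap_biomarkers(tt, V, n_beats=min(config.n_beats, ups.size - 1))
        v_peak = ap.MDP + ap.APA
        lvl30 = v_peak - 0.30 * ap.APA
        lvl90 = v_peak - 0.90 * ap.APA
        res.ead_count, ead_t = _detect_eads(tt, V, ups, lvl30, lvl90)
        res.events["ead_times"] = ead_t
        if params.ce_active:
            res.aftercontraction_count, ac_t = _detect_aftercontractions(
                tt, df["Tension"].to_numpy(), ups)
            res.events["aftercontraction_times"] = ac_t
    except bm.InsufficientBeatsError:
        pass
    return res


def ead_protocol(scaling_set: dict[str, float],
                 ikr_block: float = 0.95,
                 config: ProtocolConfig | None = None,
                 initial: np.ndarray | None = None) -> SimulationResult:
    """Spontaneous run of a conductance-scaled variant under I_Kr block.

    ``scaling_set`` maps channel names to factors (study convention:
    factors within [0.5, 2]); ``ikr_block`` is the blocked fraction, so
    the I_Kr multiplier becomes ``(1 - ikr_block)`` on top of the set.
    """
    if not 0.0 <= ikr_block <= 1.0:
        raise ValueError("ikr_block must be in [0, 1]")
    for ch, f in scaling_set.items():
        if ch not in SCALABLE_CHANNELS:
            raise KeyError(f"channel {ch!r} not scalable; use {SCALABLE_CHANNELS}")
        if not (0.5 <= f <= 2.0):
            raise ValueError(f"factor for {ch} outside [0.5, 2]: {f}")
    cfg = config or ProtocolConfig(mode="spontaneous", settle=60.0, record=20.0)
    scaling = dict(scaling_set)
    scaling["I_Kr"] = scaling.get("I_Kr", 1.0) * (1.0 - ikr_block)
    cfg = replace(cfg, channel_scaling=scaling)
    return run(cfg, initial=initial)


def coupling_feedback_study(config: ProtocolConfig | None = None,
                            initial_strong: np.ndarray | None = None,
                            initial_weak: np.ndarray | None = None):
    """Paired strong- vs weak-coupling runs with percentage deltas.

    Returns ``(strong, weak, deltas)`` where ``deltas`` holds the percent
    change of the CaT peak and of the peak active tension of the strongly
    coupled run relative to the weakly coupled one.
    """
    cfg = config or ProtocolConfig()
    strong = run(replace(cfg, coupling="strong"), initial=initial_strong)
    weak = run(replace(cfg, coupling="weak"), initial=initial_weak)

    def _peaks(res):
        t, Ca, Ten = res.t, res["Cai"], res["Tension"]
        segs = bm._segment_transients(t, Ca, cfg.n_beats)
        cat = float(np.mean([Ca[ip] - np.min(Ca[i0:ip])
                             for i0, ip, i1 in segs]))
        ten = float(np.mean([np.max(Ten[i0:i1 + 1]) - np.min(Ten[i0:i1 + 1])
                             for i0, ip, i1 in segs]))
        return cat, ten

    cat_s, ten_s = _peaks(strong)
    cat_w, ten_w = _peaks(weak)
    deltas = {
        "cat_peak_pct": (cat_s - cat_w) / cat_w * 100.0,
        "tension_peak_pct": (ten_s - ten_w) / ten_w * 100.0,
    }
    return strong, weak, deltas


def ctn_sweep(ctn_values, config: ProtocolConfig | None = None,
              initial: np.ndarray | None = None,
              normalize_to: float = 70.0) -> pd.DataFrame:
    """Mechanical summary versus percent of cardiomyocytes in the tissue.

    Returns a DataFrame indexed by ctn with fractional shortening and peak
    contraction/relaxation velocities, each also normalized to the
    ``normalize_to`` run (the study convention normalizes to 70%).
    """
    cfg = config or ProtocolConfig(settle=20.0, record=10.0)
    rows = {}
    vals = sorted(set(float(v) for v in ctn_values) | {float(normalize_to)})
    for ctn in vals:
        res = run(replace(cfg, ctn=ctn), initial=initial)
        mech = bm.mech_biomarkers(res.t, res["SL"], res["Tension"],
                                  n_beats=cfg.n_beats)
        rows[ctn] = {
            "frac_shortening": mech.frac_shortening,
            "peak_contraction_velocity": mech.peak_contraction_velocity,
            "peak_relaxation_velocity": mech.peak_relaxation_velocity,
        }
    df = pd.DataFrame(rows).T
    df.index.name = "ctn"
    ref = df.loc[float(normalize_to)]
    for col in list(df.columns):
        df[col + "_norm"] = df[col] / ref[col]
    return df.loc[[float(v) for v in ctn_values]]


# ---------------------------------------------------------------------------
# conductance-variant search for arrhythmia-capable model variants
#
# The two example sets below were found with `find_ead_variants` (repo
# search over [0.5, 2] factors); they are repo-generated illustrations of
# variants that develop early afterdepolarizations under strong I_Kr block,
# not published coefficient sets.
EXAMPLE_EAD_SETS = {
    "SET_A": {"I_CaL": 1.6, "I_NaL": 2.0, "I_Ks": 0.5},
    "SET_B": {"I_CaL": 1.5, "I_NaL": 1.8, "I_Ks": 0.6, "I_pCa": 0.5},
}


def find_ead_variants(n_trials: int = 20, seed: int = 0,
                      ikr_block: float = 0.95,
                      config: ProtocolConfig | None = None,
                      initial: np.ndarray | None = None) -> list[dict]:
    """Random search for conductance sets that develop EADs under block.

    Factors are drawn log-uniformly from [0.5, 2] for each scalable
    channel.  Returns the qualifying sets with their EAD and
    aftercontraction counts.
    """
    rng = np.random.default_rng(seed)
    cfg = config or ProtocolConfig(mode="spontaneous", settle=40.0,
                                   record=15.0)
    hits = []
    for _ in range(n_trials):
        factors = {ch: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                   for ch in SCALABLE_CHANNELS}
        try:
            res = ead_protocol(factors, ikr_block=ikr_block, config=cfg,
                               initial=initial)
        except IntegrationError:
            continue
        if res.ead_count > 0:
            hits.append({"factors": factors,
                         "ead_count": res.ead_count,
                         "aftercontraction_count": res.aftercontraction_count})
    return hits
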