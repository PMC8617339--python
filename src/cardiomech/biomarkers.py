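"""Extraction of AP, Ca2+-transient and mechanical biomarkers.

All functions accept a time axis in seconds together with the respective
trace (membrane potential in mV, cytosolic Ca2+ in mM, sarcomere length in
um, tension in kPa) at steady state and report time-based biomarkers in
milliseconds, averaged over the last ``n_beats`` complete beats.

Conventions:

* the action-potential activation time is the instant of maximum dV/dt
  during the upstroke; repolarization percentages are measured relative to
  the AP amplitude from the maximum diastolic potential (not from 0 mV);
* Ca2+-transient thresholds are computed on the diastole-to-peak
  normalized transient; its duration is measured between the 10% crossings;
* mechanical relaxation times RTx run from peak shortening to x% recovery
  of the twitch amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BiomarkerSet", "InsufficientBeatsError",
    "detect_upstrokes", "ap_biomarkers", "cat_biomarkers", "mech_biomarkers",
]


class InsufficientBeatsError(ValueError):
    """Raised when a trace contains fewer complete beats than required."""


@dataclass
class BiomarkerSet:
    """AP, CaT and mechanical biomarkers of one steady-state recording."""

    # action potential
    APA: float | None = None            # mV
    MDP: float | None = None            # mV
    CL: float | None = None             # ms
    dVdt_max: float | None = None       # V/s
    APD10: float | None = None          # ms
    APD30: float | None = None          # ms
    APD90: float | None = None          # ms
    AP_tri: float | None = None         # dimensionless
    # calcium transient
    CaT_duration: float | None = None   # ms
    tRise10_peak: float | None = None   # ms
    tRise10_50: float | None = None     # ms
    tRise10_90: float | None = None     # ms
    tDecay90_10: float | None = None    # ms
    # mechanics
    frac_shortening: float | None = None    # %
    RT25: float | None = None           # ms
    RT50: float | None = None           # ms
    RT80: float | None = None           # ms
    peak_tension: float | None = None   # kPa
    peak_contraction_velocity: float | None = None  # um/s (magnitude)
    peak_relaxation_velocity: float | None = None   # um/s
    n_beats_used: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def merge(self, other: "BiomarkerSet") -> "BiomarkerSet":
        merged = BiomarkerSet(**self.__dict__)
        for k, v in other.__dict__.items():
            if v is not None and k != "n_beats_used":
                setattr(merged, k, v)
        merged.n_beats_used = max(self.n_beats_used, other.n_beats_used)
        return merged


def _crossing(t, x, level, i0, i1, rising):
    """Linearly interpolated time where x crosses `level` in [i0, i1)."""
    seg_t = t[i0:i1]
    seg_x = x[i0:i1]
    if rising:
        idx = np.nonzero((seg_x[:-1] < level) & (seg_x[1:] >= level))[0]
    else:
        idx = np.nonzero((seg_x[:-1] > level) & (seg_x[1:] <= level))[0]
    if idx.size == 0:
        return None
    k = idx[0]
    x0, x1 = seg_x[k], seg_x[k + 1]
    if x1 == x0:
        return seg_t[k]
    return seg_t[k] + (level - x0) / (x1 - x0) * (seg_t[k + 1] - seg_t[k])


def detect_upstrokes(t: np.ndarray, V: np.ndarray,
                     dvdt_threshold: float = 1.0,
                     refractory: float = 0.1) -> np.ndarray:
    """Times (s) of positive-going AP upstrokes.

    An upstroke is a crossing of dV/dt above ``dvdt_threshold`` (V/s, i.e.
    mV/ms) with a ``refractory`` dead time (s) after each detection, so
    notches on a single upstroke are not double-counted.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    dvdt = np.gradient(V, t) / 1000.0  # mV and s -> V/s
    above = dvdt > dvdt_threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    times = []
    last = -np.inf
    for k in crossings:
        if t[k] - last >= refractory:
            times.append(t[k])
            last = t[k]
    return np.asarray(times)


def _default_triangulation(apd10, apd30, apd90):
    # family-convention shape index of repolarization; configurable because
    # published definitions vary between labs
    return (apd90 - apd10) / (apd90 - apd30)


def ap_biomarkers(t: np.ndarray, V: np.ndarray, n_beats: int = 3,
                  dvdt_threshold: float = 1.0,
                  triangulation: Callable | None = None) -> BiomarkerSet:
    """Action-potential biomarkers from a steady-state V(t) trace (mV)."""
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    ups = detect_upstrokes(t, V, dvdt_threshold=dvdt_threshold)
    if ups.size < n_beats + 1:
        raise InsufficientBeatsError(
            f"need at least {n_beats + 1} upstrokes, found {ups.size}")
    dvdt = np.gradient(V, t) / 1000.0  # V/s

    apas, mdps, dvdts, apd10s, apd30s, apd90s, acts = [], [], [], [], [], [], []
    use = ups[-(n_beats + 1):]
    for u0, u1 in zip(use[:-1], use[1:]):
        i0 = int(np.searchsorted(t, u0))
        i1 = int(np.searchsorted(t, u1))
        if i1 - i0 < 4:
            continue
        # activation: maximum upstroke velocity near the detected upstroke
        iwin = int(np.searchsorted(t, min(u0 + 0.05, t[i1 - 1])))
        k_act = i0 + int(np.argmax(dvdt[i0:max(iwin, i0 + 2)]))
        t_act = t[k_act]
        k_peak = i0 + int(np.argmax(V[i0:i1]))
        v_peak = V[k_peak]
        mdp = float(np.min(V[i0:i1]))
        apa = v_peak - mdp
        acts.append(t_act)
        apas.append(apa)
        mdps.append(mdp)
        dvdts.append(float(dvdt[k_act]))
        beat_apds = {}
        for pct, store in ((10, apd10s), (30, apd30s), (90, apd90s)):
            level = v_peak - pct / 100.0 * apa
            tc = _crossing(t, V, level, k_peak, i1, rising=False)
            if tc is not None:
                store.append((tc - t_act) * 1000.0)
    if len(apas) < n_beats or len(apd90s) < n_beats:
        raise InsufficientBeatsError("could not measure enough complete beats")

    cl = float(np.mean(np.diff(ups[-(n_beats + 1):]))) * 1000.0
    bm = BiomarkerSet(
        APA=float(np.mean(apas)),
        MDP=float(np.mean(mdps)),
        CL=cl,
        dVdt_max=float(np.mean(dvdts)),
        APD10=float(np.mean(apd10s)),
        APD30=float(np.mean(apd30s)),
        APD90=float(np.mean(apd90s)),
        n_beats_used=len(apas),
    )
    tri = triangulation or _default_triangulation
    bm.AP_tri = float(tri(bm.APD10, bm.APD30, bm.APD90))
    return bm


def _segment_transients(t, x, n_beats):
    """Peak-based segmentation of a periodic transient.

    Returns a list of (i_start, i_peak, i_end) index triples for the last
    ``n_beats`` complete transients, where start/end are the flanking
    minima.
    """
    rng = float(np.max(x) - np.min(x))
    if rng <= 0:
        return []
    peaks, _ = find_peaks(x, prominence=0.25 * rng)
    if peaks.size < 3:
        return []
    # (start, peak, end): flanking minima of each interior peak
    out = []
    for k in range(1, len(peaks) - 1):
        i_start = peaks[k - 1] + int(np.argmin(x[peaks[k - 1]:peaks[k]]))
        i_end = peaks[k] + int(np.argmin(x[peaks[k]:peaks[k + 1]]))
        out.append((i_start, peaks[k], i_end))
    return out[-n_beats:]


def cat_biomarkers(t: np.ndarray, Ca: np.ndarray,
                   n_beats: int = 3) -> BiomarkerSet:
    """Ca2+-transient biomarkers from a steady-state Cai(t) trace.

    Thresholds are computed per beat on the diastole-to-peak normalized
    transient, so the result is invariant to scaling the trace by any
    positive constant.
    """
    t = np.asarray(t, float)
    Ca = np.asarray(Ca, float)
    segs = _segment_transients(t, Ca, n_beats)
    if len(segs) < n_beats:
        raise InsufficientBeatsError(
            f"need {n_beats} complete transients, found {len(segs)}")

    t10p, t1050, t1090, tdec, dur = [], [], [], [], []
    for i0, ip, i1 in segs:
        dia = float(np.min(Ca[i0:ip]))
        peak = float(Ca[ip])
        amp = peak - dia
        if amp <= 0:
            continue
        lv = lambda pct: dia + pct / 100.0 * amp
        tr10 = _crossing(t, Ca, lv(10), i0, ip + 1, rising=True)
        tr50 = _crossing(t, Ca, lv(50), i0, ip + 1, rising=True)
        tr90 = _crossing(t, Ca, lv(90), i0, ip + 1, rising=True)
        td90 = _crossing(t, Ca, lv(90), ip, i1 + 1, rising=False)
        td10 = _crossing(t, Ca, lv(10), ip, i1 + 1, rising=False)
        if None in (tr10, tr50, tr90, td90, td10):
            continue
        t10p.append((t[ip] - tr10) * 1000.0)
        t1050.append((tr50 - tr10) * 1000.0)
        t1090.append((tr90 - tr10) * 1000.0)
        tdec.append((td10 - td90) * 1000.0)
        dur.append((td10 - tr10) * 1000.0)
    if len(dur) < n_beats:
        raise InsufficientBeatsError("could not measure enough transients")
    return BiomarkerSet(
        CaT_duration=float(np.mean(dur)),
        tRise10_peak=float(np.mean(t10p)),
        tRise10_50=float(np.mean(t1050)),
        tRise10_90=float(np.mean(t1090)),
        tDecay90_10=float(np.mean(tdec)),
        n_beats_used=len(dur),
    )


def mech_biomarkers(t: np.ndarray, SL: np.ndarray,
                    tension: np.ndarray | None = None,
                    n_beats: int = 3) -> BiomarkerSet:
    """Mechanical biomarkers from sarcomere-length (um) and tension traces.

    Fractional shortening is (diastolic SL - minimum SL)/diastolic SL x 100;
    RTx is the time from peak shortening to x% recovery of the twitch
    amplitude.  A flat SL trace yields a zero-shortening result with a
    warning rather than an error.
    """
    t = np.asarray(t, float)
    SL = np.asarray(SL, float)
    if np.ptp(SL) < 1e-6:
        warnings.warn("flat sarcomere-length trace: zero shortening")
        bm = BiomarkerSet(frac_shortening=0.0, n_beats_used=0)
        if tension is not None:
            bm.peak_tension = float(np.max(tension))
        return bm

    shortening = -SL  # twitches become positive peaks
    segs = _segment_transients(t, shortening, n_beats)
    if len(segs) < n_beats:
        raise InsufficientBeatsError(
            f"need {n_beats} complete twitches, found {len(segs)}")

    vel = np.gradient(SL, t)
    fs, rt25, rt50, rt80, pts, vcon, vrel = [], [], [], [], [], [], []
    for i0, ip, i1 in segs:
        sl_dia = float(np.max(SL[i0:ip]))
        sl_min = float(SL[ip])
        amp = sl_dia - sl_min
        if amp <= 0:
            continue
        fs.append((sl_dia - sl_min) / sl_dia * 100.0)
        for pct, store in ((25, rt25), (50, rt50), (80, rt80)):
            level = sl_min + pct / 100.0 * amp
            tc = _crossing(t, SL, level, ip, i1 + 1, rising=True)
            if tc is not None:
                store.append((tc - t[ip]) * 1000.0)
        if tension is not None:
            pts.append(float(np.max(tension[i0:i1 + 1])))
        vcon.append(float(-np.min(vel[i0:i1 + 1])))
        vrel.append(float(np.max(vel[i0:i1 + 1])))
    if len(fs) < n_beats:
        raise InsufficientBeatsError("could not measure enough twitches")
    bm = BiomarkerSet(
        frac_shortening=float(np.mean(fs)),
        RT25=float(np.mean(rt25)) if rt25 else None,
        RT50=float(np.mean(rt50)) if rt50 else None,
        RT80=float(np.mean(rt80)) if rt80 else None,
        peak_contraction_velocity=float(np.mean(vcon)),
        peak_relaxation_velocity=float(np.mean(vrel)),
        n_beats_used=len(fs),
    )
    if pts:
        bm.peak_tension = float(np.mean(pts))
    return bm
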