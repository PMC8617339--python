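"""Electrophysiology public surface: named state, currents, and RHS.

The compiled core (:mod:`cardiomech.engine`) evaluates the full coupled
system on flat vectors; this module exposes the ionic half on its own:

* :class:`IonicState` — named, validated view of the 22 ionic states;
* :class:`CurrentSet` — all 13 membrane currents plus the stimulus (A/F);
* :func:`compute_currents` — currents at one instant;
* :func:`ionic_rhs` — ionic derivatives with an *external* myofilament
  Ca2+ flux, for use when the contractile element is integrated (or
  prescribed) separately.
"""

from __future__ import annotations

import math
from dataclasses import astuple, dataclass, fields

import numpy as np

from . import engine
from .layout import NSTATE, STATE_FIELDS
from .parameters import IonicParameters, ModelParameters, pack

__all__ = ["IonicState", "CurrentSet", "compute_currents", "ionic_rhs",
           "InvalidStateError"]

#: ionic state names in core order
IONIC_FIELDS = STATE_FIELDS[:22]

#: states constrained to [0, 1] (Hodgkin-Huxley gates and RyR open/closed
#: fractions; RyRa is an adaptation level, not a fraction)
GATES = ("d", "f1", "f2", "fCa", "h", "j", "m", "Xf", "q", "r",
         "mL", "hL", "RyRo", "RyRc")


class InvalidStateError(ValueError):
    """An ionic state component violates its invariant."""


@dataclass
class IonicState:
    """Named view of the ionic state vector (V in volts, mM, seconds)."""

    Vm: float
    CaSR: float
    Cai: float
    d: float
    f1: float
    f2: float
    fCa: float
    h: float
    j: float
    m: float
    Xf: float
    q: float
    r: float
    Nai: float
    mL: float
    hL: float
    RyRa: float
    RyRo: float
    RyRc: float
    Xr1: float
    Xr2: float
    Xs: float

    def to_vector(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)

    @classmethod
    def from_vector(cls, y) -> "IonicState":
        y = np.asarray(y, dtype=float)
        if y.shape[0] < 22:
            raise ValueError("ionic state vector needs >= 22 entries")
        return cls(*y[:22])

    def validate(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not math.isfinite(v):
                raise InvalidStateError(f"non-finite state component {f_.name!r}")
        for g in GATES:
            v = getattr(self, g)
            if not (-1e-6 <= v <= 1.0 + 1e-6):
                raise InvalidStateError(f"gate {g!r}={v} outside [0, 1]")
        for c in ("Cai", "CaSR", "Nai"):
            if getattr(self, c) <= 0:
                raise InvalidStateError(f"concentration {c!r} must be > 0")


@dataclass
class CurrentSet:
    """Membrane currents at one instant (A/F)."""

    I_Na: float
    I_NaL: float
    I_CaL: float
    I_f: float
    I_K1: float
    I_Kr: float
    I_Ks: float
    I_to: float
    I_NaCa: float
    I_NaK: float
    I_pCa: float
    I_bNa: float
    I_bCa: float
    I_stim: float

    def total(self) -> float:
        """Sum of membrane currents minus the stimulus (the -C dV/dt term)."""
        return (self.I_Na + self.I_NaL + self.I_CaL + self.I_f + self.I_K1
                + self.I_Kr + self.I_Ks + self.I_to + self.I_NaCa
                + self.I_NaK + self.I_pCa + self.I_bNa + self.I_bCa
                - self.I_stim)


def _full_vector(state: IonicState) -> np.ndarray:
    y = np.zeros(NSTATE)
    y[:22] = state.to_vector()
    y[30] = 1.9  # placeholder SL; the CE is inactive in these entry points
    return y


def _pack_ionic(params: IonicParameters, I_stim: float,
                strong_buffer: bool) -> np.ndarray:
    mp = ModelParameters(ionic=params, ce_active=False,
                         coupling="strong" if strong_buffer else "weak",
                         buffer_troponin_subtraction=strong_buffer)
    return pack(mp, I_stim=I_stim)


def compute_currents(state: IonicState, params: IonicParameters | None = None,
                     t: float = 0.0, I_stim: float = 0.0) -> CurrentSet:
    """All 13 membrane currents (plus stimulus) at the given state."""
    p = params or IonicParameters()
    state.validate()
    out = engine.full_outputs(t, _full_vector(state), _pack_ionic(p, I_stim, False))
    return CurrentSet(
        I_Na=out[0], I_NaL=out[1], I_CaL=out[2], I_f=out[3], I_K1=out[4],
        I_Kr=out[5], I_Ks=out[6], I_to=out[7], I_NaCa=out[8], I_NaK=out[9],
        I_pCa=out[10], I_bNa=out[11], I_bCa=out[12], I_stim=out[13],
    )


def ionic_rhs(t: float, state: IonicState | np.ndarray,
              params: IonicParameters | None = None,
              J_myofilament: float = 0.0, I_stim: float = 0.0,
              subtract_troponin_buffer: bool = False,
              troponin_total: float = 0.070) -> np.ndarray:
    """Derivatives of the 22 ionic states with an external myofilament flux.

    ``J_myofilament`` (mM/s, positive = Ca2+ toward the myofilament) is
    subtracted from the free-Ca2+ balance through the instantaneous-buffer
    factor.  With ``subtract_troponin_buffer=True`` the troponin share is
    also removed from the static cytosolic buffer (strong-coupling
    convention); the default reproduces the standalone ionic model exactly
    when ``J_myofilament = 0``.
    """
    p = params or IonicParameters()
    if not math.isfinite(J_myofilament):
        raise InvalidStateError("non-finite J_myofilament")
    if isinstance(state, IonicState):
        st = state
    else:
        st = IonicState.from_vector(state)
    st.validate()
    P = _pack_ionic(p, I_stim, subtract_troponin_buffer)
    dy = engine.full_rhs(t, _full_vector(st), P)[:22]
    if J_myofilament != 0.0:
        Buf_eff = p.Buf_C - (troponin_total if subtract_troponin_buffer else 0.0)
        cai_buf = 1.0 / (1.0 + Buf_eff * p.Kbuf_C / (st.Cai + p.Kbuf_C) ** 2)
        dy[2] -= cai_buf * J_myofilament
    return dy
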