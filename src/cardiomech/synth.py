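"""Synthetic Ca2+-transient waveform generator for CE-only testing.

Produces an idealized periodic cytosolic Ca2+ transient: a smooth rise
to ``diastolic + amplitude`` at ``time_to_peak`` followed by a
monoexponential decay toward the diastolic level.  Used to drive the
contractile element without the ionic model (fixtures and the CE-only
CLI driver).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyntheticCaT", "generate_cat_waveform"]


@dataclass
class SyntheticCaT:
    """Parametric Ca2+-transient shape (concentrations in mM, times in ms)."""

    diastolic: float = 1.8e-5   # mM
    amplitude: float = 1.55e-4  # mM
    time_to_peak: float = 80.0  # ms
    tau_decay: float = 180.0    # ms
    frequency_hz: float = 1.0

    def validate(self) -> None:
        if self.diastolic <= 0:
            raise ValueError("diastolic level must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.time_to_peak <= 0 or self.tau_decay <= 0:
            raise ValueError("time-to-peak and decay constant must be > 0")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        if self.time_to_peak >= 1000.0 / self.frequency_hz:
            raise ValueError("time-to-peak exceeds the cycle length")


def _single_transient(phase_ms: np.ndarray, spec: SyntheticCaT) -> np.ndarray:
    """Normalized transient (0 at diastole, 1 at peak) over one cycle."""
    ttp = spec.time_to_peak
    up = phase_ms < ttp
    out = np.empty_like(phase_ms)
    # smooth half-cosine rise reaches exactly 1 at time_to_peak
    out[up] = 0.5 * (1.0 - np.cos(np.pi * phase_ms[up] / ttp))
    out[~up] = np.exp(-(phase_ms[~up] - ttp) / spec.tau_decay)
    return out


def generate_cat_waveform(spec: SyntheticCaT, duration: float,
                          dt: float) -> pd.DataFrame:
    """Periodic synthetic Ca2+ waveform table with columns ``t`` (s), ``Cai`` (mM).

    ``dt`` must resolve the upstroke (``dt < time_to_peak/10``).
    """
    spec.validate()
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be > 0")
    if dt * 1000.0 >= spec.time_to_peak / 10.0:
        raise ValueError("dt too coarse: need dt < time_to_peak/10")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    period_ms = 1000.0 / spec.frequency_hz
    phase = np.mod(t * 1000.0, period_ms)
    cai = spec.diastolic + spec.amplitude * _single_transient(phase, spec)
    return pd.DataFrame({"t": t, "Cai": cai})
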