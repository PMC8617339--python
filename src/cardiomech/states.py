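"""State-vector helpers and shipped steady-state initial conditions.

The coupled model takes hundreds of seconds of spontaneous activity to
reach its limit cycle from a cold start.  Pre-equilibrated state vectors
(obtained by running the model for 800 s spontaneous / several hundred
paced beats; see ``scripts/make_steady_states.py``) are shipped as JSON
under ``cardiomech/states`` so protocols can start a few beats away from
steady state.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .layout import NSTATE, STATE_FIELDS, STATE_INDEX

__all__ = ["cold_start_state", "default_state", "load_state", "save_state",
           "as_dict", "from_dict", "available_states"]


def cold_start_state() -> np.ndarray:
    """A physiologically plausible but non-equilibrated starting state."""
    y = np.zeros(NSTATE)
    s = STATE_INDEX
    y[s["Vm"]] = -0.075
    y[s["CaSR"]] = 0.32
    y[s["Cai"]] = 5e-5
    y[s["d"]] = 1e-4
    y[s["f1"]] = 0.95
    y[s["f2"]] = 1.0
    y[s["fCa"]] = 1.0
    y[s["h"]] = 0.75
    y[s["j"]] = 0.74
    y[s["m"]] = 0.03
    y[s["Xf"]] = 0.1
    y[s["q"]] = 0.84
    y[s["r"]] = 0.005
    y[s["Nai"]] = 9.2
    y[s["mL"]] = 0.003
    y[s["hL"]] = 0.75
    y[s["RyRa"]] = 0.03
    y[s["RyRo"]] = 0.01
    y[s["RyRc"]] = 0.99
    y[s["Xr1"]] = 0.01
    y[s["Xr2"]] = 0.48
    y[s["Xs"]] = 0.03
    y[s["N"]] = 0.97
    y[s["XBprer"]] = 1e-4
    y[s["XBpostr"]] = 1e-4
    y[s["xXBprer"]] = 0.0
    y[s["xXBpostr"]] = 0.007
    y[s["TRPNCaL"]] = 0.02
    y[s["TRPNCaH"]] = 0.13
    y[s["N_NoXB"]] = 0.97
    y[s["SL"]] = 1.9
    y[s["intf"]] = 0.0
    return y


def as_dict(y: np.ndarray) -> dict[str, float]:
    return {name: float(y[i]) for i, name in enumerate(STATE_FIELDS)}


def from_dict(d: dict[str, float]) -> np.ndarray:
    y = np.zeros(NSTATE)
    for name, v in d.items():
        if name not in STATE_INDEX:
            raise KeyError(f"unknown state variable {name!r}")
        y[STATE_INDEX[name]] = float(v)
    return y


def save_state(y: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        json.dump(as_dict(y), fh, indent=1)


def load_state(path) -> np.ndarray:
    with open(path) as fh:
        return from_dict(json.load(fh))


def available_states() -> list[str]:
    pkg = resources.files("cardiomech") / "states"
    return sorted(p.name.removesuffix(".json")
                  for p in pkg.iterdir() if p.name.endswith(".json"))


def default_state(name: str = "spontaneous_strong") -> np.ndarray:
    """Shipped pre-equilibrated state, or a cold start if not available.

    Names follow ``<mode>_<coupling>`` (e.g. ``spontaneous_strong``,
    ``paced1hz_strong``, ``spontaneous_weak``).
    """
    res = resources.files("cardiomech") / "states" / f"{name}.json"
    if res.is_file():
        return from_dict(json.loads(res.read_text()))
    return cold_start_state()
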