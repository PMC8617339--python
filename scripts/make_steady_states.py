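"""Regenerate the shipped pre-equilibrated state vectors.

Runs the baseline model to its limit cycle for each protocol/coupling
combination and writes the final states as JSON into
``src/cardiomech/states``.  Slow (tens of minutes): run only when model
constants change.

Usage:  python scripts/make_steady_states.py [--spont 800] [--paced 400]
"""

import argparse
import math
import time
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from cardiomech.engine import full_rhs
from cardiomech.layout import PARAM_INDEX
from cardiomech.parameters import ModelParameters, pack
from cardiomech.states import as_dict, cold_start_state

OUT = Path(__file__).resolve().parents[1] / "src" / "cardiomech" / "states"


def settle_spontaneous(coupling: str, duration: float) -> np.ndarray:
    P = pack(ModelParameters(coupling=coupling))
    sol = solve_ivp(full_rhs, (0.0, duration), cold_start_state(),
                    method="LSODA", rtol=1e-7, atol=1e-10, args=(P,))
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol.y[:, -1]


def settle_paced(coupling: str, freq: float, duration: float,
                 stim_A: float = 5.5e-10, stim_dur: float = 0.005,
                 start: np.ndarray | None = None) -> np.ndarray:
    mp = ModelParameters(coupling=coupling)
    P = pack(mp)
    amp = stim_A / P[PARAM_INDEX["Cm"]]
    y = cold_start_state() if start is None else start.copy()
    period = 1.0 / freq
    n_beats = int(math.ceil(duration * freq))
    for k in range(n_beats):
        t0 = k * period
        P[PARAM_INDEX["I_stim"]] = amp
        sol = solve_ivp(full_rhs, (t0, t0 + stim_dur), y, method="LSODA",
                        rtol=1e-7, atol=1e-10, args=(P,))
        y = sol.y[:, -1]
        P[PARAM_INDEX["I_stim"]] = 0.0
        sol = solve_ivp(full_rhs, (t0 + stim_dur, t0 + period), y,
                        method="LSODA", rtol=1e-7, atol=1e-10, args=(P,))
        y = sol.y[:, -1]
    return y


def save(name: str, y: np.ndarray) -> None:
    import json
    path = OUT / f"{name}.json"
    path.write_text(json.dumps(as_dict(y), indent=1))
    print(f"wrote {path}")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--spont", type=float, default=800.0,
                    help="spontaneous settling duration (s)")
    ap.add_argument("--paced", type=float, default=300.0,
                    help="paced settling duration (s)")
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    for coupling in ("strong", "weak"):
        t0 = time.time()
        y = settle_spontaneous(coupling, args.spont)
        save(f"spontaneous_{coupling}", y)
        print(f"  ({time.time() - t0:.0f} s)")
        for freq, label in ((1.0, "paced1hz"), (1.5, "paced1.5hz")):
            t0 = time.time()
            yp = settle_paced(coupling, freq, args.paced, start=y)
            save(f"{label}_{coupling}", yp)
            print(f"  ({time.time() - t0:.0f} s)")


if __name__ == "__main__":
    main()
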