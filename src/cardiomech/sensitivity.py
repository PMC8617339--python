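"""One-at-a-time +/-15% parameter sensitivity of mechanical biomarkers.

Indices (per biomarker ``b`` and parameter ``p``):

* percentage change   ``D_{b,p,+/-15%} = (b_pert - b_ctl)/b_ctl * 100``
* sensitivity         ``S_{b,p} = (D_{+15%} - D_{-15%}) / 0.3``
* relative sensitivity ``r_{b,p} = S_{b,p} / max_p |S_{b,p}|`` (per row)

The driver perturbs contractile-element parameters one at a time,
re-establishes steady state for each perturbed run, extracts the
mechanical biomarkers, and assembles the three index tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import CEParameters

__all__ = [
    "percent_change",
    "sensitivity_index",
    "relative_sensitivity",
    "SensitivityResult",
    "oat_sensitivity",
    "DEFAULT_CE_PARAMS",
    "DEFAULT_BIOMARKERS",
]

#: Table-1 tunables analysed by default
DEFAULT_CE_PARAMS = ("Kon", "KoffL", "KoffH", "Koffmod", "perm50", "nperm",
                     "kn_p", "kp_n", "mass", "kxb", "xbmodsp")
#: mechanical biomarkers analysed by default
DEFAULT_BIOMARKERS = ("peak_tension", "frac_shortening", "RT50")


def percent_change(b_perturbed: float, b_ctl: float) -> float:
    """Percentage change of a biomarker relative to control."""
    if b_ctl == 0:
        raise ZeroDivisionError("control biomarker is 0; percent change undefined")
    return (b_perturbed - b_ctl) / b_ctl * 100.0


def sensitivity_index(D_plus: float, D_minus: float) -> float:
    """Central-difference sensitivity from the +/-15% percentage changes."""
    return (D_plus - D_minus) / 0.3


def relative_sensitivity(S_matrix) -> np.ndarray:
    """Row-normalize a (biomarker x parameter) sensitivity matrix to [-1, 1].

    Each row is divided by its maximum absolute entry; an all-zero row is
    returned unchanged with a warning.
    """
    S = np.atleast_2d(np.asarray(S_matrix, dtype=float))
    r = np.zeros_like(S)
    for i in range(S.shape[0]):
        m = np.max(np.abs(S[i]))
        if m == 0:
            warnings.warn(f"sensitivity row {i} is all zero; "
                          "relative sensitivities set to 0")
            continue
        r[i] = S[i] / m
    return r


@dataclass
class SensitivityResult:
    """Long-format deltas plus wide S and r matrices."""

    biomarkers: tuple
    parameters: tuple
    control: dict
    D_plus: pd.DataFrame     # biomarker x parameter, percent
    D_minus: pd.DataFrame
    S: pd.DataFrame
    r: pd.DataFrame
    failures: list = field(default_factory=list)

    def long_format(self) -> pd.DataFrame:
        """`biomarker,parameter,direction,D,S,r` rows (CSV-ready)."""
        rows = []
        for b in self.biomarkers:
            for p in self.parameters:
                for direction, D in (("+15%", self.D_plus),
                                     ("-15%", self.D_minus)):
                    rows.append({
                        "biomarker": b, "parameter": p,
                        "direction": direction, "D": D.loc[b, p],
                        "S": self.S.loc[b, p], "r": self.r.loc[b, p],
                    })
        return pd.DataFrame(rows)


def oat_sensitivity(evaluate, params: CEParameters | None = None,
                    parameter_names=DEFAULT_CE_PARAMS,
                    biomarker_names=DEFAULT_BIOMARKERS,
                    delta: float = 0.15) -> SensitivityResult:
    """One-at-a-time +/-``delta`` sensitivity around ``params``.

    ``evaluate(ce_params) -> dict`` must run the model to steady state and
    return the biomarkers named in ``biomarker_names``.  Parameters whose
    perturbed run fails are recorded in ``failures`` with NaN entries.
    """
    base = params or CEParameters()
    ctl = evaluate(base)
    missing = [b for b in biomarker_names if b not in ctl]
    if missing:
        raise KeyError(f"evaluate() did not return biomarkers: {missing}")

    idx = list(biomarker_names)
    cols = list(parameter_names)
    Dp = pd.DataFrame(np.nan, index=idx, columns=cols)
    Dm = pd.DataFrame(np.nan, index=idx, columns=cols)
    failures = []
    for pname in cols:
        base_val = getattr(base, pname)
        for sign, D in ((+1.0, Dp), (-1.0, Dm)):
            pert = replace(base, **{pname: base_val * (1.0 + sign * delta)})
            try:
                vals = evaluate(pert)
            except Exception as exc:  # noqa: BLE001 - record and continue
                failures.append((pname, sign * delta, repr(exc)))
                continue
            for b in idx:
                D.loc[b, pname] = percent_change(vals[b], ctl[b])

    S = (Dp - Dm) / 0.3
    r = pd.DataFrame(relative_sensitivity(S.to_numpy()),
                     index=idx, columns=cols)
    return SensitivityResult(
        biomarkers=tuple(idx), parameters=tuple(cols),
        control={b: ctl[b] for b in idx},
        D_plus=Dp, D_minus=Dm, S=S, r=r, failures=failures,
    )
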