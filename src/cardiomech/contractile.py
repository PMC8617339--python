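"""Myofilament contractile element: public API and analysis helpers.

The time-critical CE kinetics live in the compiled core
(:mod:`cardiomech.engine`); this module provides the domain-facing surface:

* :class:`CEState` — named view of the 10-component CE state vector;
* :func:`thin_filament_overlap` — single-overlap fraction vs. sarcomere
  length (Rice-2008 geometry);
* :func:`passive_force` — piecewise titin/collagen passive force with the
  tissue-composition (``ctn``) scaling;
* :func:`active_tension` — tension (kPa) = ``kxb``  x normalized active force;
* :func:`ce_rhs` / :func:`sl_dynamics` — derivative wrappers;
* :func:`steady_state_force` — *independent* algebraic solution of the
  clamped-Ca2+, isosarcometric steady state (closed form, no ODE
  integration) used as a cross-check oracle for the dynamic core;
* :func:`skinned_tension_sl_curve` — steady-state tension-SL relation;
* :func:`driven_twitch` — CE-only simulation driven by a prescribed
  Ca2+ waveform.
"""

from __future__ import annotations

import math
from dataclasses import astuple, dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .engine import ce_outputs_driven, ce_rhs_driven
from .parameters import CEParameters, ModelParameters, PassiveForceConfig, pack

__all__ = [
    "CEState",
    "resting_ce_state",
    "thin_filament_overlap",
    "passive_force",
    "titin_force",
    "collagen_force",
    "active_tension",
    "ce_rhs",
    "sl_dynamics",
    "steady_state_force",
    "skinned_tension_sl_curve",
    "driven_twitch",
]


@dataclass
class CEState:
    """Named view of the contractile-element state vector.

    ``N``/``N_NoXB`` are nonpermissive regulatory-unit fractions (with and
    without cross-bridge participation), ``XB_prer``/``XB_postr`` the
    strongly-bound cross-bridge occupancies before/after the powerstroke
    with mean strains ``x_prer``/``x_postr`` (um), ``TropL``/``TropH`` the
    fractional Ca2+ occupancy of the low-/high-affinity troponin regulatory
    sites, ``SL`` the sarcomere length (um) and ``intf`` the integral of
    net normalized force.
    """

    N: float
    XB_prer: float
    XB_postr: float
    x_prer: float
    x_postr: float
    TropL: float
    TropH: float
    N_NoXB: float
    SL: float
    intf: float

    def to_vector(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)

    @classmethod
    def from_vector(cls, y) -> "CEState":
        y = np.asarray(y, dtype=float)
        if y.shape != (10,):
            raise ValueError(f"CE state vector must have 10 entries, got {y.shape}")
        return cls(*y)

    @property
    def permissive(self) -> float:
        """Permissive regulatory-unit fraction (conservation closure)."""
        return 1.0 - self.N - self.XB_prer - self.XB_postr

    def validate(self) -> None:
        for name in ("N", "XB_prer", "XB_postr", "TropL", "TropH", "N_NoXB"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"CE occupancy {name}={v} outside [0, 1]")
        if not math.isfinite(self.SL):
            raise ValueError("non-finite sarcomere length")


def resting_ce_state(params: CEParameters | None = None) -> CEState:
    """Relaxed diastolic CE state at the rest sarcomere length."""
    p = params or CEParameters()
    return CEState(N=0.97, XB_prer=0.01, XB_postr=0.01,
                   x_prer=0.0, x_postr=p.x_0,
                   TropL=0.01, TropH=0.1, N_NoXB=0.97,
                   SL=p.SL_rest, intf=0.0)


def thin_filament_overlap(SL: float, params: CEParameters | None = None) -> float:
    """Thin-filament single-overlap fraction at sarcomere length ``SL`` (um).

    Piecewise-linear in SL from the two-filament geometry: the overlap zone
    runs from the thick-filament tip (or the thin-filament tip, whichever is
    shorter) down to the bare zone.
    """
    p = params or CEParameters()
    if not (p.SLmin <= SL <= p.SLmax):
        raise ValueError(f"SL={SL} um outside valid range "
                         f"[{p.SLmin}, {p.SLmax}] um")
    sovr_ze = min(p.len_thick / 2.0, SL / 2.0)
    sovr_cle = max(p.len_thin - SL / 2.0, p.len_hbare / 2.0)
    return (sovr_ze - sovr_cle) / p.len_thin


def titin_force(SL: float, params: CEParameters | None = None) -> float:
    """Signed titin passive force (normalized), zero at the rest length."""
    p = params or CEParameters()
    d = SL - p.SL_rest
    if d >= 0.0:
        return p.PCon_t * (math.exp(p.PExp_t * d) - 1.0)
    return -p.PCon_t * (math.exp(-p.PExp_t * d) - 1.0)


def collagen_force(SL: float, params: CEParameters | None = None) -> float:
    """Collagen passive force (normalized); engages above its slack length."""
    p = params or CEParameters()
    if SL >= p.SL_collagen:
        return p.PCon_c * (math.exp(p.PExp_c * (SL - p.SL_collagen)) - 1.0)
    return 0.0


def passive_force(SL: float, cfg: PassiveForceConfig | None = None,
                  params: CEParameters | None = None) -> float:
    """Piecewise passive force vs. tissue cardiomyocyte percentage ``ctn``.

    A pure cardiomyocyte (``ctn = 100``) feels titin only.  Below 100% the
    non-myocyte matrix adds a collagen branch, scaled by one of two
    empirical prefactors with the break at ``ctn = 70`` (the 70% boundary
    itself uses the upper branch).
    """
    cfg = cfg or PassiveForceConfig()
    p = params or CEParameters()
    ft = titin_force(SL, p)
    if cfg.ctn >= 100.0:
        return ft
    fc = collagen_force(SL, p)
    c = cfg.c
    if cfg.ctn >= 70.0:
        return 10.54 * (4.66 * math.exp(-3.05 * c ** 4.9)) * (ft + fc)
    return (6.0 * math.exp(-6.17 * c ** 2.91)) * (ft + fc)


def _pack_ce(params: CEParameters | None, cfg: PassiveForceConfig | None,
             isosarcometric: bool) -> np.ndarray:
    mp = ModelParameters(ce=params or CEParameters(),
                         tissue=cfg or PassiveForceConfig(),
                         isosarcometric=isosarcometric)
    return pack(mp)


def active_tension(ce: CEState | np.ndarray,
                   params: CEParameters | None = None) -> float:
    """Active tension in kPa: ``kxb`` times the normalized active force."""
    p = params or CEParameters()
    y = ce.to_vector() if isinstance(ce, CEState) else np.asarray(ce, float)
    out = ce_outputs_driven(y, 1e-4, _pack_ce(p, None, True))
    return out["Tension"]


def ce_rhs(t: float, ce: CEState | np.ndarray, Cai: float,
           params: CEParameters | None = None,
           cfg: PassiveForceConfig | None = None,
           mode: str = "free") -> np.ndarray:
    """Contractile-element derivatives for a prescribed cytosolic Ca2+.

    ``mode`` is ``"free"`` (sarcomere length follows the force balance) or
    ``"isosarcometric"`` (length clamped, dSL/dt = 0).
    """
    if mode not in ("free", "isosarcometric"):
        raise ValueError(f"mode must be 'free' or 'isosarcometric', got {mode!r}")
    if Cai <= 0:
        raise ValueError("Cai must be > 0")
    y = ce.to_vector() if isinstance(ce, CEState) else np.asarray(ce, float)
    P = _pack_ce(params, cfg, mode == "isosarcometric")
    return ce_rhs_driven(t, y, Cai, P)


def sl_dynamics(ce: CEState | np.ndarray,
                params: CEParameters | None = None) -> float:
    """dSL/dt from the integral-of-force, viscous recoil and mass.

    ``dSL/dt = (intf + (SL_set - SL) * visc) / mass``.
    """
    p = params or CEParameters()
    if p.mass <= 0:
        raise ValueError("mass must be > 0 for sarcomere-length dynamics")
    if isinstance(ce, CEState):
        SL, intf = ce.SL, ce.intf
    else:
        SL, intf = float(ce[8]), float(ce[9])
    return (intf + (p.SL_set - SL) * p.visc) / p.mass


# ---------------------------------------------------------------------------
# independent algebraic steady state (oracle for the dynamic core)

def steady_state_force(Cai: float, SL: float,
                       params: CEParameters | None = None) -> dict:
    """Closed-form clamped-Ca2+, isosarcometric steady state of the CE.

    Derivation (independent of the ODE core): at steady state the mean
    strain ODEs force ``x_prer = 0`` and ``x_postr = x_0`` (zero net strain
    drift), at which all strain-modulation factors are unity.  The
    four-pool cycle N <-> P <-> XB_prer <-> XB_postr is then a linear
    system solved under the conservation constraint, with the permissive
    transition rates evaluated at the equilibrium troponin occupancies.

    Returns a dict with the pool occupancies, troponin occupancies and
    ``F_active`` / ``Tension`` (kPa).
    """
    p = params or CEParameters()
    if Cai <= 0:
        raise ValueError("Cai must be > 0")
    tfac = (p.TmpC - 37.0) / 10.0

    # equilibrium troponin occupancies
    konT = p.Kon * p.Qkon ** tfac
    koffLT = p.KoffL * p.Koffmod * p.Qkoff ** tfac
    koffHT = p.KoffH * p.Koffmod * p.Qkoff ** tfac
    TropL = konT * Cai / (konT * Cai + koffLT)
    TropH = konT * Cai / (konT * Cai + koffHT)

    sovthin = thin_filament_overlap(SL, p)
    sovr_ze = min(p.len_thick / 2.0, SL / 2.0)
    sovr_cle = max(p.len_thin - SL / 2.0, p.len_hbare / 2.0)
    sovthick = 2.0 * (sovr_ze - sovr_cle) / (p.len_thick - p.len_hbare)

    tropreg = max((1.0 - sovthin) * TropL + sovthin * TropH, 1e-12)
    permtot = math.sqrt(1.0 / (1.0 + (p.perm50 / tropreg) ** p.nperm))
    inprmt = min(1.0 / permtot, 100.0)
    knp = p.kn_p * permtot * p.Qkn_p ** tfac
    kpn = p.kp_n * inprmt * p.Qkp_n ** tfac

    # cycle rates at the steady-state strains (strain factors = 1)
    fapp = p.fapp * p.xbmodsp * p.Qfapp ** tfac
    gapslmd = 1.0 + (1.0 - sovthick) * p.gslmod
    gapp = p.gapp * gapslmd * p.xbmodsp * p.Qgapp ** tfac
    hf = p.hf * p.xbmodsp * p.Qhf ** tfac
    hb = p.hb * p.xbmodsp * p.Qhb ** tfac
    gxb = p.gxb * p.xbmodsp * p.Qgxb ** tfac

    # steady cycle: XB_postr = hf/(hb+gxb) XB_prer;
    # XB_prer = fapp P / (gapp + hf - hb*hf/(hb+gxb)); N = kpn/knp P.
    a_post = hf / (hb + gxb)
    a_pre = fapp / (gapp + hf - hb * a_post)
    a_N = kpn / knp
    Pfrac = 1.0 / (1.0 + a_N + a_pre + a_pre * a_post)
    XBprer = a_pre * Pfrac
    XBpostr = a_post * XBprer
    N = a_N * Pfrac

    # duty-fraction normalization at base rates (as in the dynamic core)
    fb, gb, hfb, hbb, gxbb = p.fapp, p.gapp, p.hf, p.hb, p.gxb
    denom = (gxbb * hfb + fb * hfb + gxbb * gb + hbb * fb + hbb * gb + gb * hfb)
    ssXBpostr = fb * hfb / denom

    F_active = sovthick * XBpostr / ssXBpostr  # strains (0, x_0) cancel x_0
    return {
        "N": N, "P": Pfrac, "XB_prer": XBprer, "XB_postr": XBpostr,
        "TropL": TropL, "TropH": TropH, "permtot": permtot,
        "F_active": F_active, "Tension": p.kxb * F_active,
    }


def skinned_tension_sl_curve(Ca: float, SL_grid,
                             params: CEParameters | None = None,
                             settle: float = 5.0,
                             use_oracle: bool = False) -> np.ndarray:
    """Steady-state tension vs. sarcomere length at clamped Ca2+.

    Values are normalized to the curve maximum.  By default each point is
    obtained by integrating the CE to steady state at fixed SL; with
    ``use_oracle=True`` the closed-form :func:`steady_state_force` is used
    instead (the two agree to solver tolerance).
    """
    p = params or CEParameters()
    SL_grid = np.asarray(SL_grid, dtype=float)
    tensions = np.empty_like(SL_grid)
    for i, SL in enumerate(SL_grid):
        if use_oracle:
            tensions[i] = steady_state_force(Ca, SL, p)["Tension"]
            continue
        y0 = resting_ce_state(p).to_vector()
        y0[8] = SL
        P = _pack_ce(p, None, True)
        sol = solve_ivp(ce_rhs_driven, (0.0, settle), y0, method="LSODA",
                        rtol=1e-8, atol=1e-10, args=(Ca, P))
        tensions[i] = ce_outputs_driven(sol.y[:, -1], Ca, P)["Tension"]
    m = tensions.max()
    return tensions / m if m > 0 else tensions


def driven_twitch(t: np.ndarray, Cai: np.ndarray,
                  params: CEParameters | None = None,
                  cfg: PassiveForceConfig | None = None,
                  isosarcometric: bool = False,
                  y0: CEState | None = None,
                  rtol: float = 1e-7, atol: float = 1e-9) -> pd.DataFrame:
    """Integrate the CE alone, driven by a prescribed Ca2+ waveform.

    ``t`` (s) and ``Cai`` (mM) sample the waveform; linear interpolation in
    between.  Returns a DataFrame with the CE states and derived forces on
    the same time grid.
    """
    t = np.asarray(t, float)
    Cai = np.asarray(Cai, float)
    if t.ndim != 1 or t.shape != Cai.shape or len(t) < 2:
        raise ValueError("t and Cai must be matching 1-D arrays (n >= 2)")
    if np.any(Cai <= 0):
        raise ValueError("Cai waveform must be strictly positive")
    P = _pack_ce(params, cfg, isosarcometric)
    y_init = (y0 or resting_ce_state(params)).to_vector()

    def rhs(tt, y):
        ca = np.interp(tt, t, Cai)
        return ce_rhs_driven(tt, y, ca, P)

    sol = solve_ivp(rhs, (t[0], t[-1]), y_init, method="LSODA",
                    rtol=rtol, atol=atol, t_eval=t)
    if not sol.success:
        raise RuntimeError(f"CE integration failed: {sol.message}")
    rows = {k: np.empty(len(t)) for k in
            ("Tension", "F_active", "F_passive", "TropApr", "SOVFThin",
             "FrSBXB", "JCaBMyo")}
    for i in range(len(t)):
        out = ce_outputs_driven(sol.y[:, i], Cai[i], P)
        for k in rows:
            rows[k][i] = out[k]
    df = pd.DataFrame({"t": t, "Cai": Cai})
    for j, name in enumerate(("N", "XB_prer", "XB_postr", "x_prer",
                              "x_postr", "TropL", "TropH", "N_NoXB",
                              "SL", "intf")):
        df[name] = sol.y[j]
    for k, v in rows.items():
        df[k] = v
    return df
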