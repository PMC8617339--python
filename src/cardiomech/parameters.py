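"""Model parameters: electrophysiology, contractile element, tissue composition.

Three dataclasses hold the tunable constants:

* :class:`IonicParameters` — the hiPSC-CM electrophysiology (Paci-family
  formulation): maximal conductances, pump/exchanger constants, Ca2+
  handling, and per-channel scale multipliers.
* :class:`CEParameters` — the myofilament contractile element (Rice-2008
  formulation) with the hiPSC-CM recalibration applied to the Ca2+-troponin
  and regulatory-unit constants, plus sarcomere mechanics and the
  titin/collagen passive-force constants.
* :class:`PassiveForceConfig` — percent of cardiomyocytes in the tissue,
  the argument of the piecewise passive-force law.

``pack()`` flattens everything into the float64 vector consumed by the
compiled ODE core (see :mod:`cardiomech.layout`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .layout import NPARAM, PARAM_INDEX

__all__ = [
    "IonicParameters",
    "CEParameters",
    "PassiveForceConfig",
    "ModelParameters",
    "CHANNELS",
    "apply_channel_scaling",
    "pack",
    "provenance",
]

#: channel name -> multiplier attribute on IonicParameters
CHANNELS = {
    "I_Na": "s_Na",
    "I_NaL": "s_NaL",
    "I_CaL": "s_CaL",
    "I_f": "s_f",
    "I_K1": "s_K1",
    "I_Kr": "s_Kr",
    "I_Ks": "s_Ks",
    "I_to": "s_to",
    "I_NaCa": "s_NaCa",
    "I_NaK": "s_NaK",
    "I_pCa": "s_pCa",
    "I_bNa": "s_bNa",
    "I_bCa": "s_bCa",
}


@dataclass
class IonicParameters:
    """Electrophysiology constants of the spontaneously beating hiPSC-CM.

    Values follow the Paci-family model of hiPSC-CM electrophysiology in
    its 2020 parameterization (cytosol + SR compartments, Hodgkin-Huxley
    currents, funny current and Na/Ca-exchanger-driven automaticity).
    Units: volts, seconds, mM, A/F, S/F.
    """

    # cell geometry / environment
    Cm: float = 9.87109e-11     # F
    Vc: float = 8800.0          # um^3
    V_SR: float = 583.73        # um^3
    Nao: float = 151.0          # mM
    Ko: float = 5.4             # mM
    Cao: float = 1.8            # mM
    Ki: float = 150.0           # mM (clamped)
    T: float = 310.0            # K

    # Maximal rates marked "calibrated" below were fitted against the
    # published spontaneous AP/CaT biomarker tables of the coupled model
    # (uncoupled and coupled columns plus the coupling-feedback deltas);
    # the remaining kinetic constants are ionic-model-source values.

    # fast and late Na+
    g_Na: float = 3344.487920918987   # S/F (calibrated)
    g_NaL: float = 17.25        # S/F (2.3 * 7.5)
    tau_hL: float = 0.200       # s
    Vh_hL: float = 87.61        # mV
    # L-type Ca2+
    g_CaL: float = 1.1423204339125068e-4  # m^3/(F s) (calibrated)
    # K+ currents
    g_to: float = 44.26149507763696   # S/F (calibrated)
    g_Ks: float = 2.041         # S/F
    g_Kr: float = 44.43650211804262   # S/F (calibrated)
    L0_Kr: float = 0.025
    Q_Kr: float = 2.3
    g_K1: float = 25.747369722495236  # S/F (calibrated)
    # funny current (split into Na+ and K+ components)
    g_f: float = 33.23784077374907    # S/F (calibrated)
    fNa_f: float = 0.37
    # Na/Ca exchanger
    kNaCa: float = 6911.445909987897  # A/F (calibrated)
    alpha_NaCa: float = 2.16659
    gamma_NaCa: float = 0.35
    Ksat: float = 0.1
    KmCa: float = 1.38          # mM
    KmNai: float = 87.5         # mM
    # Na/K pump
    PNaK: float = 2.74240       # A/F
    Km_K: float = 1.0           # mM
    Km_Na: float = 40.0         # mM
    # sarcolemmal Ca2+ pump and background currents
    g_PCa: float = 0.23122317352447277  # A/F (calibrated)
    KPCa: float = 0.0005        # mM
    g_b_Na: float = 0.95        # S/F
    g_b_Ca: float = 0.727272    # S/F
    # SR Ca2+ handling
    VmaxUp: float = 0.7409362437544483  # mM/s (calibrated)
    Kup: float = 4.40435e-4     # mM
    V_leak: float = 4.7279e-4   # 1/s
    g_irel_max: float = 43.867344085669416  # mM/s (calibrated)
    RyRa1: float = 0.05169
    RyRa2: float = 0.050001
    RyRahalf: float = 0.02632
    RyRohalf: float = 0.00944
    RyRchalf: float = 0.00167
    # cytosolic / SR Ca2+ buffering
    Buf_C: float = 0.25         # mM
    Kbuf_C: float = 0.001       # mM
    Buf_SR: float = 10.0        # mM
    Kbuf_SR: float = 0.3        # mM

    # per-channel scale multipliers (dimensionless, 1 = baseline)
    s_Na: float = 1.0
    s_NaL: float = 1.0
    s_CaL: float = 1.0
    s_f: float = 1.0
    s_K1: float = 1.0
    s_Kr: float = 1.0
    s_Ks: float = 1.0
    s_to: float = 1.0
    s_NaCa: float = 1.0
    s_NaK: float = 1.0
    s_pCa: float = 1.0
    s_bNa: float = 1.0
    s_bCa: float = 1.0

    def validate(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite ionic parameter {f_.name!r}")
        for ch, attr in CHANNELS.items():
            if getattr(self, attr) <= 0:
                raise ValueError(f"multiplier for {ch} must be > 0")


@dataclass
class CEParameters:
    """Myofilament contractile-element constants (Rice-2008 formulation).

    Defaults are the hiPSC-CM recalibration: troponin/regulatory constants
    retuned against stem-cell-derived cardiomyocyte contraction data, rest
    sarcomere length 1.9 um, mass 2e-5 s^2/um, viscosity 0.3% of maximal
    force per um, tension scaling kxb = 12 kPa, and the small-organism
    cross-bridge species factor xbmodsp = 0.2.  ``rice_baseline()`` restores
    the original large-animal values for cross-checks.
    """

    # sarcomere geometry (um)
    SLmin: float = 1.4
    SLmax: float = 2.4
    len_thick: float = 1.65
    len_hbare: float = 0.1
    len_thin: float = 1.2
    x_0: float = 0.007
    SL_rest: float = 1.9
    SL_set: float = 1.9

    # Ca2+-troponin kinetics
    Kon: float = 62.5e3         # 1/(mM s); recalibrated (baseline 50e3)
    KoffL: float = 200.0        # 1/s; recalibrated (baseline 250)
    KoffH: float = 25.0         # 1/s
    Koffmod: float = 0.5        # recalibrated (baseline 1)
    Qkon: float = 1.5
    Qkoff: float = 1.3
    TropTotal: float = 0.070    # mM

    # thin-filament regulation
    perm50: float = 0.6         # recalibrated (baseline 0.5)
    nperm: float = 11.28        # recalibrated (baseline 15)
    kn_p: float = 550.0         # 1/s; recalibrated (baseline 500)
    kp_n: float = 50.0          # 1/s
    Qkn_p: float = 1.6
    Qkp_n: float = 1.6

    # cross-bridge cycling (base rates at 37 C, 1/s)
    fapp: float = 500.0
    gapp: float = 70.0
    gslmod: float = 6.0
    hf: float = 2000.0
    hfmdc: float = 5.0
    hb: float = 400.0
    hbmdc: float = 0.0
    gxb: float = 70.0
    sigmap: float = 8.0
    sigman: float = 1.0
    Qfapp: float = 6.25
    Qgapp: float = 2.5
    Qhf: float = 6.25
    Qhb: float = 6.25
    Qgxb: float = 6.25
    xbmodsp: float = 0.2        # human/large-mammal end of the species scale
    TmpC: float = 37.0
    xPsi: float = 2.0

    # sarcomere mechanics
    mass: float = 2e-5          # s^2/um; recalibrated (baseline 5e-5)
    visc: float = 0.003         # normalized force / um (0.3% of F_max)
    kxb: float = 12.0           # kPa; tension scaling constant
    afterload: float = 0.0      # normalized; unloaded cell

    # passive force: titin and collagen
    PCon_t: float = 0.002
    PExp_t: float = 10.0
    SL_collagen: float = 2.25
    PCon_c: float = 0.02
    PExp_c: float = 70.0

    @classmethod
    def rice_baseline(cls) -> "CEParameters":
        """Original (rabbit-data) constant set for the retuned parameters."""
        return cls(
            Kon=50e3, KoffL=250.0, KoffH=25.0, Koffmod=1.0,
            perm50=0.5, nperm=15.0, kn_p=500.0, kp_n=50.0,
            mass=5e-5, kxb=120.0, SL_rest=1.85, SL_set=1.85,
        )

    def validate(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite CE parameter {f_.name!r}")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        for name in ("Kon", "KoffL", "KoffH", "kn_p", "kp_n",
                     "fapp", "gapp", "hf", "hb", "gxb"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be >= 0")
        if not (self.SLmin < self.SL_rest < self.SLmax):
            raise ValueError("SL_rest must lie inside [SLmin, SLmax]")


@dataclass
class PassiveForceConfig:
    """Tissue composition for the piecewise passive-force law.

    ``ctn`` is the percent of cardiomyocytes in the engineered tissue; the
    remainder is the non-cardiomyocyte fraction whose mechanical load the
    passive force emulates.  ``ctn = 100`` is a pure cardiomyocyte (titin
    only).
    """

    ctn: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ctn <= 100.0):
            raise ValueError(f"ctn must be in (0, 100], got {self.ctn}")

    @property
    def c(self) -> float:
        return self.ctn / 100.0


@dataclass
class ModelParameters:
    """Bundle of the three parameter groups plus runtime coupling flags."""

    ionic: IonicParameters = field(default_factory=IonicParameters)
    ce: CEParameters = field(default_factory=CEParameters)
    tissue: PassiveForceConfig = field(default_factory=PassiveForceConfig)
    coupling: str = "strong"        # "strong" | "weak"
    isosarcometric: bool = False
    ce_active: bool = True
    # Optional strong-coupling variant: additionally remove the troponin
    # share from the static cytosolic buffer.  The default (False) keeps
    # the static buffer at full capacity while subtracting J_CaBMyo, which
    # reproduces the published coupling-feedback deltas; with the
    # reduction enabled the dynamic troponin (effective Kd 1.6 uM) binds
    # less Ca2+ than the static share it replaces (Kd 1.0 uM) and the
    # feedback raises rather than lowers the CaT.
    buffer_troponin_subtraction: bool = False

    def validate(self) -> None:
        self.ionic.validate()
        self.ce.validate()
        if self.coupling not in ("strong", "weak"):
            raise ValueError(f"coupling must be 'strong' or 'weak', got {self.coupling!r}")


def apply_channel_scaling(params: IonicParameters,
                          multipliers: dict[str, float]) -> IonicParameters:
    """Return a copy with the listed channel multipliers scaled.

    Scaling composes multiplicatively with whatever multipliers are already
    set, so applying ``a`` then ``b`` equals applying ``a*b``.
    """
    updates: dict[str, float] = {}
    for ch, factor in multipliers.items():
        if ch not in CHANNELS:
            raise KeyError(
                f"unknown channel {ch!r}; valid channels: {sorted(CHANNELS)}")
        if factor <= 0 or not math.isfinite(factor):
            raise ValueError(f"scale factor for {ch} must be positive/finite")
        attr = CHANNELS[ch]
        updates[attr] = getattr(params, attr) * factor
    return replace(params, **updates)


def pack(params: ModelParameters, I_stim: float = 0.0) -> np.ndarray:
    """Flatten a :class:`ModelParameters` bundle into the core's P vector."""
    params.validate()
    P = np.zeros(NPARAM)
    for group in (params.ionic, params.ce):
        for f_ in fields(group):
            if f_.name in PARAM_INDEX:
                P[PARAM_INDEX[f_.name]] = getattr(group, f_.name)
    P[PARAM_INDEX["ctn"]] = params.tissue.ctn
    P[PARAM_INDEX["I_stim"]] = I_stim
    P[PARAM_INDEX["coupling_strong"]] = 1.0 if params.coupling == "strong" else 0.0
    P[PARAM_INDEX["isosarcometric"]] = 1.0 if params.isosarcometric else 0.0
    P[PARAM_INDEX["ce_active"]] = 1.0 if params.ce_active else 0.0
    P[PARAM_INDEX["buffer_troponin_subtraction"]] = \
        1.0 if params.buffer_troponin_subtraction else 0.0
    return P


def provenance(params: ModelParameters) -> dict[str, str]:
    """Provenance tag for every numeric parameter in the bundle."""
    recalibrated = {"Kon", "KoffL", "Koffmod", "perm50", "nperm", "kn_p",
                    "mass", "kxb", "xbmodsp", "SL_rest", "SL_set", "visc"}
    calibrated = {"g_Na", "g_CaL", "g_to", "g_Kr", "g_K1", "g_f", "kNaCa",
                  "g_PCa", "VmaxUp", "g_irel_max"}
    tags: dict[str, str] = {}
    for f_ in fields(params.ionic):
        if f_.name.startswith("s_"):
            tag = "repo-default"
        elif f_.name in calibrated:
            tag = "biomarker-calibration"
        else:
            tag = "ionic-model-source"
        tags[f"ionic.{f_.name}"] = tag
    for f_ in fields(params.ce):
        if f_.name in recalibrated:
            tags[f"ce.{f_.name}"] = "hipsc-recalibration"
        elif f_.name in ("PCon_t", "PExp_t", "SL_collagen", "PCon_c",
                         "PExp_c", "afterload"):
            tags[f"ce.{f_.name}"] = "ce-source"
        else:
            tags[f"ce.{f_.name}"] = "ce-source"
    tags["tissue.ctn"] = "repo-default"
    return tags
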