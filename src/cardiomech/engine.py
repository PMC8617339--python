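"""Compiled right-hand side of the coupled electromechanical ODE system.

One scalar-arithmetic core evaluates the full model: the hiPSC-CM
electrophysiology (13 membrane currents, SR Ca2+ cycling), the myofilament
contractile element (thin-filament activation, cross-bridge cycling,
sarcomere-length dynamics), and the bidirectional coupling (apparent
Ca2+-troponin binding flux).  The core is jit-compiled with numba when
available and falls back to plain Python otherwise; both paths execute the
same source.

Internal unit convention: potential in volts, time in seconds,
concentrations in mM, currents in A/F, sarcomere length in micrometres.
"""

from __future__ import annotations

import math

import numpy as np

from .layout import *  # noqa: F401,F403 - index constants
from .layout import NOUT, NSTATE

__all__ = ["full_rhs", "full_outputs", "ce_rhs_driven", "ce_outputs_driven",
           "NUMBA_ENABLED"]

# number of CE-specific derived outputs from the CE kernel
_NCEOUT = 7


def _ce_core(yce, Cai, P):
    """Contractile-element derivatives and derived quantities.

    ``yce`` is the 10-component CE state (N, XBprer, XBpostr, xXBprer,
    xXBpostr, TRPNCaL, TRPNCaH, N_NoXB, SL, intf); ``Cai`` the cytosolic
    Ca2+ (mM) driving the thin filament.  Returns ``(dyce, out)`` with
    ``out = (JCaBMyo, F_active, Tension, F_passive, SOVFThin, FrSBXB,
    TropApr)``.
    """
    N = yce[0]
    XBprer = yce[1]
    XBpostr = yce[2]
    xXBprer = yce[3]
    xXBpostr = yce[4]
    TRPNCaL = yce[5]
    TRPNCaH = yce[6]
    N_NoXB = yce[7]
    SL = yce[8]
    intf = yce[9]

    len_thick = P[P_LEN_THICK]
    len_hbare = P[P_LEN_HBARE]
    len_thin = P[P_LEN_THIN]
    x_0 = P[P_X_0]
    xbmodsp = P[P_XBMODSP]
    tfac = (P[P_TMPC] - 37.0) / 10.0

    # --- thin/thick filament single-overlap geometry --------------------
    sovr_ze = min(len_thick / 2.0, SL / 2.0)
    sovr_cle = max(len_thin - SL / 2.0, len_hbare / 2.0)
    len_sovr = sovr_ze - sovr_cle
    SOVFThick = 2.0 * len_sovr / (len_thick - len_hbare)
    SOVFThin = len_sovr / len_thin

    # --- Ca2+ binding to troponin regulatory sites ----------------------
    konT = P[P_KON] * P[P_QKON] ** tfac
    koffLT = P[P_KOFFL] * P[P_KOFFMOD] * P[P_QKOFF] ** tfac
    koffHT = P[P_KOFFH] * P[P_KOFFMOD] * P[P_QKOFF] ** tfac
    dTRPNCaL = konT * Cai * (1.0 - TRPNCaL) - koffLT * TRPNCaL
    dTRPNCaH = konT * Cai * (1.0 - TRPNCaH) - koffHT * TRPNCaH

    # --- regulatory-unit permissivity ------------------------------------
    Tropreg = (1.0 - SOVFThin) * TRPNCaL + SOVFThin * TRPNCaH
    if Tropreg < 1e-12:
        Tropreg = 1e-12
    permtot = math.sqrt(1.0 / (1.0 + (P[P_PERM50] / Tropreg) ** P[P_NPERM]))
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0
    knpT = P[P_KN_P] * permtot * P[P_QKN_P] ** tfac
    kpnT = P[P_KP_N] * inprmt * P[P_QKP_N] ** tfac

    # --- cross-bridge cycling rates (strain- and SL-modulated) -----------
    fappT = P[P_FAPP] * xbmodsp * P[P_QFAPP] ** tfac
    gapslmd = 1.0 + (1.0 - SOVFThick) * P[P_GSLMOD]
    gappT = P[P_GAPP] * gapslmd * xbmodsp * P[P_QGAPP] ** tfac
    if xXBprer >= 0.0:
        hfmd = math.exp(-P[P_HFMDC] * (xXBprer / x_0) ** 2)
    else:
        hfmd = math.exp(P[P_HFMDC] * (xXBprer / x_0) ** 2)
    hfT = P[P_HF] * hfmd * xbmodsp * P[P_QHF] ** tfac
    if xXBpostr >= x_0:
        hbmd = math.exp(P[P_HBMDC] * ((xXBpostr - x_0) / x_0) ** 2)
    else:
        hbmd = math.exp(-P[P_HBMDC] * ((xXBpostr - x_0) / x_0) ** 2)
    hbT = P[P_HB] * hbmd * xbmodsp * P[P_QHB] ** tfac
    if xXBpostr < x_0:
        gxbmd = math.exp(P[P_SIGMAP] * ((x_0 - xXBpostr) / x_0) ** 2)
    else:
        gxbmd = math.exp(P[P_SIGMAN] * ((xXBpostr - x_0) / x_0) ** 2)
    gxbT = P[P_GXB] * gxbmd * xbmodsp * P[P_QGXB] ** tfac

    # --- regulatory-unit / cross-bridge state transitions -----------------
    Pfract = 1.0 - N - XBprer - XBpostr
    dN = -knpT * N + kpnT * Pfract
    dXBprer = fappT * Pfract - gappT * XBprer - hfT * XBprer + hbT * XBpostr
    dXBpostr = hfT * XBprer - hbT * XBpostr - gxbT * XBpostr
    dN_NoXB = -knpT * N_NoXB + kpnT * (1.0 - N_NoXB)

    # steady-state duty fractions at the unmodulated base rates; used for
    # force normalization and the mean-strain dynamics
    fapp = P[P_FAPP]
    gapp = P[P_GAPP]
    hfb = P[P_HF]
    hbb = P[P_HB]
    gxb = P[P_GXB]
    denom = (gxb * hfb + fapp * hfb + gxb * gapp + hbb * fapp
             + hbb * gapp + gapp * hfb)
    ssXBprer = (hbb * fapp + gxb * fapp) / denom
    ssXBpostr = fapp * hfb / denom

    # --- normalized forces -----------------------------------------------
    F_active = SOVFThick * (XBprer * xXBprer + XBpostr * xXBpostr) / (x_0 * ssXBpostr)
    Tension = P[P_KXB] * F_active

    SL_rest = P[P_SL_REST]
    # titin
    d_rest = SL - SL_rest
    if d_rest >= 0.0:
        F_titin = P[P_PCON_T] * (math.exp(P[P_PEXP_T] * d_rest) - 1.0)
    else:
        F_titin = -P[P_PCON_T] * (math.exp(-P[P_PEXP_T] * d_rest) - 1.0)
    # collagen
    if SL >= P[P_SL_COLLAGEN]:
        F_coll = P[P_PCON_C] * (math.exp(P[P_PEXP_C] * (SL - P[P_SL_COLLAGEN])) - 1.0)
    else:
        F_coll = 0.0
    ctn = P[P_CTN]
    c = ctn / 100.0
    if ctn >= 100.0:
        F_passive = F_titin
    elif ctn >= 70.0:
        F_passive = 10.54 * (4.66 * math.exp(-3.05 * c ** 4.9)) * (F_titin + F_coll)
    else:
        F_passive = (6.0 * math.exp(-6.17 * c ** 2.91)) * (F_titin + F_coll)

    # preload: passive force at the reference length (zero when SL_set is
    # the rest length)
    d_set = P[P_SL_SET] - SL_rest
    if d_set >= 0.0:
        pre_t = P[P_PCON_T] * (math.exp(P[P_PEXP_T] * d_set) - 1.0)
    else:
        pre_t = -P[P_PCON_T] * (math.exp(-P[P_PEXP_T] * d_set) - 1.0)
    if P[P_SL_SET] >= P[P_SL_COLLAGEN]:
        pre_c = P[P_PCON_C] * (math.exp(P[P_PEXP_C] * (P[P_SL_SET] - P[P_SL_COLLAGEN])) - 1.0)
    else:
        pre_c = 0.0
    if ctn >= 100.0:
        preload = pre_t
    elif ctn >= 70.0:
        preload = 10.54 * (4.66 * math.exp(-3.05 * c ** 4.9)) * (pre_t + pre_c)
    else:
        preload = (6.0 * math.exp(-6.17 * c ** 2.91)) * (pre_t + pre_c)

    # --- sarcomere-length dynamics ---------------------------------------
    if P[P_ISOSARCOMETRIC] > 0.5:
        dSL = 0.0
        dintf = 0.0
    else:
        dSL = (intf + (P[P_SL_SET] - SL) * P[P_VISC]) / P[P_MASS]
        if SL <= P[P_SLMIN] or SL >= P[P_SLMAX]:
            dSL = 0.0
        dintf = -F_passive + preload - F_active + P[P_AFTERLOAD]

    # --- mean cross-bridge strains ---------------------------------------
    xPsi = P[P_XPSI]
    dxXBprer = 0.5 * dSL + (xPsi / ssXBprer) * (
        -fappT * xXBprer + hbT * (xXBpostr - x_0 - xXBprer))
    dxXBpostr = 0.5 * dSL + (xPsi / ssXBpostr) * (
        hfT * (xXBprer + x_0 - xXBpostr))

    # --- apparent Ca2+-troponin binding (cytosolic feedback) --------------
    FrSBXB = (XBprer + XBpostr) / (ssXBprer + ssXBpostr)
    dFrSBXB = (dXBprer + dXBpostr) / (ssXBprer + ssXBpostr)
    # d/dt of the overlap fractions
    dsovr_ze = 0.5 * dSL if SL < len_thick else 0.0
    dsovr_cle = -0.5 * dSL if SL < (2.0 * len_thin - len_hbare) else 0.0
    dlen_sovr = dsovr_ze - dsovr_cle
    dSOVFThin = dlen_sovr / len_thin

    TropApr = ((1.0 - SOVFThin) * TRPNCaL
               + SOVFThin * (FrSBXB * TRPNCaH + (1.0 - FrSBXB) * TRPNCaL))
    dTropApr = (-dSOVFThin * TRPNCaL + (1.0 - SOVFThin) * dTRPNCaL
                + dSOVFThin * (FrSBXB * TRPNCaH + (1.0 - FrSBXB) * TRPNCaL)
                + SOVFThin * (dFrSBXB * TRPNCaH + FrSBXB * dTRPNCaH
                              - dFrSBXB * TRPNCaL + (1.0 - FrSBXB) * dTRPNCaL))
    JCaBMyo = P[P_TROPTOTAL] * dTropApr

    dyce = np.empty(10)
    dyce[0] = dN
    dyce[1] = dXBprer
    dyce[2] = dXBpostr
    dyce[3] = dxXBprer
    dyce[4] = dxXBpostr
    dyce[5] = dTRPNCaL
    dyce[6] = dTRPNCaH
    dyce[7] = dN_NoXB
    dyce[8] = dSL
    dyce[9] = dintf

    out = np.empty(_NCEOUT)
    out[0] = JCaBMyo
    out[1] = F_active
    out[2] = Tension
    out[3] = F_passive
    out[4] = SOVFThin
    out[5] = FrSBXB
    out[6] = TropApr
    return dyce, out


def _core(t, y, P):
    """Full coupled derivative plus derived outputs.

    Returns ``(dy, out)`` with ``dy`` of length NSTATE and ``out`` of
    length NOUT (currents, fluxes, forces; see layout.OUT_FIELDS).
    """
    # --- unpack ionic state ------------------------------------------------
    Vm = y[S_VM]
    CaSR = y[S_CASR]
    Cai = y[S_CAI]
    d = y[S_D]
    f1 = y[S_F1]
    f2 = y[S_F2]
    fCa = y[S_FCA]
    h = y[S_H]
    j = y[S_J]
    m = y[S_M]
    Xf = y[S_XF]
    q = y[S_Q]
    r = y[S_R]
    Nai = y[S_NAI]
    mL = y[S_ML]
    hL = y[S_HL]
    RyRa = y[S_RYRA]
    RyRo = y[S_RYRO]
    RyRc = y[S_RYRC]
    Xr1 = y[S_XR1]
    Xr2 = y[S_XR2]
    Xs = y[S_XS]

    Rgas = 8.314472
    Frdy = 96485.3415
    T = P[P_T]
    RTF = Rgas * T / Frdy
    FRT = 1.0 / RTF
    V = Vm * 1000.0  # mV, for the gate formulations

    Nao = P[P_NAO]
    Ko = P[P_KO]
    Cao = P[P_CAO]
    Ki = P[P_KI]

    if Cai < 1e-10:
        Cai_safe = 1e-10
    else:
        Cai_safe = Cai
    E_Na = RTF * math.log(Nao / Nai)
    E_Ca = 0.5 * RTF * math.log(Cao / Cai_safe)
    E_K = RTF * math.log(Ko / Ki)
    PkNa = 0.03
    E_Ks = RTF * math.log((Ko + PkNa * Nao) / (Ki + PkNa * Nai))

    # --- fast Na+ current ---------------------------------------------------
    i_Na = P[P_S_NA] * P[P_G_NA] * m ** 3 * h * j * (Vm - E_Na)

    m_inf = (1.0 / (1.0 + math.exp((-V - 34.1) / 5.9))) ** (1.0 / 3.0)
    alpha_m = 1.0 / (1.0 + math.exp((-V - 60.0) / 5.0))
    beta_m = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
              + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0)))
    tau_m = alpha_m * beta_m / 1000.0

    h_inf = 1.0 / math.sqrt(1.0 + math.exp((V + 72.1) / 5.7))
    if V < -40.0:
        alpha_h = 0.057 * math.exp(-(V + 80.0) / 6.8)
        beta_h = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
        tau_h = 1.5 / ((alpha_h + beta_h) * 1000.0)
    else:
        tau_h = 2.542 / 1000.0

    j_inf = h_inf
    if V < -40.0:
        alpha_j = ((-25428.0 * math.exp(0.2444 * V)
                    - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
                   / (1.0 + math.exp(0.311 * (V + 79.23))))
        beta_j = (0.02424 * math.exp(-0.01052 * V)
                  / (1.0 + math.exp(-0.1378 * (V + 40.14))))
    else:
        alpha_j = 0.0
        beta_j = (0.6 * math.exp(0.057 * V)
                  / (1.0 + math.exp(-0.1 * (V + 32.0))))
    tau_j = 7.0 / ((alpha_j + beta_j) * 1000.0)

    # --- late Na+ current ----------------------------------------------------
    i_NaL = P[P_S_NAL] * P[P_G_NAL] * mL ** 3 * hL * (Vm - E_Na)
    mL_inf = 1.0 / (1.0 + math.exp((-V - 42.85) / 5.264))
    alpha_mL = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    beta_mL = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
               + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0)))
    tau_mL = alpha_mL * beta_mL / 1000.0
    hL_inf = 1.0 / (1.0 + math.exp((V + P[P_VH_HL]) / 7.488))
    tau_hL = P[P_TAU_HL]

    # --- L-type Ca2+ current -------------------------------------------------
    expVFRT2 = math.exp(2.0 * Vm * FRT)
    if abs(Vm) < 1e-8:
        # V -> 0 limit of the electrodiffusion driving term
        i_CaL_drv = P[P_G_CAL] * 2.0 * Frdy * (Cai_safe - 0.341 * Cao)
    else:
        i_CaL_drv = (P[P_G_CAL] * 4.0 * Vm * Frdy * FRT
                     * (Cai_safe * expVFRT2 - 0.341 * Cao) / (expVFRT2 - 1.0))
    i_CaL = P[P_S_CAL] * i_CaL_drv * d * f1 * f2 * fCa

    d_inf = 1.0 / (1.0 + math.exp(-(V + 9.1) / 7.0))
    alpha_d = 0.25 + 1.4 / (1.0 + math.exp((-V - 35.0) / 13.0))
    beta_d = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gamma_d = 1.0 / (1.0 + math.exp((-V + 50.0) / 20.0))
    tau_d = (alpha_d * beta_d + gamma_d) / 1000.0

    f1_inf = 1.0 / (1.0 + math.exp((V + 26.0) / 3.0))
    if f1_inf - f1 > 0.0:
        constf1 = 1.0 + 1433.0 * (Cai - 50.0e-6)
    else:
        constf1 = 1.0
    tau_f1 = ((20.0
               + 1102.5 * math.exp(-(((V + 27.0) ** 2) / 15.0) ** 2)
               + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
               + 180.0 / (1.0 + math.exp((30.0 + V) / 10.0)))
              * constf1 / 1000.0)

    f2_inf = 0.33 + 0.67 / (1.0 + math.exp((V + 32.0) / 4.0))
    tau_f2 = ((600.0 * math.exp(-((V + 25.0) ** 2) / 170.0)
               + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
               + 16.0 / (1.0 + math.exp((30.0 + V) / 10.0)))
              / 1000.0)

    alpha_fCa = 1.0 / (1.0 + (Cai_safe / 0.0006) ** 8)
    beta_fCa = 0.1 / (1.0 + math.exp((Cai_safe - 0.0009) / 0.0001))
    gamma_fCa = 0.3 / (1.0 + math.exp((Cai_safe - 0.00075) / 0.0008))
    fCa_inf = (alpha_fCa + beta_fCa + gamma_fCa) / 1.3156
    if fCa_inf > fCa and V > -60.0:
        constfCa = 0.0
    else:
        constfCa = 1.0
    tau_fCa = 0.002

    # --- transient outward K+ ------------------------------------------------
    i_to = P[P_S_TO] * P[P_G_TO] * q * r * (Vm - E_K)
    q_inf = 1.0 / (1.0 + math.exp((V + 53.0) / 13.0))
    tau_q = ((6.06 + 39.102 / (0.57 * math.exp(-0.08 * (V + 44.0))
                               + 0.065 * math.exp(0.1 * (V + 45.93))))
             / 1000.0)
    r_inf = 1.0 / (1.0 + math.exp(-(V - 22.3) / 18.75))
    tau_r = ((2.75352 + 14.40516 / (1.037 * math.exp(0.09 * (V + 30.61))
                                    + 0.369 * math.exp(-0.12 * (V + 23.84))))
             / 1000.0)

    # --- slow delayed rectifier ---------------------------------------------
    i_Ks = (P[P_S_KS] * P[P_G_KS] * Xs ** 2 * (Vm - E_Ks)
            * (1.0 + 0.6 / (1.0 + (3.8e-5 / Cai_safe) ** 1.4)))
    Xs_inf = 1.0 / (1.0 + math.exp((-V - 20.0) / 16.0))
    alpha_Xs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - V) / 6.0))
    beta_Xs = 1.0 / (1.0 + math.exp((-60.0 + V) / 20.0))
    tau_Xs = alpha_Xs * beta_Xs / 1000.0

    # --- rapid delayed rectifier ---------------------------------------------
    i_Kr = (P[P_S_KR] * P[P_G_KR] * math.sqrt(Ko / 5.4)
            * Xr1 * Xr2 * (Vm - E_K))
    V_half = 1000.0 * (-RTF / P[P_Q_KR]
                       * math.log((1.0 + Cao / 2.6) ** 4
                                  / (P[P_L0_KR] * (1.0 + Cao / 0.58) ** 4))
                       - 0.019)
    Xr1_inf = 1.0 / (1.0 + math.exp((V_half - V) / 4.9))
    alpha_Xr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    beta_Xr1 = 6.0 / (1.0 + math.exp((30.0 + V) / 11.5))
    tau_Xr1 = alpha_Xr1 * beta_Xr1 / 1000.0
    Xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 50.0))
    alpha_Xr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    beta_Xr2 = 1.12 / (1.0 + math.exp((-60.0 + V) / 20.0))
    tau_Xr2 = alpha_Xr2 * beta_Xr2 / 1000.0

    # --- inward rectifier ------------------------------------------------------
    VEK = V - E_K * 1000.0
    alpha_K1 = 3.91 / (1.0 + math.exp(0.5942 * (VEK - 200.0)))
    beta_K1 = ((-1.509 * math.exp(0.0002 * (VEK + 100.0))
                + math.exp(0.5886 * (VEK - 10.0)))
               / (1.0 + math.exp(0.4547 * VEK)))
    XK1_inf = alpha_K1 / (alpha_K1 + beta_K1)
    i_K1 = (P[P_S_K1] * P[P_G_K1] * math.sqrt(Ko / 5.4)
            * XK1_inf * (Vm - E_K))

    # --- funny current ---------------------------------------------------------
    fNa = P[P_FNA_F]
    i_fNa = P[P_S_F] * fNa * P[P_G_F] * Xf * (Vm - E_Na)
    i_fK = P[P_S_F] * (1.0 - fNa) * P[P_G_F] * Xf * (Vm - E_K)
    i_f = i_fNa + i_fK
    Xf_inf = 1.0 / (1.0 + math.exp((V + 77.85) / 5.0))
    tau_Xf = (1900.0 / (1.0 + math.exp((V + 15.0) / 10.0))) / 1000.0

    # --- Na/Ca exchanger --------------------------------------------------------
    gam = P[P_GAMMA_NACA]
    i_NaCa = (P[P_S_NACA] * P[P_KNACA]
              * (math.exp(gam * Vm * FRT) * Nai ** 3 * Cao
                 - math.exp((gam - 1.0) * Vm * FRT) * Nao ** 3 * Cai_safe
                 * P[P_ALPHA_NACA])
              / ((P[P_KMNAI] ** 3 + Nao ** 3) * (P[P_KMCA] + Cao)
                 * (1.0 + P[P_KSAT] * math.exp((gam - 1.0) * Vm * FRT))))

    # --- Na/K pump ----------------------------------------------------------------
    i_NaK = (P[P_S_NAK] * P[P_PNAK] * Ko / (Ko + P[P_KM_K])
             * Nai / (Nai + P[P_KM_NA])
             / (1.0 + 0.1245 * math.exp(-0.1 * Vm * FRT)
                + 0.0353 * math.exp(-Vm * FRT)))

    # --- sarcolemmal Ca pump and background currents -------------------------------
    i_PCa = P[P_S_PCA] * P[P_G_PCA] * Cai_safe / (Cai_safe + P[P_KPCA])
    i_b_Na = P[P_S_BNA] * P[P_G_B_NA] * (Vm - E_Na)
    i_b_Ca = P[P_S_BCA] * P[P_G_B_CA] * (Vm - E_Ca)

    # --- SR Ca2+ fluxes --------------------------------------------------------------
    i_up = P[P_VMAXUP] / (1.0 + (P[P_KUP] / Cai_safe) ** 2)
    i_leak = (CaSR - Cai) * P[P_V_LEAK]

    RyRSRCass = 1.0 - 1.0 / (1.0 + math.exp((CaSR - 0.3) / 0.1))
    i_rel = P[P_G_IREL_MAX] * RyRSRCass * RyRo * RyRc * (CaSR - Cai)
    RyRainfss = P[P_RYRA1] - P[P_RYRA2] / (
        1.0 + math.exp((1000.0 * Cai - P[P_RYRAHALF]) / 0.0082))
    RyRoinfss = 1.0 - 1.0 / (
        1.0 + math.exp((1000.0 * Cai - (RyRa + P[P_RYROHALF])) / 0.003))
    RyRcinfss = 1.0 / (
        1.0 + math.exp((1000.0 * Cai - (RyRa + P[P_RYRCHALF])) / 0.001))

    # --- contractile element -----------------------------------------------------------
    ce_on = P[P_CE_ACTIVE] > 0.5
    if ce_on:
        dyce, ce_out = _ce_core(y[22:32], Cai_safe, P)
        JCaBMyo = ce_out[0]
    else:
        dyce = np.zeros(10)
        ce_out = np.zeros(_NCEOUT)
        JCaBMyo = 0.0

    strong = ce_on and P[P_COUPLING_STRONG] > 0.5

    # --- ionic balances ------------------------------------------------------------------
    Cm = P[P_CM]
    Vc = P[P_VC]
    V_SR = P[P_V_SR]

    if P[P_BUFFER_TROPONIN_SUBTRACTION] > 0.5:
        Buf_C_eff = P[P_BUF_C] - P[P_TROPTOTAL]
    else:
        Buf_C_eff = P[P_BUF_C]
    J_myo = JCaBMyo if strong else 0.0

    Cai_buf = 1.0 / (1.0 + Buf_C_eff * P[P_KBUF_C]
                     / (Cai + P[P_KBUF_C]) ** 2)
    CaSR_buf = 1.0 / (1.0 + P[P_BUF_SR] * P[P_KBUF_SR]
                      / (CaSR + P[P_KBUF_SR]) ** 2)

    i_stim = P[P_I_STIM]

    dCai = Cai_buf * (i_leak - i_up + i_rel
                      - (i_CaL + i_b_Ca + i_PCa - 2.0 * i_NaCa)
                      * Cm / (2.0 * Vc * Frdy * 1.0e-18)
                      - J_myo)
    dCaSR = CaSR_buf * (Vc / V_SR) * (i_up - i_rel - i_leak)
    dNai = -(i_Na + i_NaL + i_b_Na + 3.0 * i_NaK + 3.0 * i_NaCa + i_fNa) \
        * Cm / (Frdy * Vc * 1.0e-18)

    dVm = -(i_Na + i_NaL + i_CaL + i_f + i_K1 + i_Kr + i_Ks + i_to
            + i_NaCa + i_NaK + i_PCa + i_b_Na + i_b_Ca - i_stim)

    dy = np.empty(NSTATE)
    dy[S_VM] = dVm
    dy[S_CASR] = dCaSR
    dy[S_CAI] = dCai
    dy[S_D] = (d_inf - d) / tau_d
    dy[S_F1] = (f1_inf - f1) / tau_f1
    dy[S_F2] = (f2_inf - f2) / tau_f2
    dy[S_FCA] = constfCa * (fCa_inf - fCa) / tau_fCa
    dy[S_H] = (h_inf - h) / tau_h
    dy[S_J] = (j_inf - j) / tau_j
    dy[S_M] = (m_inf - m) / tau_m
    dy[S_XF] = (Xf_inf - Xf) / tau_Xf
    dy[S_Q] = (q_inf - q) / tau_q
    dy[S_R] = (r_inf - r) / tau_r
    dy[S_NAI] = dNai
    dy[S_ML] = (mL_inf - mL) / tau_mL
    dy[S_HL] = (hL_inf - hL) / tau_hL
    dy[S_RYRA] = (RyRainfss - RyRa) / 1.0
    dy[S_RYRO] = (RyRoinfss - RyRo) / 18.75e-3
    dy[S_RYRC] = (RyRcinfss - RyRc) / 87.5e-3
    dy[S_XR1] = (Xr1_inf - Xr1) / tau_Xr1
    dy[S_XR2] = (Xr2_inf - Xr2) / tau_Xr2
    dy[S_XS] = (Xs_inf - Xs) / tau_Xs
    for k in range(10):
        dy[22 + k] = dyce[k]

    out = np.empty(NOUT)
    out[O_INA] = i_Na
    out[O_INAL] = i_NaL
    out[O_ICAL] = i_CaL
    out[O_IF] = i_f
    out[O_IK1] = i_K1
    out[O_IKR] = i_Kr
    out[O_IKS] = i_Ks
    out[O_ITO] = i_to
    out[O_INACA] = i_NaCa
    out[O_INAK] = i_NaK
    out[O_IPCA] = i_PCa
    out[O_IBNA] = i_b_Na
    out[O_IBCA] = i_b_Ca
    out[O_ISTIM] = i_stim
    out[O_JUP] = i_up
    out[O_JREL] = i_rel
    out[O_JLEAK] = i_leak
    out[O_JCABMYO] = JCaBMyo
    out[O_F_ACTIVE] = ce_out[1]
    out[O_TENSION] = ce_out[2]
    out[O_F_PASSIVE] = ce_out[3]
    out[O_SOVFTHIN] = ce_out[4]
    out[O_FRSBXB] = ce_out[5]
    out[O_TROPAPR] = ce_out[6]
    return dy, out


def _ce_driven_core(t, yce, Cai, P):
    dyce, _ = _ce_core(yce, Cai, P)
    return dyce


# ---------------------------------------------------------------------------
# jit compilation (optional)
NUMBA_ENABLED = False
try:  # pragma: no cover - exercised implicitly by every simulation
    import numba

    _ce_core = numba.njit(cache=True)(_ce_core)
    _core = numba.njit(cache=True)(_core)
    NUMBA_ENABLED = True
except ImportError:  # pragma: no cover
    pass


def full_rhs(t, y, P):
    """d(state)/dt of the coupled model (solver-facing signature)."""
    dy, _ = _core(t, y, P)
    return dy


def full_outputs(t, y, P):
    """Derived quantities (currents, fluxes, forces) at one instant."""
    _, out = _core(t, y, P)
    return out


def ce_rhs_driven(t, yce, Cai, P):
    """CE-only derivative with a prescribed cytosolic Ca2+ (mM)."""
    dyce, _ = _ce_core(yce, Cai, P)
    return dyce


def ce_outputs_driven(yce, Cai, P):
    """CE-only derived quantities for a prescribed Ca2+."""
    _, out = _ce_core(yce, Cai, P)
    return {
        "JCaBMyo": out[0], "F_active": out[1], "Tension": out[2],
        "F_passive": out[3], "SOVFThin": out[4], "FrSBXB": out[5],
        "TropApr": out[6],
    }
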