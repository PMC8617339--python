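"""Flat state/parameter vector layout shared by the Python API and the compiled core.

The ODE core operates on plain float64 arrays so it can be jit-compiled.
This module is the single source of truth for which slot holds what.
Index constants (``S_*`` for states, ``P_*`` for parameters, ``O_*`` for
derived outputs) are generated from the ordered field tuples below.
"""

# ---------------------------------------------------------------------------
# State vector: 22 ionic states followed by 10 contractile states.
# Membrane potential is in volts, concentrations in mM, sarcomere length in
# micrometres, time in seconds throughout the core.
STATE_FIELDS = (
    # ionic
    "Vm",       # membrane potential (V)
    "CaSR",     # sarcoplasmic-reticulum Ca2+ (mM)
    "Cai",      # cytosolic Ca2+ (mM)
    "d", "f1", "f2", "fCa",          # L-type Ca2+ channel gates
    "h", "j", "m",                   # fast Na+ channel gates
    "Xf",                            # funny-current gate
    "q", "r",                        # transient-outward gates
    "Nai",      # cytosolic Na+ (mM)
    "mL", "hL",                      # late Na+ gates
    "RyRa", "RyRo", "RyRc",          # SR release channel adaptation/open/close
    "Xr1", "Xr2",                    # rapid delayed-rectifier gates
    "Xs",                            # slow delayed-rectifier gate
    # contractile element
    "N",        # nonpermissive regulatory units, cross-bridge population
    "XBprer",   # strongly-bound pre-rotated cross-bridge fraction
    "XBpostr",  # strongly-bound post-rotated cross-bridge fraction
    "xXBprer",  # mean strain of pre-rotated cross-bridges (um)
    "xXBpostr", # mean strain of post-rotated cross-bridges (um)
    "TRPNCaL",  # Ca2+ occupancy of low-affinity troponin sites
    "TRPNCaH",  # Ca2+ occupancy of high-affinity troponin sites
    "N_NoXB",   # nonpermissive units of the no-cross-bridge population
    "SL",       # sarcomere length (um)
    "intf",     # time integral of net normalized force
)

# ---------------------------------------------------------------------------
# Parameter vector.
PARAM_FIELDS = (
    # -- cell geometry / environment ------------------------------------
    "Cm",           # membrane capacitance (F)
    "Vc", "V_SR",   # cytosol and SR volumes (um^3)
    "Nao", "Ko", "Cao",  # extracellular concentrations (mM)
    "Ki",           # fixed intracellular K+ (mM)
    "T",            # temperature (K)
    # -- membrane currents ----------------------------------------------
    "g_Na",         # fast Na+ conductance (S/F)
    "g_NaL",        # late Na+ conductance (S/F)
    "tau_hL",       # late Na+ inactivation time constant (s)
    "Vh_hL",        # late Na+ inactivation half-voltage (mV)
    "g_CaL",        # L-type Ca2+ permeability (m^3/(F s))
    "g_to",         # transient outward conductance (S/F)
    "g_Ks",         # slow delayed rectifier conductance (S/F)
    "g_Kr",         # rapid delayed rectifier conductance (S/F)
    "L0_Kr", "Q_Kr",  # IKr activation half-voltage model constants
    "g_K1",         # inward rectifier conductance (S/F)
    "g_f",          # funny current conductance (S/F)
    "fNa_f",        # Na+ fraction of the funny current
    "kNaCa",        # Na/Ca exchanger maximal current (A/F)
    "alpha_NaCa", "gamma_NaCa", "Ksat", "KmCa", "KmNai",
    "PNaK",         # Na/K pump maximal current (A/F)
    "Km_K", "Km_Na",
    "g_PCa", "KPCa",        # sarcolemmal Ca2+ pump
    "g_b_Na", "g_b_Ca",     # background currents (S/F)
    # -- Ca2+ handling ----------------------------------------------------
    "VmaxUp", "Kup",        # SERCA uptake
    "V_leak",               # SR leak rate (1/s)
    "g_irel_max",           # SR release scaling (mM/s)
    "RyRa1", "RyRa2", "RyRahalf", "RyRohalf", "RyRchalf",
    "Buf_C", "Kbuf_C",      # cytosolic fast buffer (total, Kd; mM)
    "Buf_SR", "Kbuf_SR",    # SR buffer
    # -- per-channel scale multipliers (dimensionless) --------------------
    "s_Na", "s_NaL", "s_CaL", "s_f", "s_K1", "s_Kr", "s_Ks", "s_to",
    "s_NaCa", "s_NaK", "s_pCa", "s_bNa", "s_bCa",
    # -- contractile element: sarcomere geometry --------------------------
    "SLmin", "SLmax",       # admissible sarcomere length range (um)
    "len_thick", "len_hbare", "len_thin",   # filament geometry (um)
    "x_0",                  # cross-bridge power-stroke distance (um)
    "SL_rest",              # rest length: zero titin force (um)
    "SL_set",               # initial/reference length for the viscous term (um)
    # -- Ca2+/troponin kinetics -------------------------------------------
    "Kon",                  # troponin on-rate (1/(mM s))
    "KoffL", "KoffH",       # low/high affinity off-rates (1/s)
    "Koffmod",              # species modifier on the off-rates
    "Qkon", "Qkoff",        # Q10 factors
    "TropTotal",            # total troponin concentration (mM)
    # -- thin-filament regulation -----------------------------------------
    "perm50", "nperm",      # permissivity half-activation and steepness
    "kn_p", "kp_n",         # nonpermissive<->permissive rates (1/s)
    "Qkn_p", "Qkp_n",
    # -- cross-bridge cycling ---------------------------------------------
    "fapp", "gapp", "gslmod", "hf", "hfmdc", "hb", "hbmdc",
    "gxb", "sigmap", "sigman",
    "Qfapp", "Qgapp", "Qhf", "Qhb", "Qgxb",
    "xbmodsp",              # species scaling of cross-bridge cycling
    "TmpC",                 # CE temperature (deg C)
    "xPsi",                 # strain-rate scaling constant
    # -- sarcomere mechanics ----------------------------------------------
    "mass",                 # mass term (s^2/um, normalized force units)
    "visc",                 # viscosity (normalized force per um)
    "kxb",                  # tension scaling constant (kPa)
    "afterload",            # external normalized afterload
    # -- passive force ----------------------------------------------------
    "PCon_t", "PExp_t",     # titin
    "SL_collagen", "PCon_c", "PExp_c",  # collagen
    "ctn",                  # percent cardiomyocytes in the tissue
    # -- runtime/protocol flags -------------------------------------------
    "I_stim",               # current stimulus value (A/F), piecewise constant
    "coupling_strong",      # 1: myofilament feedback on, 0: feed-forward only
    "buffer_troponin_subtraction",  # 1: also remove troponin from the static buffer
    "isosarcometric",       # 1: clamp SL
    "ce_active",            # 0: freeze the contractile states entirely
)

# ---------------------------------------------------------------------------
# Derived outputs produced alongside the derivative (for recording).
OUT_FIELDS = (
    "INa", "INaL", "ICaL", "If", "IK1", "IKr", "IKs", "Ito",
    "INaCa", "INaK", "IpCa", "IbNa", "IbCa", "Istim",
    "Jup", "Jrel", "Jleak",
    "JCaBMyo",      # Ca2+ flux toward the myofilament (mM/s)
    "F_active",     # normalized active force
    "Tension",      # kxb * F_active (kPa)
    "F_passive",    # normalized passive force (tissue-composition law)
    "SOVFThin",     # thin-filament single-overlap fraction
    "FrSBXB",       # fraction of strongly-bound cross-bridges
    "TropApr",      # apparent fractional troponin Ca2+ occupancy
)

NSTATE = len(STATE_FIELDS)
NPARAM = len(PARAM_FIELDS)
NOUT = len(OUT_FIELDS)

STATE_INDEX = {name: i for i, name in enumerate(STATE_FIELDS)}
PARAM_INDEX = {name: i for i, name in enumerate(PARAM_FIELDS)}
OUT_INDEX = {name: i for i, name in enumerate(OUT_FIELDS)}

for _name, _i in STATE_INDEX.items():
    globals()["S_" + _name.upper()] = _i
for _name, _i in PARAM_INDEX.items():
    globals()["P_" + _name.upper()] = _i
for _name, _i in OUT_INDEX.items():
    globals()["O_" + _name.upper()] = _i

del _name, _i
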