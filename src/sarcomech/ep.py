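"""Host hiPSC-CM electrophysiology model.

A ventricular-like human induced pluripotent stem cell-derived cardiomyocyte
action-potential model of the Paci family: Hodgkin-Huxley sarcolemmal currents
(INa, ICaL, IKr, IKs, IK1, Ito, If, INaCa, INaK, IpCa, background Na/Ca), a
two-compartment Ca2+ subsystem (cytosol + SR with SERCA uptake, leak, and
Ca2+-induced Ca2+ release), and intracellular Na+ bookkeeping.  hiPSC-CMs beat
spontaneously: the depolarised diastolic potential, the funny current If and a
prominent reverse-mode INaCa drive automaticity, with cycle lengths around
1.6-1.9 s and APD90 near 400 ms.

Native units: volts, seconds, mM; currents in A/F.

The model is reimplemented from the published formulation of this lineage; it
couples to the contractile element through cytosolic Ca2+ (the troponin flux
jcb is debited from the Ca2+ mass balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .contractile import njit

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class EPParameters:
    """Sarcolemmal / SR parameters of the host AP model."""

    F: float = 96485.3415        # C/mol
    R: float = 8.314472          # J/(mol K)
    T: float = 310.0             # K
    Cm: float = 9.87109e-11      # F
    Vc: float = 8800.0           # um^3, cytosol
    V_SR: float = 583.73         # um^3, sarcoplasmic reticulum

    Nao: float = 151.0           # mM
    Ko: float = 5.4              # mM
    Cao: float = 1.8             # mM
    Ki: float = 150.0            # mM (fixed)

    g_Na: float = 3671.2302      # S/F
    g_CaL: float = 8.635702e-5   # m^3/(F s)
    g_Kr: float = 29.8667        # S/F
    g_Ks: float = 2.041          # S/F
    g_K1: float = 28.1492        # S/F
    g_f: float = 30.10312        # S/F
    E_f: float = -0.017          # V
    g_to: float = 29.9038        # S/F
    g_b_Na: float = 0.9          # S/F
    g_b_Ca: float = 0.69264      # S/F
    g_PCa: float = 0.4125        # A/F
    KPCa: float = 0.0005         # mM

    PNaK: float = 1.841424       # A/F
    Km_K: float = 1.0            # mM
    Km_Na: float = 40.0          # mM

    kNaCa: float = 4900.0        # A/F
    KmCa: float = 1.38           # mM
    KmNai: float = 87.5          # mM
    Ksat: float = 0.1
    alpha_ncx: float = 2.8571432
    gamma_ncx: float = 0.35

    PkNa: float = 0.03
    L0: float = 0.025
    Q_kr: float = 2.3

    Vmax_up: float = 0.56064     # mM/s
    Kup: float = 2.5e-4          # mM
    V_leak: float = 4.4444e-4    # 1/s
    a_rel: float = 16.464        # mM/s
    b_rel: float = 0.25          # mM
    c_rel: float = 8.232         # mM/s
    tau_g: float = 0.002         # s

    Buf_C: float = 0.25          # mM
    Kbuf_C: float = 0.001        # mM
    Buf_SR: float = 10.0         # mM
    Kbuf_SR: float = 0.3         # mM


_EP_FIELDS = tuple(f.name for f in fields(EPParameters))
_EP_INDEX = {n: i for i, n in enumerate(_EP_FIELDS)}
EPV_LEN = len(_EP_FIELDS)


def build_epv(p: EPParameters | None = None) -> np.ndarray:
    p = p or EPParameters()
    return np.array([getattr(p, n) for n in _EP_FIELDS], dtype=float)


# resolve indices once for the kernel
(JF, JR, JT, JCM, JVC, JVSR, JNAO, JKO, JCAO, JKI, JGNA, JGCAL, JGKR, JGKS,
 JGK1, JGF, JEF, JGTO, JGBNA, JGBCA, JGPCA, JKPCA, JPNAK, JKMK, JKMNA, JKNACA,
 JKMCA, JKMNAI, JKSAT, JALPHA, JGAMMA, JPKNA, JL0, JQKR, JVMAXUP, JKUP,
 JVLEAK, JAREL, JBREL, JCREL, JTAUG, JBUFC, JKBUFC, JBUFSR, JKBUFSR) = range(EPV_LEN)

#: State layout of the EP subsystem.
EP_STATE_NAMES = (
    "Vm", "m", "h", "j", "d", "f1", "f2", "fCa", "Xr1", "Xr2", "Xs", "Xf",
    "q", "r", "g", "Nai", "Cai", "Ca_SR",
)
N_EP_STATES = len(EP_STATE_NAMES)

# Resting-ish initial state (diastole of the spontaneous limit cycle).
EP_Y0 = np.array([
    -0.0743340057623841,   # Vm (V)
    0.102953468725004,     # m
    0.786926637881461,     # h
    0.253943221774722,     # j
    8.96088425225182e-5,   # d
    0.970411811263976,     # f1
    0.999965815466749,     # f2
    0.998925296531804,     # fCa
    0.00778547011240132,   # Xr1
    0.432116086418796,     # Xr2
    0.0322944866983666,    # Xs
    0.100615100568753,     # Xf
    0.839295925773219,     # q
    0.00573289893326379,   # r
    0.999999981028517,     # g
    10.9248496211574,      # Nai (mM)
    1.80773974140477e-5,   # Cai (mM)
    0.2734234751931,       # Ca_SR (mM)
])


@njit(cache=True)
def _ep_rhs(y, pv, istim, jcb):
    """Right-hand side of the host AP model.

    ``istim`` in A/F (depolarising positive), ``jcb`` in mM/s (Ca2+ flux onto
    the myofilament, debited from the cytosolic pool).
    Returns (dy, currents) with currents =
    (INa, ICaL, IKr, IKs, IK1, If, Ito, INaCa, INaK, IpCa, IbNa, IbCa,
     Irel, Iup, Ileak).
    """
    V = y[0]
    m, h, j = y[1], y[2], y[3]
    d, f1, f2, fca = y[4], y[5], y[6], y[7]
    xr1, xr2, xs, xf = y[8], y[9], y[10], y[11]
    q, r, g = y[12], y[13], y[14]
    nai, cai, casr = y[15], y[16], y[17]

    cai = max(cai, 1e-9)
    casr = max(casr, 1e-9)
    nai = max(nai, 1e-3)

    FF, RR, TT = pv[JF], pv[JR], pv[JT]
    rtf = RR * TT / FF
    vm_mv = V * 1000.0

    e_na = rtf * math.log(pv[JNAO] / nai)
    e_k = rtf * math.log(pv[JKO] / pv[JKI])
    e_ks = rtf * math.log((pv[JKO] + pv[JPKNA] * pv[JNAO])
                          / (pv[JKI] + pv[JPKNA] * nai))
    e_ca = 0.5 * rtf * math.log(pv[JCAO] / cai)

    # --- fast Na+ current ---
    i_na = pv[JGNA] * m**3 * h * j * (V - e_na)

    m_inf = (1.0 + math.exp((-vm_mv - 34.1) / 5.9)) ** (-1.0 / 3.0)
    alpha_m = 1.0 / (1.0 + math.exp((-vm_mv - 60.0) / 5.0))
    beta_m = (0.1 / (1.0 + math.exp((vm_mv + 35.0) / 5.0))
              + 0.1 / (1.0 + math.exp((vm_mv - 50.0) / 200.0)))
    tau_m = alpha_m * beta_m * 1e-3

    h_inf = 1.0 / math.sqrt(1.0 + math.exp((vm_mv + 72.1) / 5.7))
    if V < -0.04:
        alpha_h = 0.057 * math.exp(-(vm_mv + 80.0) / 6.8)
        beta_h = 2.7 * math.exp(0.079 * vm_mv) + 3.1e5 * math.exp(0.3485 * vm_mv)
        tau_h = 1.5 / ((alpha_h + beta_h) * 1000.0)
    else:
        tau_h = 2.542e-3

    j_inf = h_inf
    if V < -0.04:
        alpha_j = ((-25428.0 * math.exp(0.2444 * vm_mv)
                    - 6.948e-6 * math.exp(-0.04391 * vm_mv))
                   * (vm_mv + 37.78) / (1.0 + math.exp(0.311 * (vm_mv + 79.23))))
        beta_j = (0.02424 * math.exp(-0.01052 * vm_mv)
                  / (1.0 + math.exp(-0.1378 * (vm_mv + 40.14))))
    else:
        alpha_j = 0.0
        beta_j = (0.6 * math.exp(0.057 * vm_mv)
                  / (1.0 + math.exp(-0.1 * (vm_mv + 32.0))))
    tau_j = 7.0 / ((alpha_j + beta_j) * 1000.0)

    # --- L-type Ca2+ current ---
    expvf = math.exp(2.0 * V / rtf)
    if abs(expvf - 1.0) < 1e-9:
        ghk = pv[JGCAL] * 2.0 * FF * (cai - 0.341 * pv[JCAO])
    else:
        ghk = (pv[JGCAL] * 4.0 * V * FF / rtf
               * (cai * expvf - 0.341 * pv[JCAO]) / (expvf - 1.0))
    i_cal = ghk * d * f1 * f2 * fca

    d_inf = 1.0 / (1.0 + math.exp(-(vm_mv + 9.1) / 7.0))
    alpha_d = 0.25 + 1.4 / (1.0 + math.exp((-vm_mv - 35.0) / 13.0))
    beta_d = 1.4 / (1.0 + math.exp((vm_mv + 5.0) / 5.0))
    gamma_d = 1.0 / (1.0 + math.exp((-vm_mv + 50.0) / 20.0))
    tau_d = (alpha_d * beta_d + gamma_d) * 1e-3

    f1_inf = 1.0 / (1.0 + math.exp((vm_mv + 26.0) / 3.0))
    if f1_inf - f1 > 0.0:
        constf1 = 1.0 + 1433.0 * (cai - 50.0e-6)
    else:
        constf1 = 1.0
    tau_f1 = (20.0
              + 1102.5 * math.exp(-(((vm_mv + 27.0) ** 2) / 15.0) ** 2)
              + 200.0 / (1.0 + math.exp((13.0 - vm_mv) / 10.0))
              + 180.0 / (1.0 + math.exp((30.0 + vm_mv) / 10.0))) * constf1 / 1000.0

    f2_inf = 0.33 + 0.67 / (1.0 + math.exp((vm_mv + 35.0) / 4.0))
    tau_f2 = (600.0 * math.exp(-((vm_mv + 25.0) ** 2) / 170.0)
              + 31.0 / (1.0 + math.exp((25.0 - vm_mv) / 10.0))
              + 16.0 / (1.0 + math.exp((30.0 + vm_mv) / 10.0))) / 1000.0

    alpha_fca = 1.0 / (1.0 + (cai / 0.0006) ** 8)
    beta_fca = 0.1 / (1.0 + math.exp((cai - 0.0009) / 0.0001))
    gamma_fca = 0.3 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    fca_inf = (alpha_fca + beta_fca + gamma_fca) / 1.3156
    if V > -0.06 and fca_inf > fca:
        constfca = 0.0
    else:
        constfca = 1.0
    dfca = constfca * (fca_inf - fca) / 0.002

    # --- transient outward K+ ---
    i_to = pv[JGTO] * q * r * (V - e_k)
    q_inf = 1.0 / (1.0 + math.exp((vm_mv + 53.0) / 13.0))
    tau_q = (6.06 + 39.102 / (0.57 * math.exp(-0.08 * (vm_mv + 44.0))
                              + 0.065 * math.exp(0.1 * (vm_mv + 45.93)))) / 1000.0
    r_inf = 1.0 / (1.0 + math.exp(-(vm_mv - 22.3) / 18.75))
    tau_r = (2.75352 + 14.40516 / (1.037 * math.exp(0.09 * (vm_mv + 30.61))
                                   + 0.369 * math.exp(-0.12 * (vm_mv + 23.84)))) / 1000.0

    # --- slow delayed rectifier ---
    i_ks = (pv[JGKS] * xs**2 * (V - e_ks)
            * (1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)))
    xs_inf = 1.0 / (1.0 + math.exp((-vm_mv - 20.0) / 16.0))
    alpha_xs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - vm_mv) / 6.0))
    beta_xs = 1.0 / (1.0 + math.exp((-60.0 + vm_mv) / 20.0))
    tau_xs = alpha_xs * beta_xs / 1000.0

    # --- rapid delayed rectifier ---
    v_half = 1000.0 * (-rtf / pv[JQKR]
                       * math.log((1.0 + pv[JCAO] / 2.6) ** 4
                                  / (pv[JL0] * (1.0 + pv[JCAO] / 0.58) ** 4))
                       - 0.019)
    i_kr = pv[JGKR] * math.sqrt(pv[JKO] / 5.4) * xr1 * xr2 * (V - e_k)
    xr1_inf = 1.0 / (1.0 + math.exp((v_half - vm_mv) / 4.9))
    alpha_xr1 = 450.0 / (1.0 + math.exp((-45.0 - vm_mv) / 10.0))
    beta_xr1 = 6.0 / (1.0 + math.exp((30.0 + vm_mv) / 11.5))
    tau_xr1 = alpha_xr1 * beta_xr1 / 1000.0
    xr2_inf = 1.0 / (1.0 + math.exp((vm_mv + 88.0) / 50.0))
    alpha_xr2 = 3.0 / (1.0 + math.exp((-60.0 - vm_mv) / 20.0))
    beta_xr2 = 1.12 / (1.0 + math.exp((-60.0 + vm_mv) / 20.0))
    tau_xr2 = alpha_xr2 * beta_xr2 / 1000.0

    # --- inward rectifier ---
    dvk = vm_mv - e_k * 1000.0
    alpha_k1 = 3.91 / (1.0 + math.exp(0.5942 * (dvk - 200.0)))
    beta_k1 = ((-1.509 * math.exp(0.0002 * (dvk + 100.0))
                + math.exp(0.5886 * (dvk - 10.0)))
               / (1.0 + math.exp(0.4547 * dvk)))
    xk1_inf = alpha_k1 / (alpha_k1 + beta_k1)
    i_k1 = pv[JGK1] * xk1_inf * math.sqrt(pv[JKO] / 5.4) * (V - e_k)

    # --- funny current ---
    i_f = pv[JGF] * xf * (V - pv[JEF])
    xf_inf = 1.0 / (1.0 + math.exp((vm_mv + 77.85) / 5.0))
    tau_xf = 1900.0 / (1.0 + math.exp((vm_mv + 15.0) / 10.0)) / 1000.0

    # --- Na+/Ca2+ exchanger ---
    eg = math.exp(pv[JGAMMA] * V / rtf)
    egm = math.exp((pv[JGAMMA] - 1.0) * V / rtf)
    i_naca = (pv[JKNACA]
              * (eg * nai**3 * pv[JCAO] - egm * pv[JNAO] ** 3 * cai * pv[JALPHA])
              / ((pv[JKMNAI] ** 3 + pv[JNAO] ** 3) * (pv[JKMCA] + pv[JCAO])
                 * (1.0 + pv[JKSAT] * egm)))

    # --- Na+/K+ pump ---
    i_nak = (pv[JPNAK] * pv[JKO] * nai
             / ((pv[JKO] + pv[JKMK]) * (nai + pv[JKMNA])
                * (1.0 + 0.1245 * math.exp(-0.1 * V / rtf)
                   + 0.0353 * math.exp(-V / rtf))))

    i_pca = pv[JGPCA] * cai / (cai + pv[JKPCA])
    i_b_na = pv[JGBNA] * (V - e_na)
    i_b_ca = pv[JGBCA] * (V - e_ca)

    # --- SR fluxes ---
    i_up = pv[JVMAXUP] / (1.0 + pv[JKUP] ** 2 / cai**2)
    i_leak = (casr - cai) * pv[JVLEAK]
    i_rel = ((pv[JCREL] + pv[JAREL] * casr**2 / (pv[JBREL] ** 2 + casr**2))
             * d * g * 0.0411)

    if cai <= 0.00035:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        g_inf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    if g_inf > g and V > -0.06:
        const_g = 0.0
    else:
        const_g = 1.0

    # --- mass balances ---
    cm_conv = pv[JCM] / (2.0 * pv[JVC] * FF * 1e-18)
    bufc = 1.0 / (1.0 + pv[JBUFC] * pv[JKBUFC] / (cai + pv[JKBUFC]) ** 2)
    bufsr = 1.0 / (1.0 + pv[JBUFSR] * pv[JKBUFSR] / (casr + pv[JKBUFSR]) ** 2)

    dcai = bufc * (i_leak - i_up + i_rel - jcb
                   - (i_cal + i_b_ca + i_pca - 2.0 * i_naca) * cm_conv)
    dcasr = bufsr * pv[JVC] / pv[JVSR] * (i_up - (i_rel + i_leak))
    dnai = (-pv[JCM] * (i_na + i_b_na + 3.0 * i_nak + 3.0 * i_naca)
            / (FF * pv[JVC] * 1e-18))

    i_tot = (i_k1 + i_to + i_kr + i_ks + i_cal + i_nak + i_na + i_naca
             + i_pca + i_f + i_b_na + i_b_ca)

    dy = np.empty(18)
    dy[0] = -(i_tot - istim)
    dy[1] = (m_inf - m) / tau_m
    dy[2] = (h_inf - h) / tau_h
    dy[3] = (j_inf - j) / tau_j
    dy[4] = (d_inf - d) / tau_d
    dy[5] = (f1_inf - f1) / tau_f1
    dy[6] = (f2_inf - f2) / tau_f2
    dy[7] = dfca
    dy[8] = (xr1_inf - xr1) / tau_xr1
    dy[9] = (xr2_inf - xr2) / tau_xr2
    dy[10] = (xs_inf - xs) / tau_xs
    dy[11] = (xf_inf - xf) / tau_xf
    dy[12] = (q_inf - q) / tau_q
    dy[13] = (r_inf - r) / tau_r
    dy[14] = const_g * (g_inf - g) / pv[JTAUG]
    dy[15] = dnai
    dy[16] = dcai
    dy[17] = dcasr

    currents = (i_na, i_cal, i_kr, i_ks, i_k1, i_f, i_to, i_naca, i_nak,
                i_pca, i_b_na, i_b_ca, i_rel, i_up, i_leak)
    return dy, currents


def ep_derivatives(y: np.ndarray, t: float = 0.0, istim: float = 0.0,
                   jcb: float = 0.0,
                   p: EPParameters | None = None) -> tuple[np.ndarray, dict]:
    """Python-facing wrapper of the AP right-hand side with named currents."""
    pv = build_epv(p)
    dy, cur = _ep_rhs(np.asarray(y, dtype=float), pv, istim, jcb)
    if not np.all(np.isfinite(dy)):
        bad = [EP_STATE_NAMES[i] for i in range(len(dy)) if not math.isfinite(dy[i])]
        raise FloatingPointError(f"non-finite EP derivative(s) in: {bad}")
    names = ("I_Na", "I_CaL", "I_Kr", "I_Ks", "I_K1", "I_f", "I_to", "I_NCX",
             "I_NaK", "I_pCa", "I_bNa", "I_bCa", "J_rel", "J_up", "J_leak")
    return dy, dict(zip(names, map(float, cur)))
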