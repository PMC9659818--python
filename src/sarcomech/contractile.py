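"""Metabolite-sensitive contractile element of a human iPSC-derived cardiomyocyte.

The sarcomere is described by a mean-field four-state crossbridge (XB) cycle

    N_XB  <-- knpT/kpnT -->  P_XB  <-- ap1/am1 -->  XB_preR  <-- ap2/am2 -->  XB_pstR
                               ^---------------------- ap3/am3 ----------------^

where ``N_XB`` is the non-permissive thin-filament state, ``P_XB`` the
permissive state, and ``XB_preR``/``XB_pstR`` the strongly bound states before
and after the isomerised power stroke.  Three transitions carry metabolite
sensitivity:

* ``am1`` (detachment XB_preR -> P_XB) scales with inorganic phosphate,
  ``[Pi]/Pi_ref`` (Pi rebinding reverses the attachment step);
* ``am2`` (reverse power stroke) scales with protons and with the fraction of
  post-stroke heads carrying MgADP (rapid-equilibrium ADP substates);
* ``ap3`` (MgATP-induced detachment XB_pstR -> P_XB) scales with MgATP and is
  inhibited by MgADP competition.

All metabolite factors are normalised so that at reference concentrations
(MgADP = 36 uM, Pi = Pi_ref, pH = pH_ref, MgATP = 5 mM) each factor equals 1
and the rate set reduces to the underlying non-metabolic crossbridge model.
``am3`` closes the cycle thermodynamically via detailed balance against the
free energy of MgATP hydrolysis and is numerically negligible under
physiological conditions.

Rates are per second, concentrations in mM, lengths in um, tension in kPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

R_GAS = 8.314  # J / (mol K)
DG0_ATP = -30_000.0  # J/mol, standard free energy of MgATP hydrolysis

# Sarcomere geometry of the underlying crossbridge formulation (um)
LEN_THIN = 1.2
LEN_THICK = 1.65
LEN_HBARE = 0.1


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteState:
    """Concentrations of the metabolites coupled to crossbridge cycling.

    ``Pi_ref`` is the reference inorganic-phosphate level normalising the
    Pi-dependent detachment rate; disease overlays raise it while the simulated
    ``Pi`` pool stays at its control value (the calibration's way of encoding a
    chronically re-equilibrated phosphate balance).
    """

    MgATP: float = 5.0          # mM
    MgADP: float = 36e-3        # mM
    Pi: float = 2.0             # mM
    pH: float = 7.15
    MgATP_ref: float = 5.0      # mM
    MgADP_ref: float = 36e-3    # mM
    Pi_ref: float = 2.0         # mM
    pH_ref: float = 7.15
    kdADP: float = 4e-3         # mM, ADP dissociation of the post-stroke substates

    def __post_init__(self) -> None:
        for name in ("MgATP", "MgADP", "Pi"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.kdADP <= 0:
            raise ValueError("kdADP must be positive")

    @property
    def H(self) -> float:
        """Proton concentration in mM."""
        return 10.0 ** (-self.pH) * 1e3

    @property
    def H_ref(self) -> float:
        return 10.0 ** (-self.pH_ref) * 1e3


@dataclass
class CEParameters:
    """Contractile-element parameters (control mode).

    The first block is the calibrated control parameter set; the second block
    holds constants inherited from the underlying crossbridge formulation
    (attachment/detachment base rates, temperature Q10-style factors, strain
    conventions, passive-element constants).
    """

    # --- calibrated control values ---
    F1: float = 1.0              # DRX:SRX ratio multiplier, P_XB -> XB_preR influx
    F2: float = 1.0              # DRX:SRX ratio multiplier, XB_preR -> P_XB efflux
    kon: float = 62.5e3          # 1/(mM s), Ca2+ binding to troponin
    koffL: float = 200.0         # 1/s, Ca2+ unbinding, low-affinity site
    koffH: float = 25.0          # 1/s, Ca2+ unbinding, high-affinity site
    koffmod: float = 0.5         # unbinding modulation factor
    perm50: float = 0.6          # half-activation of the permissive gate
    nperm: float = 11.55         # cooperativity (Hill) of the permissive gate
    knp: float = 550.0           # 1/s, N_XB -> P_XB base rate
    kpn: float = 50.0            # 1/s, P_XB -> N_XB base rate
    mass: float = 2e-5           # s^2/um, sarcomere mass term
    kxb: float = 13.1            # kPa, tension scaler
    xbmodsp: float = 0.2         # species-dependent XB cycling rate scaler
    hf: float = 2000.0           # 1/s, XB_preR -> XB_pstR base rate
    Tmpc: float = 37.0           # deg C

    # --- inherited crossbridge constants ---
    fap: float = 500.0           # 1/s, attachment P_XB -> XB_preR
    gap: float = 70.0            # 1/s, detachment XB_preR -> P_XB
    hb: float = 400.0            # 1/s, reverse power stroke
    gxb: float = 70.0            # 1/s, MgATP-induced detachment
    Qfap: float = 6.25
    Qgap: float = 2.5
    Qhf: float = 6.25
    Qhb: float = 6.25
    Qgxb: float = 6.25
    Qkon: float = 1.5
    Qkoff: float = 1.3
    Qknp: float = 1.6
    Qkpn: float = 1.6
    x0: float = 0.007            # um, zero-motion post-stroke strain
    hfmdc: float = 5.0           # strain-dependence exponent coefficient
    phi: float = 2.0             # empirical strain scaler
    gslmod: float = 6.0          # overlap dependence of detachment
    sigmap: float = 8.0          # strain dependence of detachment, compressed heads
    sigman: float = 1.0          # strain dependence of detachment, stretched heads
    trpn_conc: float = 70e-3     # mM, total troponin regulatory sites
    kdHCa: float = 2e-4          # mM, proton competition on troponin C
    pi_exp: float = 1.0          # exponent of the (Pi/Pi_ref) detachment law

    # --- passive/length dynamics ---
    # visc and PCon_t are the two free constants of the passive element,
    # calibrated once so the control spontaneous fractional shortening matches
    # the model's validated value (~3.2%); see docs/methods.md
    visc: float = 1e-2           # normalized force s/um, viscous damping
    PCon_t: float = 8e-3         # titin-like parallel elastic scale
    PExp_t: float = 10.0         # titin-like exponent (1/um)
    SLrest_pas: float = 1.85     # um, slack length of the parallel elastic element
    PCon_c: float = 0.02         # collagen-like element scale
    PExp_c: float = 70.0         # collagen-like exponent (1/um)
    SL_col: float = 2.25         # um, collagen engagement length
    SL0: float = 1.90            # um, resting sarcomere length of the cell

    # --- output conventions ---
    atpase_net: bool = False     # ATPase = ap3*XB_pstR (False) or net ap3*pstR - am3*P

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.type == "float" and not isinstance(v, bool) and v is not None:
                if f.name not in ("Tmpc",) and v < 0:
                    raise ValueError(f"parameter {f.name} must be >= 0, got {v}")

    @property
    def ssxb_max(self) -> float:
        """Frozen duty-fraction normaliser of the active-tension formula.

        Steady-state post-stroke occupancy of the fully permissive cycle at
        zero strain and reference metabolites; the species and temperature
        scalers cancel in the ratio.
        """
        f, g, h, b, x = self.fap, self.gap, self.hf, self.hb, self.gxb
        return (f * h) / (x * h + f * h + x * g + b * f + b * g + x * f)


@dataclass(frozen=True)
class ModeOverlay:
    """Multiplicative/absolute modifications defining a simulation mode.

    The control overlay is the identity: every coefficient 1, every override
    ``None``.  ``scale`` entries multiply the named baseline parameter
    ("BL x factor" semantics); ``F1``/``F2``/metabolite entries replace.
    """

    name: str = "control"
    A: float = 1.0
    B: float = 1.0
    C: float = 1.0
    D: float = 1.0
    E: float = 1.0
    ap1_coef: float = 1.0
    ap2_coef: float = 1.0
    ap3_coef: float = 1.0
    am2_coef: float = 1.0
    tropreg_coef: float = 1.0
    F1: float | None = None
    F2: float | None = None
    scale: tuple[tuple[str, float], ...] = ()
    Pi_ref: float | None = None
    MgADP: float | None = None

    _SCALABLE = (
        "kon", "nperm", "perm50", "kpn", "knp", "koffmod", "koffL", "koffH", "hf",
    )

    def __post_init__(self) -> None:
        for c in ("A", "B", "C", "D", "E", "ap1_coef", "ap2_coef", "ap3_coef",
                  "am2_coef", "tropreg_coef"):
            if getattr(self, c) <= 0:
                raise ValueError(f"overlay coefficient {c} must be positive")
        for key, _ in self.scale:
            if key not in self._SCALABLE:
                raise ValueError(f"unknown scalable parameter {key!r}")
        # canonical ordering so serialisation round-trips compare equal
        object.__setattr__(self, "scale",
                           tuple(sorted(self.scale, key=lambda kv: kv[0])))

    @property
    def is_identity(self) -> bool:
        return (
            all(getattr(self, c) == 1.0 for c in
                ("A", "B", "C", "D", "E", "ap1_coef", "ap2_coef", "ap3_coef",
                 "am2_coef", "tropreg_coef"))
            and self.F1 is None and self.F2 is None and not self.scale
            and self.Pi_ref is None and self.MgADP is None
        )


# ---------------------------------------------------------------------------
# State containers (thin wrappers used by the functional API)
# ---------------------------------------------------------------------------


@dataclass
class XBState:
    P_XB: float = 0.0
    XB_preR: float = 0.0
    XB_pstR: float = 0.0

    @property
    def N_XB(self) -> float:
        """Non-permissive occupancy, enforced algebraically (never integrated)."""
        return 1.0 - (self.P_XB + self.XB_preR + self.XB_pstR)


@dataclass
class StrainState:
    x_XBpreR: float = 0.0
    x_XBpstR: float = 0.007

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_XBpreR) and math.isfinite(self.x_XBpstR)):
            raise ValueError("strains must be finite")


@dataclass
class ThinFilamentState:
    TropCaL: float = 0.0
    TropCaH: float = 0.0


@dataclass
class SarcomereState:
    SL: float = 1.90
    dSL_dt: float = 0.0
    isometric: bool = False

    def __post_init__(self) -> None:
        if self.SL <= 0:
            raise ValueError("sarcomere length must be positive")


@dataclass
class RateSet:
    """Instantaneous crossbridge transition rates (1/s)."""

    knpT: float
    kpnT: float
    ap1: float
    ap2: float
    ap3: float
    am1: float
    am2: float
    am3: float


# ---------------------------------------------------------------------------
# Parameter vector layout for the compiled kernels
# ---------------------------------------------------------------------------

_PV_FIELDS = (
    "F1", "F2", "kon", "koffL", "koffH", "koffmod", "perm50", "nperm",
    "knp", "kpn", "mass", "kxb", "xbmodsp", "hf", "Tmpc",
    "fap", "gap", "hb", "gxb",
    "Qfap", "Qgap", "Qhf", "Qhb", "Qgxb", "Qkon", "Qkoff", "Qknp", "Qkpn",
    "x0", "hfmdc", "phi", "gslmod", "sigmap", "sigman", "trpn_conc", "kdHCa",
    "pi_exp",
    "visc", "PCon_t", "PExp_t", "SLrest_pas", "PCon_c", "PExp_c", "SL_col", "SL0",
)
_PV_INDEX = {name: i for i, name in enumerate(_PV_FIELDS)}
_N_PAR = len(_PV_FIELDS)

# overlay coefficients
IA, IB, IC, ID, IE = _N_PAR, _N_PAR + 1, _N_PAR + 2, _N_PAR + 3, _N_PAR + 4
IAP1C, IAP2C, IAP3C, IAM2C, ITRC = (_N_PAR + 5, _N_PAR + 6, _N_PAR + 7,
                                    _N_PAR + 8, _N_PAR + 9)
# metabolites
IMGATP, IMGADP, IPI, IH = _N_PAR + 10, _N_PAR + 11, _N_PAR + 12, _N_PAR + 13
IMGATPR, IMGADPR, IPIREF, IHREF = (_N_PAR + 14, _N_PAR + 15, _N_PAR + 16,
                                   _N_PAR + 17)
IKDADP, IDGF = _N_PAR + 18, _N_PAR + 19
# derived / conventions
ISSXB, IATPNET = _N_PAR + 20, _N_PAR + 21
PV_LEN = _N_PAR + 22

# named indices used by the kernels (resolved once at import)
I_F1 = _PV_INDEX["F1"]
I_F2 = _PV_INDEX["F2"]
I_KON = _PV_INDEX["kon"]
I_KOFFL = _PV_INDEX["koffL"]
I_KOFFH = _PV_INDEX["koffH"]
I_KOFFMOD = _PV_INDEX["koffmod"]
I_PERM50 = _PV_INDEX["perm50"]
I_NPERM = _PV_INDEX["nperm"]
I_KNP = _PV_INDEX["knp"]
I_KPN = _PV_INDEX["kpn"]
I_MASS = _PV_INDEX["mass"]
I_KXB = _PV_INDEX["kxb"]
I_XBMODSP = _PV_INDEX["xbmodsp"]
I_HF = _PV_INDEX["hf"]
I_TMPC = _PV_INDEX["Tmpc"]
I_FAP = _PV_INDEX["fap"]
I_GAP = _PV_INDEX["gap"]
I_HB = _PV_INDEX["hb"]
I_GXB = _PV_INDEX["gxb"]
I_QFAP = _PV_INDEX["Qfap"]
I_QGAP = _PV_INDEX["Qgap"]
I_QHF = _PV_INDEX["Qhf"]
I_QHB = _PV_INDEX["Qhb"]
I_QGXB = _PV_INDEX["Qgxb"]
I_QKON = _PV_INDEX["Qkon"]
I_QKOFF = _PV_INDEX["Qkoff"]
I_QKNP = _PV_INDEX["Qknp"]
I_QKPN = _PV_INDEX["Qkpn"]
I_X0 = _PV_INDEX["x0"]
I_HFMDC = _PV_INDEX["hfmdc"]
I_PHI = _PV_INDEX["phi"]
I_GSLMOD = _PV_INDEX["gslmod"]
I_SIGMAP = _PV_INDEX["sigmap"]
I_SIGMAN = _PV_INDEX["sigman"]
I_TRPN = _PV_INDEX["trpn_conc"]
I_KDHCA = _PV_INDEX["kdHCa"]
I_PIEXP = _PV_INDEX["pi_exp"]
I_VISC = _PV_INDEX["visc"]
I_PCONT = _PV_INDEX["PCon_t"]
I_PEXPT = _PV_INDEX["PExp_t"]
I_SLREST = _PV_INDEX["SLrest_pas"]
I_PCONC = _PV_INDEX["PCon_c"]
I_PEXPC = _PV_INDEX["PExp_c"]
I_SLCOL = _PV_INDEX["SL_col"]
I_SL0 = _PV_INDEX["SL0"]


def apply_overlay(p: CEParameters, ov: ModeOverlay) -> CEParameters:
    """Return a new parameter set with an overlay's rescalings applied.

    "BL x factor" entries multiply the baseline value; F1/F2 replace.
    Applying the control (identity) overlay returns an equal parameter set,
    and application is idempotent per overlay by construction (the overlay
    always acts on the baseline passed in).
    """
    changes: dict[str, float] = {}
    for key, factor in ov.scale:
        changes[key] = getattr(p, key) * factor
    if ov.F1 is not None:
        changes["F1"] = ov.F1
    if ov.F2 is not None:
        changes["F2"] = ov.F2
    out = replace(p, **changes) if changes else replace(p)
    for name, v in (("kon", out.kon), ("knp", out.knp), ("kpn", out.kpn),
                    ("hf", out.hf), ("koffL", out.koffL), ("koffH", out.koffH)):
        if v <= 0:
            raise ValueError(f"overlay {ov.name!r} drives {name} non-positive")
    return out


def apply_overlay_metabolites(met: MetaboliteState, ov: ModeOverlay) -> MetaboliteState:
    """Return metabolite state with the overlay's Pi_ref/MgADP overrides."""
    kw = {}
    if ov.Pi_ref is not None:
        kw["Pi_ref"] = ov.Pi_ref
    if ov.MgADP is not None:
        kw["MgADP"] = ov.MgADP
    return replace(met, **kw) if kw else replace(met)


def build_pv(p: CEParameters, met: MetaboliteState, ov: ModeOverlay | None = None) -> np.ndarray:
    """Flatten parameters + overlay coefficients + metabolites into the kernel vector."""
    if ov is None:
        ov = ModeOverlay()
    p = apply_overlay(p, ov)
    met = apply_overlay_metabolites(met, ov)
    pv = np.zeros(PV_LEN)
    for name, i in _PV_INDEX.items():
        pv[i] = getattr(p, name)
    pv[IA], pv[IB], pv[IC], pv[ID], pv[IE] = ov.A, ov.B, ov.C, ov.D, ov.E
    pv[IAP1C], pv[IAP2C], pv[IAP3C] = ov.ap1_coef, ov.ap2_coef, ov.ap3_coef
    pv[IAM2C], pv[ITRC] = ov.am2_coef, ov.tropreg_coef
    pv[IMGATP], pv[IMGADP], pv[IPI], pv[IH] = met.MgATP, met.MgADP, met.Pi, met.H
    pv[IMGATPR], pv[IMGADPR] = met.MgATP_ref, met.MgADP_ref
    pv[IPIREF], pv[IHREF] = met.Pi_ref, met.H_ref
    pv[IKDADP] = met.kdADP
    # detailed-balance factor: exp(dG_ATP/RT) with concentrations in molar
    rt = R_GAS * (273.15 + p.Tmpc)
    conc = max(met.MgADP * 1e-3, 1e-30) * max(met.Pi * 1e-3, 1e-30) / max(met.MgATP * 1e-3, 1e-30)
    pv[IDGF] = math.exp(DG0_ATP / rt) * conc
    pv[ISSXB] = p.ssxb_max
    pv[IATPNET] = 1.0 if p.atpase_net else 0.0
    return pv


# ---------------------------------------------------------------------------
# Compiled kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _qt(Q, tmpc):
    return Q ** ((tmpc - 37.0) / 10.0)


@njit(cache=True)
def _overlap(SL):
    """Single-overlap fractions of thick/thin filaments and d(SOVFThin)/dSL."""
    sovr_ze = min(LEN_THICK / 2.0, SL / 2.0)
    sovr_cle = max(SL / 2.0 - (SL - LEN_THIN), LEN_HBARE / 2.0)
    len_sovr = sovr_ze - sovr_cle
    sovf_thick = len_sovr * 2.0 / (LEN_THICK - LEN_HBARE)
    sovf_thin = len_sovr / LEN_THIN
    dze = 0.5 if SL < LEN_THICK else 0.0
    dcle = -0.5 if (LEN_THIN - SL / 2.0) > (LEN_HBARE / 2.0) else 0.0
    dthin = (dze - dcle) / LEN_THIN
    return sovf_thick, sovf_thin, dthin


@njit(cache=True)
def _xb_rates(x_pre, x_pst, SL, pv):
    """Instantaneous XB cycle rates (ap1, am1, ap2, am2, ap3, am3)."""
    tmpc = pv[I_TMPC]
    xbsp = pv[I_XBMODSP]
    x0 = pv[I_X0]
    sovf_thick, _, _ = _overlap(SL)

    ap1 = pv[I_FAP] * pv[IA] * pv[IAP1C] * xbsp * _qt(pv[I_QFAP], tmpc)

    gapslmd = 1.0 + (1.0 - sovf_thick) * pv[I_GSLMOD]
    # Pi rebinding reverses the attachment step; the dependence on the
    # phosphate ratio is apportioned with exponent pi_exp, so the factor is 1
    # at the reference phosphate level
    am1 = (pv[I_GAP] * gapslmd * pv[IB] * xbsp * _qt(pv[I_QGAP], tmpc)
           * (pv[IPI] / pv[IPIREF]) ** pv[I_PIEXP])

    if x_pre > 0.0:
        sgn = 1.0
    elif x_pre < 0.0:
        sgn = -1.0
    else:
        sgn = 0.0
    # exponent clipped: |x_preR| beyond ~2.5 x0 is outside the physical range
    # of mean strains and would overflow the strain modifier
    arg = -sgn * pv[I_HFMDC] * (x_pre / x0) ** 2
    hfmd = math.exp(min(max(arg, -30.0), 30.0))
    ap2 = pv[I_HF] * hfmd * pv[IC] * pv[IAP2C] * xbsp * _qt(pv[I_QHF], tmpc)

    kd = pv[IKDADP]
    adp_bound = ((kd + pv[IMGADPR]) / pv[IMGADPR]) * (pv[IMGADP] / (kd + pv[IMGADP]))
    am2 = (pv[I_HB] * pv[ID] * pv[IAM2C] * xbsp * _qt(pv[I_QHB], tmpc)
           * (pv[IH] / pv[IHREF]) * adp_bound)

    if x_pst < x0:
        garg = pv[I_SIGMAP] * ((x0 - x_pst) / x0) ** 2
    else:
        garg = pv[I_SIGMAN] * ((x_pst - x0) / x0) ** 2
    gxbmd = math.exp(min(garg, 30.0))
    adp_free = (kd + pv[IMGADPR]) / (kd + pv[IMGADP])
    ap3 = (pv[I_GXB] * max(gxbmd, 1.0) * pv[IE] * pv[IAP3C] * xbsp
           * _qt(pv[I_QGXB], tmpc) * (pv[IMGATP] / pv[IMGATPR]) * adp_free)

    # thermodynamic closure of the cycle (detailed balance on ATP hydrolysis)
    am3 = ap1 * ap2 * ap3 / max(am1 * am2, 1e-300) * pv[IDGF]
    return ap1, am1, ap2, am2, ap3, am3


@njit(cache=True)
def _thin_rates(trop_l, trop_h, SL, pv):
    """Permissive-gate rates (knpT, kpnT) and the regulatory occupancy.

    The overlap-weighted Ca2+-bound troponin fraction (Tropreg) feeds a
    cooperative permissive function; the mode coefficient of the regulatory
    variable scales that permissive function (and its inverse in the backward
    rate), lowering the apparent cooperativity of Ca2+ activation without
    detaching the gate from its operating range.
    """
    tmpc = pv[I_TMPC]
    _, sovf_thin, _ = _overlap(SL)
    tropreg = (1.0 - sovf_thin) * trop_l + sovf_thin * trop_h
    base = math.sqrt(1.0 / (1.0 + (pv[I_PERM50] / max(tropreg, 1e-12)) ** pv[I_NPERM]))
    permtot = pv[ITRC] * base
    inprmt = min(1.0 / max(permtot, 1e-12), 100.0)
    knpT = pv[I_KNP] * permtot * _qt(pv[I_QKNP], tmpc)
    kpnT = pv[I_KPN] * inprmt * _qt(pv[I_QKPN], tmpc)
    return knpT, kpnT, tropreg


@njit(cache=True)
def _thin_derivs(cai, trop_l, trop_h, pv):
    """Troponin Ca2+ occupancy derivatives with proton competition on binding."""
    tmpc = pv[I_TMPC]
    hfac = (pv[I_KDHCA] + pv[IHREF]) / (pv[I_KDHCA] + pv[IH])
    konT = pv[I_KON] * _qt(pv[I_QKON], tmpc) * hfac
    koffLT = pv[I_KOFFL] * pv[I_KOFFMOD] * _qt(pv[I_QKOFF], tmpc)
    koffHT = pv[I_KOFFH] * pv[I_KOFFMOD] * _qt(pv[I_QKOFF], tmpc)
    d_l = konT * cai * (1.0 - trop_l) - koffLT * trop_l
    d_h = konT * cai * (1.0 - trop_h) - koffHT * trop_h
    return d_l, d_h


@njit(cache=True)
def _duty_fractions(ap1, am1, ap2, am2, ap3, am3):
    """Steady-state strongly bound occupancies of the clamped 3-state cycle.

    Spanning-tree (King-Altman) solution; identical to the null space of the
    rate matrix with P_XB + XB_preR + XB_pstR = 1.
    """
    pi_p = am1 * am2 + am1 * ap3 + ap2 * ap3
    pi_pre = ap1 * am2 + ap1 * ap3 + am3 * am2
    pi_pst = ap1 * ap2 + am3 * am1 + am3 * ap2
    den = pi_p + pi_pre + pi_pst
    return pi_pre / den, pi_pst / den, den


@njit(cache=True)
def _passive_force(SL, pv):
    """Parallel elastic (titin + collagen) force in normalised force units."""
    d = SL - pv[I_SLREST]
    if d >= 0.0:
        f_titin = pv[I_PCONT] * (math.exp(pv[I_PEXPT] * d) - 1.0)
    else:
        f_titin = -pv[I_PCONT] * (math.exp(-pv[I_PEXPT] * d) - 1.0)
    if SL > pv[I_SLCOL]:
        f_titin += pv[I_PCONC] * (math.exp(pv[I_PEXPC] * (SL - pv[I_SLCOL])) - 1.0)
    return f_titin


@njit(cache=True)
def _norm_force(p_pre, p_pst, x_pre, x_pst, SL, pv):
    sovf_thick, _, _ = _overlap(SL)
    return sovf_thick * (x_pst * p_pst + x_pre * p_pre) / (pv[I_X0] * pv[ISSXB])


@njit(cache=True)
def _ce_rhs(y, cai, pv, isometric):
    """Full contractile-element right-hand side.

    ``y`` = [TropCaL, TropCaH, P_XB, XB_preR, XB_pstR, x_preR, x_pstR, SL, dSL/dt].
    Returns (dy, tension_kPa, atpase_rate, jcb_mM_per_s).
    """
    trop_l, trop_h = y[0], y[1]
    p_xb, p_pre, p_pst = y[2], y[3], y[4]
    x_pre, x_pst = y[5], y[6]
    SL, sld = y[7], y[8]
    if isometric:
        sld = 0.0
    n_xb = 1.0 - (p_xb + p_pre + p_pst)

    d_l, d_h = _thin_derivs(cai, trop_l, trop_h, pv)
    knpT, kpnT, _ = _thin_rates(trop_l, trop_h, SL, pv)
    ap1, am1, ap2, am2, ap3, am3 = _xb_rates(x_pre, x_pst, SL, pv)

    # F1/F2 modulate the P_XB <-> XB_preR transition itself, so they appear in
    # both balances: the scheme stays probability-conserving for any F1, F2.
    dp = (knpT * n_xb + ap3 * p_pst + am1 * pv[I_F2] * p_pre
          - (kpnT + ap1 * pv[I_F1] + am3) * p_xb)
    dpre = (ap1 * pv[I_F1] * p_xb - am1 * pv[I_F2] * p_pre
            - ap2 * p_pre + am2 * p_pst)
    dpst = am3 * p_xb + ap2 * p_pre - (am2 + ap3) * p_pst

    pre_f, pst_f, _ = _duty_fractions(ap1, am1, ap2, am2, ap3, am3)
    phi = pv[I_PHI]
    x0 = pv[I_X0]
    dx_pre = 0.5 * sld + (phi / max(pre_f, 1e-12)) * (
        -ap1 * x_pre + am2 * (x_pst - x0 - x_pre))
    dx_pst = 0.5 * sld + (phi / max(pst_f, 1e-12)) * (ap2 * (x_pre + x0 - x_pst))

    fnorm = _norm_force(p_pre, p_pst, x_pre, x_pst, SL, pv)
    tension = pv[I_KXB] * fnorm

    if isometric:
        dsl = 0.0
        dsld = 0.0
    else:
        preload = _passive_force(pv[I_SL0], pv)
        fpas = _passive_force(SL, pv)
        dsl = sld
        dsld = (-fnorm - fpas + preload - pv[I_VISC] * sld) / pv[I_MASS]

    if pv[IATPNET] > 0.5:
        atpase = ap3 * p_pst - am3 * p_xb
    else:
        atpase = ap3 * p_pst

    _, sovf_thin, dthin = _overlap(SL)
    jcb = pv[I_TRPN] * ((1.0 - sovf_thin) * d_l + sovf_thin * d_h
                        + dthin * sld * (trop_h - trop_l))

    dy = np.empty(9)
    dy[0] = d_l
    dy[1] = d_h
    dy[2] = dp
    dy[3] = dpre
    dy[4] = dpst
    dy[5] = dx_pre
    dy[6] = dx_pst
    dy[7] = dsl
    dy[8] = dsld
    return dy, tension, atpase, jcb


# ---------------------------------------------------------------------------
# Functional API (spec-level operations; thin wrappers over the kernels)
# ---------------------------------------------------------------------------


def temperature_factor(Q: float, Tmpc: float) -> float:
    """Q10-style temperature scaling Q**((Tmpc-37)/10); equals 1 at 37 degC."""
    if Q <= 0:
        raise ValueError("temperature-dependence base Q must be positive")
    return float(Q ** ((Tmpc - 37.0) / 10.0))


def hfmd(strain: StrainState, p: CEParameters | None = None) -> float:
    """Strain modulation of the forward isomerisation rate.

    exp(-sign(x_preR) * hfmdc * (x_preR/x0)^2): 1 at zero strain, < 1 for
    positive strain (stretched heads isomerise more slowly), > 1 for negative.
    """
    p = p or CEParameters()
    if p.x0 <= 0:
        raise ValueError("x0 must be positive")
    x = strain.x_XBpreR
    return float(math.exp(-math.copysign(1.0, x) * p.hfmdc * (x / p.x0) ** 2)
                 if x != 0.0 else 1.0)


def compute_rates(
    xb: XBState,
    strain: StrainState,
    met: MetaboliteState,
    p: CEParameters,
    ov: ModeOverlay | None = None,
    SL: float = 2.2,
    thin: ThinFilamentState | None = None,
) -> RateSet:
    """Instantaneous transition rates of the activation + crossbridge cycle."""
    if min(met.MgATP, met.MgADP, met.Pi) < 0:
        raise ValueError("metabolite concentrations must be non-negative")
    if not (math.isfinite(strain.x_XBpreR) and math.isfinite(strain.x_XBpstR)):
        raise ValueError("strain state contains non-finite values")
    pv = build_pv(p, met, ov)
    ap1, am1, ap2, am2, ap3, am3 = _xb_rates(strain.x_XBpreR, strain.x_XBpstR, SL, pv)
    thin = thin or ThinFilamentState(1.0, 1.0)
    knpT, kpnT, _ = _thin_rates(thin.TropCaL, thin.TropCaH, SL, pv)
    return RateSet(knpT=float(knpT), kpnT=float(kpnT), ap1=float(ap1),
                   ap2=float(ap2), ap3=float(ap3), am1=float(am1),
                   am2=float(am2), am3=float(am3))


def xb_derivatives(xb: XBState, r: RateSet, ov: ModeOverlay | None = None,
                   p: CEParameters | None = None) -> tuple[float, float, float]:
    """Time derivatives of (P_XB, XB_preR, XB_pstR).

    F1 multiplies the ap1 transition and F2 the am1 transition (the DRX:SRX
    modulation of the P_XB <-> XB_preR exchange); both balances carry the
    modulated fluxes, so the scheme conserves occupancy for any F1, F2.
    N_XB is recovered algebraically, never integrated.
    """
    for name, v in (("P_XB", xb.P_XB), ("XB_preR", xb.XB_preR),
                    ("XB_pstR", xb.XB_pstR)):
        if v < -1e-9 or v > 1.0 + 1e-9:
            raise ValueError(f"{name} outside [0, 1]: {v}")
    if ov is not None and p is None:
        p = CEParameters()
    if p is not None and ov is not None:
        p = apply_overlay(p, ov)
    f1 = p.F1 if p is not None else 1.0
    f2 = p.F2 if p is not None else 1.0
    n = xb.N_XB
    dp = (r.knpT * n + r.ap3 * xb.XB_pstR + r.am1 * f2 * xb.XB_preR
          - (r.kpnT + r.ap1 * f1 + r.am3) * xb.P_XB)
    dpre = (r.ap1 * f1 * xb.P_XB - r.am1 * f2 * xb.XB_preR
            - r.ap2 * xb.XB_preR + r.am2 * xb.XB_pstR)
    dpst = r.am3 * xb.P_XB + r.ap2 * xb.XB_preR - (r.am2 + r.ap3) * xb.XB_pstR
    return dp, dpre, dpst


def steady_state_duty_fractions(r: RateSet) -> tuple[float, float]:
    """Steady-state strongly bound occupancies of the clamped 3-state cycle."""
    try:
        pre, pst, den = _duty_fractions(r.ap1, r.am1, r.ap2, r.am2, r.ap3,
                                        r.am3)
    except ZeroDivisionError:
        den = 0.0
    if den <= 0:
        raise ValueError("degenerate rate set: zero duty-fraction normaliser")
    return float(pre), float(pst)


def strain_derivatives(strain: StrainState, r: RateSet, dSL_dt: float,
                       p: CEParameters) -> tuple[float, float]:
    """Mean-strain dynamics of the strongly bound states."""
    pre_f, pst_f, den = _duty_fractions(r.ap1, r.am1, r.ap2, r.am2, r.ap3, r.am3)
    if den <= 0 or pre_f <= 0 or pst_f <= 0:
        raise ValueError("degenerate rate set: zero duty fraction")
    dx_pre = 0.5 * dSL_dt + (p.phi / pre_f) * (
        -r.ap1 * strain.x_XBpreR
        + r.am2 * (strain.x_XBpstR - p.x0 - strain.x_XBpreR))
    dx_pst = 0.5 * dSL_dt + (p.phi / pst_f) * (
        r.ap2 * (strain.x_XBpreR + p.x0 - strain.x_XBpstR))
    return float(dx_pre), float(dx_pst)


def thin_filament_derivatives(
    Cai: float,
    tf: ThinFilamentState,
    met: MetaboliteState,
    p: CEParameters,
    ov: ModeOverlay | None = None,
    SL: float = 2.2,
) -> dict[str, float]:
    """Troponin occupancy derivatives plus the permissive-gate rates."""
    if Cai < 0:
        raise ValueError("Cai must be non-negative")
    pv = build_pv(p, met, ov)
    d_l, d_h = _thin_derivs(Cai, tf.TropCaL, tf.TropCaH, pv)
    knpT, kpnT, tropreg = _thin_rates(tf.TropCaL, tf.TropCaH, SL, pv)
    return {"dTropCaL": float(d_l), "dTropCaH": float(d_h),
            "knpT": float(knpT), "kpnT": float(kpnT), "Tropreg": float(tropreg)}


def active_tension(xb: XBState, strain: StrainState, p: CEParameters,
                   SL: float = 2.2) -> float:
    """Active tension (kPa): strain-weighted strongly bound occupancy.

    Normalised by the maximal zero-strain duty fraction of the control cycle
    so that the tension scaler kxb acts linearly.
    """
    pv = build_pv(p, MetaboliteState())
    return float(p.kxb * _norm_force(xb.XB_preR, xb.XB_pstR, strain.x_XBpreR,
                                     strain.x_XBpstR, SL, pv))


def atpase_rate(xb: XBState, r: RateSet, net: bool = False) -> float:
    """Crossbridge ATP consumption flux (1/s): MgATP-binding detachment step."""
    flux = r.ap3 * xb.XB_pstR
    if net:
        flux -= r.am3 * xb.P_XB
    return float(flux)


def jcb_flux(dTropCaL: float, dTropCaH: float, SL: float, dSL_dt: float,
             tf: ThinFilamentState, p: CEParameters) -> float:
    """Net Ca2+ flux (mM/s) from the cytosol onto the troponin buffer."""
    _, sovf_thin, dthin = _overlap(SL)
    return float(p.trpn_conc * ((1.0 - sovf_thin) * dTropCaL
                                + sovf_thin * dTropCaH
                                + dthin * dSL_dt * (tf.TropCaH - tf.TropCaL)))


def passive_and_length_dynamics(s: SarcomereState, active_kPa: float,
                                p: CEParameters) -> tuple[float, float]:
    """Unloaded-shortening dynamics: (dSL/dt, d(dSL/dt)/dt).

    The mass term balances active + parallel-elastic force against a constant
    preload (the passive force at the resting length) and viscous damping.
    Isometric mode freezes the length.
    """
    if s.SL <= 0:
        raise ValueError(f"sarcomere length collapsed to {s.SL} um")
    if s.isometric:
        return 0.0, 0.0
    pv = build_pv(p, MetaboliteState())
    fnorm = active_kPa / p.kxb
    preload = _passive_force(p.SL0, pv)
    fpas = _passive_force(s.SL, pv)
    dsld = (-fnorm - fpas + preload - p.visc * s.dSL_dt) / p.mass
    return float(s.dSL_dt), float(dsld)


# Default resting CE state: relaxed, zero strongly bound XBs, slack length.
def initial_ce_state(p: CEParameters | None = None) -> np.ndarray:
    p = p or CEParameters()
    return np.array([
        0.0089,      # TropCaL (diastolic occupancy at ~100 nM Ca)
        0.0665,      # TropCaH
        0.0267,      # P_XB
        1.0e-4,      # XB_preR
        5.0e-5,      # XB_pstR
        3.5e-4,      # x_XBpreR (um)
        p.x0,        # x_XBpstR (um)
        p.SL0,       # SL (um)
        0.0,         # dSL/dt (um/s)
    ])
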