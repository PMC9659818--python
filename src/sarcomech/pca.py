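"""Isometric tension-pCa protocol, Hill analysis, and dose-response scans.

The tension-Ca2+ relationship is measured the way a skinned-fibre experiment
does: sarcomere length clamped, intracellular Ca2+ clamped at each point of a
pCa grid, and the contractile element integrated to steady state.  The curve is
summarised by a least-squares Hill fit

    T(pCa) = Tmax / (1 + 10^(nH (pCa - pCa50)))

where pCa50 is the -log10 of the Ca2+ concentration (in M) giving half-maximal
tension and nH the apparent cooperativity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .contractile import (
    CEParameters,
    MetaboliteState,
    ModeOverlay,
    _ce_rhs,
    build_pv,
    initial_ce_state,
)

__all__ = [
    "PCaCurve",
    "HillFit",
    "DEFAULT_PCA_GRID",
    "steady_isometric_tension",
    "isometric_pca_curve",
    "hill_fit",
    "mode_delta",
    "dose_response_scan",
    "DOSE_AP2_TABLES",
]

#: Default pCa grid spanning diastolic to saturating Ca2+ (descending pCa).
DEFAULT_PCA_GRID = np.round(np.arange(7.4, 3.99, -0.1), 3)

#: Sarcomere length (um) at which the clamped-Ca curves are measured.
PCA_SL = 2.2


@dataclass
class HillFit:
    pCa50: float
    nH: float
    Tmax: float
    residual_rms: float
    converged: bool


@dataclass
class PCaCurve:
    """Steady isometric tension sampled over a pCa grid."""

    pCa: np.ndarray
    tension: np.ndarray           # kPa
    mode: str = "control"
    T0: float | None = None       # normalisation tension (drug-free maximum)
    fit: HillFit | None = None

    def __post_init__(self) -> None:
        d = np.diff(self.pCa)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("pCa grid must be strictly monotone")
        if np.any(self.tension < -1e-9):
            raise ValueError("tensions must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        t0 = self.T0 if self.T0 else float(self.tension.max())
        return self.tension / t0


def steady_isometric_tension(
    pv: np.ndarray,
    cai: float,
    y0: np.ndarray,
    rel_tol: float = 1e-6,
    max_time: float = 400.0,
    chunk: float = 10.0,
) -> tuple[float, np.ndarray, float]:
    """Integrate the clamped-Ca CE to steady tension.

    Convergence criterion: relative tension change below ``rel_tol`` per
    second.  Returns (tension_kPa, final_state, residual); a point that fails
    to converge is reported with its residual rather than silently accepted.
    """
    y = y0.copy()
    t_prev = _ce_rhs(y, cai, pv, True)[1]
    elapsed = 0.0
    resid = np.inf
    while elapsed < max_time:
        sol = solve_ivp(
            lambda t, yy: _ce_rhs(yy, cai, pv, True)[0],
            (0.0, chunk), y, method="LSODA", rtol=1e-9, atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"CE integration failed at Cai={cai} mM: {sol.message}")
        y = sol.y[:, -1]
        elapsed += chunk
        t_now = _ce_rhs(y, cai, pv, True)[1]
        scale = max(abs(t_now), 1e-9)
        resid = abs(t_now - t_prev) / (scale * chunk)
        t_prev = t_now
        if resid < rel_tol:
            return float(t_now), y, float(resid)
    return float(t_prev), y, float(resid)


def isometric_pca_curve(
    mode: ModeOverlay | None = None,
    pca_grid: np.ndarray | None = None,
    p: CEParameters | None = None,
    met: MetaboliteState | None = None,
    sl: float = PCA_SL,
    T0: float | None = None,
    fit: bool = True,
) -> PCaCurve:
    """Steady isometric tension over a pCa grid for one mode.

    Points are visited from high pCa (relaxed) to low, warm-starting each
    point from the previous steady state (continuation), which mirrors the
    staircase Ca2+ protocol of skinned-fibre experiments and avoids spurious
    transients of the strain-dependent rates.
    """
    mode = mode or ModeOverlay()
    grid = np.asarray(DEFAULT_PCA_GRID if pca_grid is None else pca_grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        grid = np.sort(grid)[::-1]
    p = p or CEParameters()
    met = met or MetaboliteState()
    pv = build_pv(p, met, mode)
    y = initial_ce_state(p)
    y[7] = sl
    y[8] = 0.0
    tensions = np.empty_like(grid)
    for i, pca in enumerate(grid):
        cai = 10.0 ** (3.0 - pca)  # M -> mM
        tensions[i], y, resid = steady_isometric_tension(pv, cai, y)
        if resid > 1e-5:
            raise RuntimeError(
                f"tension-pCa point pCa={pca} did not converge (residual {resid:.2e}/s)")
    curve = PCaCurve(pCa=grid, tension=np.maximum(tensions, 0.0),
                     mode=mode.name, T0=T0)
    if fit:
        curve.fit = hill_fit(curve)
    return curve


def _hill(pca, pca50, nh, tmax):
    return tmax / (1.0 + 10.0 ** (nh * (pca - pca50)))


def hill_fit(curve: PCaCurve) -> HillFit:
    """Least-squares Hill fit of a tension-pCa curve.

    Requires at least 5 points spanning the activation transition; flat or
    non-sigmoidal data raise instead of extrapolating.
    """
    pca = np.asarray(curve.pCa, dtype=float)
    t = np.asarray(curve.tension, dtype=float)
    if len(pca) < 5:
        raise ValueError("Hill fit requires at least 5 pCa points")
    tmax = float(t.max())
    if tmax <= 0 or (tmax - t.min()) < 0.05 * tmax:
        raise ValueError("curve is flat: no activation transition to fit")
    half = np.argmin(np.abs(t - 0.5 * tmax))
    p0 = (float(pca[half]), 4.0, tmax)
    try:
        popt, pcov = curve_fit(
            _hill, pca, t, p0=p0,
            bounds=([pca.min() - 2.0, 0.05, 0.0],
                    [pca.max() + 2.0, 60.0, 10.0 * tmax]),
            maxfev=40000,
        )
    except RuntimeError as err:
        raise ValueError(f"Hill fit failed to converge: {err}") from None
    resid = t - _hill(pca, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    converged = bool(np.all(np.isfinite(pcov)))
    return HillFit(pCa50=float(popt[0]), nH=float(popt[1]), Tmax=float(popt[2]),
                   residual_rms=rms, converged=converged)


def mode_delta(metric: str, reference: dict, test: dict) -> float:
    """Percent change of a named metric: 100*(test - ref)/ref."""
    try:
        ref_v = reference[metric]
        test_v = test[metric]
    except KeyError as k:
        raise KeyError(f"metric {k} missing from one of the runs") from None
    if ref_v == 0:
        raise ZeroDivisionError(f"reference value of {metric!r} is zero")
    return 100.0 * (test_v - ref_v) / ref_v


# ---------------------------------------------------------------------------
# Dose-response machinery
# ---------------------------------------------------------------------------

#: Editable ap2-coefficient-per-dose tables for the dose-response scans.
#: These defaults are illustrative interpolations consistent with the single
#: calibrated doses (5 uM BLEB -> 0.012, 1 uM OM -> 0.02) and an inverse-Hill
#: trend in concentration; they are configuration, not measured constants.
DOSE_AP2_TABLES: dict[str, dict[float, float]] = {
    "BLEB": {0.0: 1.0, 0.5: 0.55, 1.0: 0.30, 2.0: 0.10, 5.0: 0.012, 10.0: 0.006},
    "OM": {0.0: 1.0, 0.1: 0.50, 0.3: 0.16, 1.0: 0.02, 3.0: 0.008, 10.0: 0.005},
}


def dose_response_scan(
    drug: str,
    ap2_table: dict[float, float] | None = None,
    pca_grid: np.ndarray | None = None,
    p: CEParameters | None = None,
) -> dict[float, PCaCurve]:
    """Isometric tension-pCa curves across a dose-indexed ap2-coefficient table.

    ap2 (the forward isomerisation coefficient) is the dominant variable
    governing maximal developed tension and carries the dose dependence: each
    dose maps to an ap2 coefficient applied to the control cycle, and the
    curves are normalised by the drug-free maximum T0.  ``ap2_coef = 1``
    reproduces the control curve exactly, and by the ap2 monotonicity of peak
    tension a monotone coefficient table yields monotone normalised maxima
    within [0, 1].
    """
    key = drug.upper()
    if key not in ("BLEB", "OM"):
        raise ValueError("drug must be 'BLEB' or 'OM'")
    table = DOSE_AP2_TABLES[key] if ap2_table is None else ap2_table
    if any(c <= 0 for c in table.values()):
        raise ValueError("ap2 coefficients must be positive")
    control = isometric_pca_curve(ModeOverlay(), pca_grid, p, fit=False)
    t0 = float(control.tension.max())
    out: dict[float, PCaCurve] = {}
    for dose in sorted(table):
        coef = table[dose]
        ov = ModeOverlay(name=f"{key}_{dose}uM", ap2_coef=coef)
        out[dose] = isometric_pca_curve(ov, pca_grid, p, T0=t0, fit=False)
    return out
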