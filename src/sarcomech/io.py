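"""Configuration files, biomarker-report serialisation, synthetic fixtures.

Config files are YAML whose keys mirror the published parameter names
verbatim (``F1, F2, K_on, K_offL, K_offH, perm50, n_perm, K_np, K_pn,
K_offmod, m, kxb, xbmodsp, h_f, Pi_ref, MgADP, ap1_coef, ap2_coef, ap3_coef,
am2_coef, Tropreg_coef, A, B, C, D, E``).

The synthetic-trace generators produce transients with analytically known
biomarkers (linear rise + single-exponential decay; trapezoidal APs) so the
analysis code can be tested without any simulation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .contractile import CEParameters, ModeOverlay

__all__ = [
    "overlay_to_config", "overlay_from_config", "load_config", "save_config",
    "write_report", "read_report",
    "synthetic_transient", "synthetic_ap", "synthetic_ca_waveform_file",
]

# published-name <-> field-name mapping
_PARAM_KEYS = {
    "F1": "F1", "F2": "F2", "K_on": "kon", "K_offL": "koffL",
    "K_offH": "koffH", "K_offmod": "koffmod", "perm50": "perm50",
    "n_perm": "nperm", "K_np": "knp", "K_pn": "kpn", "m": "mass",
    "kxb": "kxb", "xbmodsp": "xbmodsp", "h_f": "hf",
}
_COEF_KEYS = {
    "A": "A", "B": "B", "C": "C", "D": "D", "E": "E",
    "ap1_coef": "ap1_coef", "ap2_coef": "ap2_coef", "ap3_coef": "ap3_coef",
    "am2_coef": "am2_coef", "Tropreg_coef": "tropreg_coef",
}


def overlay_to_config(ov: ModeOverlay) -> dict:
    """Overlay -> config dict with published key names."""
    cfg: dict = {"name": ov.name}
    for pub, attr in _COEF_KEYS.items():
        v = getattr(ov, attr)
        if v != 1.0:
            cfg[pub] = v
    if ov.F1 is not None:
        cfg["F1"] = ov.F1
    if ov.F2 is not None:
        cfg["F2"] = ov.F2
    if ov.scale:
        inv = {v: k for k, v in _PARAM_KEYS.items()}
        cfg["scale"] = {inv[k]: f for k, f in ov.scale}
    if ov.Pi_ref is not None:
        cfg["Pi_ref"] = ov.Pi_ref
    if ov.MgADP is not None:
        cfg["MgADP"] = ov.MgADP
    return cfg


def overlay_from_config(cfg: dict) -> ModeOverlay:
    kw: dict = {"name": cfg.get("name", "custom")}
    for pub, attr in _COEF_KEYS.items():
        if pub in cfg:
            kw[attr] = float(cfg[pub])
    for key in ("F1", "F2", "Pi_ref", "MgADP"):
        if key in cfg:
            kw[key] = float(cfg[key])
    if "scale" in cfg:
        kw["scale"] = tuple((_PARAM_KEYS[k], float(v))
                            for k, v in cfg["scale"].items())
    return ModeOverlay(**kw)


def save_config(ov: ModeOverlay, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(overlay_to_config(ov), sort_keys=True))


def load_config(path: str | Path) -> ModeOverlay:
    return overlay_from_config(yaml.safe_load(Path(path).read_text()))


def baseline_config(p: CEParameters | None = None) -> dict:
    """Control parameter values under their published key names."""
    p = p or CEParameters()
    return {pub: getattr(p, attr) for pub, attr in _PARAM_KEYS.items()}


def write_report(report: dict, path: str | Path) -> None:
    """Flat key: value text document (one biomarker per line)."""
    lines = [f"{k}\t{v:.10g}" if isinstance(v, float) else f"{k}\t{v}"
             for k, v in report.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        k, v = line.split("\t")
        try:
            out[k] = float(v)
        except ValueError:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# Synthetic fixtures with closed-form biomarkers
# ---------------------------------------------------------------------------


def synthetic_transient(
    period_ms: float = 1000.0,
    n_beats: int = 3,
    baseline: float = 1e-4,
    amplitude: float = 2e-4,
    t_rise_ms: float = 50.0,
    tau_decay_ms: float = 150.0,
    t_start_ms: float = 50.0,
    dt_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic Ca2+-transient-like trace: linear rise, exponential decay.

    Closed forms (per beat): tRise10,50 = 0.4 t_rise; tRise10,90 = 0.8 t_rise;
    tRise10,peak = 0.9 t_rise; tDecay90,10 = tau ln 9; the 10%-crossing decay
    time after the peak is tau ln 10, so DURATION = 0.9 t_rise + tau ln 10.
    """
    if period_ms <= 0:
        raise ValueError("period must be positive")
    t = np.arange(0.0, n_beats * period_ms, dt_ms)
    y = np.full_like(t, baseline)
    if amplitude == 0.0:
        return t, y
    for k in range(n_beats):
        t0 = k * period_ms + t_start_ms
        rise = (t >= t0) & (t < t0 + t_rise_ms)
        y[rise] = baseline + amplitude * (t[rise] - t0) / t_rise_ms
        dec = (t >= t0 + t_rise_ms) & (t < (k + 1) * period_ms)
        y[dec] = baseline + amplitude * np.exp(-(t[dec] - t0 - t_rise_ms)
                                               / tau_decay_ms)
    return t, y


def synthetic_ap(
    period_ms: float = 1000.0,
    n_beats: int = 3,
    mdp_mV: float = -75.0,
    apa_mV: float = 105.0,
    t_up_ms: float = 2.0,
    plateau_ms: float = 200.0,
    t_fall_ms: float = 200.0,
    t_start_ms: float = 50.0,
    dt_ms: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoidal AP train with analytically known APDx.

    Measured from the end of the (fast linear) upstroke:
    APD_x = plateau_ms + (x/100) t_fall_ms; the upstroke adds at most
    t_up_ms/2 measurement offset.
    """
    if period_ms <= 0:
        raise ValueError("period must be positive")
    t = np.arange(0.0, n_beats * period_ms, dt_ms)
    v = np.full_like(t, mdp_mV)
    for k in range(n_beats):
        t0 = k * period_ms + t_start_ms
        up = (t >= t0) & (t < t0 + t_up_ms)
        v[up] = mdp_mV + apa_mV * (t[up] - t0) / t_up_ms
        pl = (t >= t0 + t_up_ms) & (t < t0 + t_up_ms + plateau_ms)
        v[pl] = mdp_mV + apa_mV
        f0 = t0 + t_up_ms + plateau_ms
        fa = (t >= f0) & (t < f0 + t_fall_ms)
        v[fa] = mdp_mV + apa_mV * (1.0 - (t[fa] - f0) / t_fall_ms)
    return t, v


def synthetic_ca_waveform_file(
    path: str | Path,
    period_ms: float = 1000.0,
    baseline: float = 1e-4,
    amplitude: float = 2.5e-4,
    t_rise_ms: float = 60.0,
    tau_decay_ms: float = 180.0,
    dt_ms: float = 1.0,
) -> Path:
    """Write a one-period two-column (time_ms, Cai_mM) waveform file."""
    t, y = synthetic_transient(period_ms, 1, baseline, amplitude, t_rise_ms,
                               tau_decay_ms, t_start_ms=20.0, dt_ms=dt_ms)
    path = Path(path)
    np.savetxt(path, np.column_stack([t, y]), fmt="%.8g",
               header="time_ms Cai_mM")
    return path


def trace_from_arrays(t_ms, columns: dict) -> "TimeSeries":
    """Assemble a TimeSeries from raw arrays (fixture helper)."""
    import pandas as pd

    from .coupled import TimeSeries
    data = {"time_ms": np.asarray(t_ms, dtype=float)}
    data.update({k: np.asarray(v, dtype=float) for k, v in columns.items()})
    return TimeSeries(data=pd.DataFrame(data), manifest={"mode": "synthetic"})
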