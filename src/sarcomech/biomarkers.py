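"""Action-potential, Ca2+-transient and contraction biomarkers.

Conventions (recorded here because several are conventions, not physics):

* Beats are segmented at the maximal-upstroke-velocity threshold crossing of
  the membrane potential (or, for Ca2+/tension-only traces, at the 10%
  upward crossing of the normalised transient).
* APD_x is measured from the upstroke to x% repolarisation between that
  beat's peak and its own maximum diastolic potential (MDP).
* Ca2+-transient rise/decay times use thresholds on the min-max normalised
  beat; DURATION is the time spent above 10% of the beat amplitude.
* RT50 ("time from peak contraction to 50% of relaxation") is measured on the
  contraction signal, i.e. the shortening trace (SL_rest - SL), from its peak
  to 50% recovery; ``RT50_tension_ms`` reports the tension-based variant,
  which is also used when no length signal exists (isometric runs).
* %FS = 100 * (SL_rest - SL_min) / SL_rest with SL_rest the diastolic
  (maximal) sarcomere length of the analysed window.

All reported times are in ms; per-beat values are averaged over the final
beats of the trace.
"""

from __future__ import annotations

import numpy as np

from .coupled import TimeSeries

__all__ = ["ap_biomarkers", "cat_tension_biomarkers", "biomarker_report"]


def _as_arrays(trace, ycol: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, TimeSeries):
        return trace["time_ms"], trace[ycol]
    raise TypeError("expected a TimeSeries")


def _resample(t: np.ndarray, y: np.ndarray, dt: float = 0.5):
    tu = np.arange(t[0], t[-1], dt)
    return tu, np.interp(tu, t, y)


def _upstroke_indices(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Indices where V crosses the mid-range upward (beat starts)."""
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin < 10.0:  # mV; flat or subthreshold trace
        raise ValueError("no beat detected: voltage range below 10 mV")
    thr = vmin + 0.5 * (vmax - vmin)
    ups = np.where((v[:-1] < thr) & (v[1:] >= thr))[0] + 1
    # collapse crossings closer than 50 ms (noise on the upstroke)
    if len(ups):
        keep = [ups[0]]
        for i in ups[1:]:
            if t[i] - t[keep[-1]] > 50.0:
                keep.append(i)
        ups = np.array(keep)
    if len(ups) == 0:
        raise ValueError("no beat detected")
    return ups


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """First linear-interpolated crossing of ``level``."""
    if rising:
        idx = np.where((y[:-1] < level) & (y[1:] >= level))[0]
    else:
        idx = np.where((y[:-1] > level) & (y[1:] <= level))[0]
    if len(idx) == 0:
        return float("nan")
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def ap_biomarkers(trace: TimeSeries, n_last: int = 3) -> dict[str, float]:
    """AP biomarkers: APA, MDP, CL, dV/dt_max, APD10/30/90, AP triangulation.

    Requires at least two full beats.  Raises ``ValueError`` on flat traces.
    """
    t, v = _as_arrays(trace, "Vm_mV")
    t, v = _resample(t, v)
    ups = _upstroke_indices(t, v)
    if len(ups) < 2:
        raise ValueError("need at least 2 beats for AP biomarkers")
    dt = t[1] - t[0]
    dvdt = np.gradient(v, dt)  # mV/ms == V/s

    beats = []
    for k in range(len(ups) - 1):
        s = slice(ups[k], ups[k + 1])
        tb, vb = t[s], v[s]
        pk = int(np.argmax(vb))
        vpk = vb[pk]
        mdp = float(vb[pk:].min())  # diastole of this beat
        # upstroke time: maximal dV/dt in the 30 ms window around the crossing
        w0 = max(ups[k] - int(30 / dt), 0)
        w1 = min(ups[k] + int(30 / dt), len(t) - 1)
        iup = w0 + int(np.argmax(dvdt[w0:w1]))
        t_up = t[iup]
        apa = vpk - mdp
        apds = {}
        for x in (10, 30, 90):
            level = vpk - (x / 100.0) * (vpk - mdp)
            tx = _crossing_time(tb[pk:], vb[pk:], level, rising=False)
            apds[x] = tx - t_up if np.isfinite(tx) else np.nan
        beats.append({
            "APA": apa, "MDP": mdp, "dVdt_max": float(dvdt[iup]),
            "APD10": apds[10], "APD30": apds[30], "APD90": apds[90],
            "t_up": t_up,
        })
    cls = np.diff([b["t_up"] for b in beats])
    use = beats[-n_last:]
    out = {
        "APA_mV": float(np.mean([b["APA"] for b in use])),
        "MDP_mV": float(np.mean([b["MDP"] for b in use])),
        "CL_ms": float(np.mean(cls[-n_last:])) if len(cls) else float("nan"),
        "dVdt_max_V_per_s": float(np.mean([b["dVdt_max"] for b in use])),
        "APD10_ms": float(np.nanmean([b["APD10"] for b in use])),
        "APD30_ms": float(np.nanmean([b["APD30"] for b in use])),
        "APD90_ms": float(np.nanmean([b["APD90"] for b in use])),
    }
    if np.isfinite(out["APD30_ms"]) and np.isfinite(out["APD90_ms"]):
        out["AP_tri"] = (out["APD90_ms"] - out["APD30_ms"]) / out["APD30_ms"]
    return out


def _transient_metrics(tb: np.ndarray, yb: np.ndarray) -> dict[str, float]:
    """Threshold timings of one normalised transient beat."""
    lo, hi = float(yb.min()), float(yb.max())
    amp = hi - lo
    if amp <= 0:
        raise ValueError("flat transient")
    yn = (yb - lo) / amp
    pk = int(np.argmax(yn))
    t10_up = _crossing_time(tb[:pk + 1], yn[:pk + 1], 0.10, rising=True)
    t50_up = _crossing_time(tb[:pk + 1], yn[:pk + 1], 0.50, rising=True)
    t90_up = _crossing_time(tb[:pk + 1], yn[:pk + 1], 0.90, rising=True)
    t90_dn = _crossing_time(tb[pk:], yn[pk:], 0.90, rising=False)
    t50_dn = _crossing_time(tb[pk:], yn[pk:], 0.50, rising=False)
    t10_dn = _crossing_time(tb[pk:], yn[pk:], 0.10, rising=False)
    return {
        "t10_up": t10_up, "t50_up": t50_up, "t90_up": t90_up,
        "t_peak": float(tb[pk]), "t90_dn": t90_dn, "t50_dn": t50_dn,
        "t10_dn": t10_dn, "peak": hi, "baseline": lo, "amp": amp,
    }


def _segment(t: np.ndarray, y: np.ndarray, ups_t: np.ndarray | None):
    """Beat windows from upstroke times, or from the transient itself."""
    if ups_t is not None and len(ups_t) >= 2:
        return [(float(a), float(b)) for a, b in zip(ups_t[:-1], ups_t[1:])]
    lo, hi = float(y.min()), float(y.max())
    if hi - lo <= max(1e-12, 0.01 * abs(hi)):
        raise ValueError("flat trace: no beat to segment")
    yn = (y - lo) / (hi - lo)
    idx = np.where((yn[:-1] < 0.10) & (yn[1:] >= 0.10))[0]
    if len(idx) < 2:
        raise ValueError("no beat detected in transient")
    times = t[idx]
    keep = [times[0]]
    for x in times[1:]:
        if x - keep[-1] > 100.0:
            keep.append(x)
    if len(keep) < 2:
        raise ValueError("no repeated beats detected in transient")
    return [(float(a), float(b)) for a, b in zip(keep[:-1], keep[1:])]


def cat_tension_biomarkers(trace: TimeSeries, n_last: int = 3) -> dict[str, float]:
    """Ca2+-transient, tension and shortening biomarkers of the final beats."""
    t = trace["time_ms"]
    try:
        tv, vv = _resample(*_as_arrays(trace, "Vm_mV"))
        ups_idx = _upstroke_indices(tv, vv)
        ups_t = tv[ups_idx]
    except (KeyError, ValueError):
        ups_t = None

    out: dict[str, float] = {}

    # --- Ca2+ transient ---
    tu, ca = _resample(t, trace["Cai_mM"])
    windows = _segment(tu, ca, ups_t)[-n_last:]
    mets = []
    for a, b in windows:
        s = (tu >= a) & (tu < b)
        if s.sum() > 10:
            mets.append(_transient_metrics(tu[s], ca[s]))
    if not mets:
        raise ValueError("no analysable Ca transient beat")
    def avg(f):
        vals = [f(m) for m in mets]
        return float(np.nanmean(vals))
    out["CaT_duration_ms"] = avg(lambda m: m["t10_dn"] - m["t10_up"])
    out["CaT_tRise10_peak_ms"] = avg(lambda m: m["t_peak"] - m["t10_up"])
    out["CaT_tRise10_50_ms"] = avg(lambda m: m["t50_up"] - m["t10_up"])
    out["CaT_tRise10_90_ms"] = avg(lambda m: m["t90_up"] - m["t10_up"])
    out["CaT_tDecay90_10_ms"] = avg(lambda m: m["t10_dn"] - m["t90_dn"])
    out["CaT_peak_mM"] = avg(lambda m: m["peak"])
    out["CaT_amp_mM"] = avg(lambda m: m["amp"])

    # --- active tension ---
    tu, ten = _resample(t, trace["tension_kPa"])
    if ten.max() - ten.min() <= 1e-9:
        raise ValueError("flat tension trace")
    twin = _segment(tu, ten, ups_t)[-n_last:]
    tmets = []
    for a, b in twin:
        s = (tu >= a) & (tu < b)
        if s.sum() > 10:
            tmets.append(_transient_metrics(tu[s], ten[s]))
    out["AT_magnitude_kPa"] = float(np.nanmean([m["amp"] for m in tmets]))
    out["AT_peak_kPa"] = float(np.nanmean([m["peak"] for m in tmets]))
    out["RT50_tension_ms"] = float(np.nanmean([m["t50_dn"] - m["t_peak"]
                                               for m in tmets]))
    out["AT_tPeak_ms"] = float(np.nanmean([m["t_peak"] - m["t10_up"] for m in tmets]))
    out["RT50_ms"] = out["RT50_tension_ms"]

    # --- fractional shortening and contraction-based relaxation ---
    if "SL_um" in trace.columns:
        tu, sl = _resample(t, trace["SL_um"])
        a, b = twin[0][0], twin[-1][1]
        s = (tu >= a) & (tu < b)
        sl_rest = float(sl[s].max())
        sl_min = float(sl[s].min())
        out["FS_pct"] = 100.0 * (sl_rest - sl_min) / sl_rest
        if sl_rest - sl_min > 1e-5:
            short = sl_rest - sl  # contraction (shortening) signal
            swin = _segment(tu, short, ups_t)[-n_last:]
            smets = []
            for a, b in swin:
                ss = (tu >= a) & (tu < b)
                if ss.sum() > 10:
                    smets.append(_transient_metrics(tu[ss], short[ss]))
            if smets:
                out["RT50_ms"] = float(np.nanmean(
                    [m["t50_dn"] - m["t_peak"] for m in smets]))

    # --- cycle-averaged ATPase over the final beats ---
    if "atpase" in trace.columns:
        tu, atp = _resample(t, trace["atpase"])
        s = (tu >= twin[0][0]) & (tu < twin[-1][1])
        out["ATPase_mean"] = float(np.trapezoid(atp[s], tu[s])
                                   / (tu[s][-1] - tu[s][0]))
        out["ATPase_peak"] = float(atp[s].max())

    return out


def biomarker_report(trace: TimeSeries, n_last: int = 3) -> dict[str, float]:
    """Full per-run biomarker dictionary (AP + CaT + tension + shortening)."""
    rep: dict[str, float] = {}
    try:
        rep.update(ap_biomarkers(trace, n_last))
    except (KeyError, ValueError):
        pass
    rep.update(cat_tension_biomarkers(trace, n_last))
    return rep
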