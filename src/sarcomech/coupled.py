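"""Coupled electromechanics: host AP model + metabolite-sensitive sarcomere.

The two subsystems exchange exactly two signals: the cytosolic Ca2+
concentration drives troponin binding in the contractile element, and the net
Ca2+ flux onto troponin (jcb) is debited from the electrophysiology model's
Ca2+ mass balance.  The combined state is integrated with a stiff
variable-order solver (LSODA) with a maximum step of 1 ms and an initial step
of 20 us.

Protocols: spontaneous (no stimulus; hiPSC-CMs are automatic) or paced
(suprathreshold current pulses at a fixed rate, 5 ms, ~5.6 A/F).  Runs can be
driven to a quasi-steady state: integration proceeds beat by beat until the
beat-to-beat change of APD90, Ca2+-transient peak and tension peak all fall
below 0.1%.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import __version__
from .contractile import (
    CEParameters,
    MetaboliteState,
    ModeOverlay,
    _ce_rhs,
    build_pv,
    initial_ce_state,
    njit,
)
from .ep import EP_Y0, N_EP_STATES, build_epv, _ep_rhs

__all__ = [
    "SolverSettings",
    "StimulusProtocol",
    "TimeSeries",
    "stimulus_protocol",
    "run_simulation",
    "prescribed_ca_driver",
    "run_ce_prescribed",
    "initial_state",
    "load_mode_snapshot",
]

N_CE_STATES = 9
N_STATES = N_EP_STATES + N_CE_STATES

#: cytosolic Ca2+ lives at this index of the coupled state vector
_ICAI = 16


@dataclass
class SolverSettings:
    """Stiff-solver configuration for the coupled model."""

    method: str = "LSODA"
    max_step: float = 1e-3       # s
    first_step: float = 2e-5     # s
    rtol: float = 1e-7
    atol: float = 1e-9
    beats: int = 800             # upper bound on beats
    qss_tol: float = 1e-3        # beat-to-beat relative change for quasi-steady state
    qss: bool = True             # stop early once quasi-steady

    def __post_init__(self) -> None:
        if self.max_step < self.first_step:
            raise ValueError("max_step must be >= first_step")


@dataclass
class StimulusProtocol:
    kind: str = "spontaneous"    # 'spontaneous' | 'paced'
    rate_hz: float = 1.0
    amplitude: float = 5.57e0    # A/F, depolarising
    duration: float = 5e-3       # s

    @property
    def period(self) -> float:
        return 1.0 / self.rate_hz


def stimulus_protocol(kind: str, rate_hz: float = 1.0) -> StimulusProtocol:
    """Build a stimulus protocol: paced pulses at ``rate_hz`` or none."""
    if kind not in ("spontaneous", "paced"):
        raise ValueError("protocol kind must be 'spontaneous' or 'paced'")
    if kind == "paced" and rate_hz <= 0:
        raise ValueError("pacing rate must be positive")
    return StimulusProtocol(kind=kind, rate_hz=rate_hz)


@dataclass
class TimeSeries:
    """Uniformly sampled trajectories of a run plus its manifest."""

    data: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key].to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self.manifest, default=str) + "\n")
        self.data.to_csv(path, sep="\t", index=False, mode="a",
                         float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path) -> "TimeSeries":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
        manifest = json.loads(first[1:].strip()) if first.startswith("#") else {}
        data = pd.read_csv(path, sep="\t", comment="#")
        return cls(data=data, manifest=manifest)


@njit(cache=True)
def _coupled_rhs(t, y, epv, cev, stim_amp, stim_dur, stim_period, paced):
    """Joint RHS: CE first (yields jcb), then EP with the Ca2+ debit."""
    y_ep = y[:18]
    y_ce = y[18:]
    cai = max(y[16], 1e-9)
    dy_ce, tension, atpase, jcb = _ce_rhs(y_ce, cai, cev, False)
    istim = 0.0
    if paced and (t % stim_period) < stim_dur:
        istim = stim_amp
    dy_ep, _ = _ep_rhs(y_ep, epv, istim, jcb)
    out = np.empty(27)
    out[:18] = dy_ep
    out[18:] = dy_ce
    return out


@njit(cache=True)
def _coupled_outputs(y, epv, cev):
    y_ce = y[18:]
    cai = max(y[16], 1e-9)
    dy_ce, tension, atpase, jcb = _ce_rhs(y_ce, cai, cev, False)
    _, cur = _ep_rhs(y[:18], epv, 0.0, jcb)
    return tension, atpase, jcb, cur[7], cur[8], cur[1], cur[9]


# ---------------------------------------------------------------------------
# Per-mode steady-state snapshots
# ---------------------------------------------------------------------------

_SNAPSHOT_FILE = Path(__file__).with_name("mode_snapshots.json")


def initial_state(p: CEParameters | None = None) -> np.ndarray:
    """Generic (non-steady) initial condition: EP diastole + relaxed sarcomere."""
    return np.concatenate([EP_Y0, initial_ce_state(p or CEParameters())])


def load_mode_snapshot(mode: str, protocol: str) -> np.ndarray | None:
    """Pre-equilibrated state for (mode, protocol), if shipped."""
    if not _SNAPSHOT_FILE.exists():
        return None
    snaps = json.loads(_SNAPSHOT_FILE.read_text())
    key = f"{mode}:{protocol}"
    if key in snaps:
        return np.asarray(snaps[key], dtype=float)
    return None


def _beat_metrics(t: np.ndarray, V: np.ndarray, cai: np.ndarray,
                  tension: np.ndarray) -> tuple[float, float, float] | None:
    """Quick (APD90, CaT peak, tension peak) of the last complete beat."""
    vmax, vmin = V.max(), V.min()
    if vmax - vmin < 20.0:
        return None
    thr = vmin + 0.5 * (vmax - vmin)
    up = np.where((V[:-1] < thr) & (V[1:] >= thr))[0]
    if len(up) < 1:
        return None
    i0 = up[-1]
    seg = slice(i0, len(V))
    vseg = V[seg]
    pk = int(np.argmax(vseg))
    vpk = vseg[pk]
    mdp = vmin
    v90 = vpk - 0.9 * (vpk - mdp)
    below = np.where(vseg[pk:] <= v90)[0]
    apd90 = (t[seg][pk + below[0]] - t[i0]) if len(below) else (t[-1] - t[i0])
    return float(apd90), float(cai.max()), float(tension.max())


def run_simulation(
    mode: ModeOverlay | None = None,
    protocol: StimulusProtocol | str = "spontaneous",
    settings: SolverSettings | None = None,
    p: CEParameters | None = None,
    met: MetaboliteState | None = None,
    y0: np.ndarray | None = None,
    keep_s: float = 10.0,
    sample_ms: float = 1.0,
) -> TimeSeries:
    """Run the coupled model and return uniformly resampled trajectories.

    Integration proceeds in one-beat windows (paced) or 2-s windows
    (spontaneous).  With ``settings.qss`` the run stops once APD90, the CaT
    peak and the tension peak each change by less than ``qss_tol`` between
    consecutive windows; ``settings.beats`` caps the total length either way.
    The last ``keep_s`` seconds are returned.
    """
    mode = mode or ModeOverlay()
    if isinstance(protocol, str):
        protocol = stimulus_protocol(protocol)
    settings = settings or SolverSettings()
    p = p or CEParameters()
    met = met or MetaboliteState()
    epv = build_epv()
    cev = build_pv(p, met, mode)
    paced = protocol.kind == "paced"
    window = protocol.period if paced else 2.0

    if y0 is None:
        y0 = load_mode_snapshot(mode.name, protocol.kind)
    if y0 is None:
        y0 = initial_state(p)
    y = np.asarray(y0, dtype=float).copy()
    if len(y) != N_STATES:
        raise ValueError(f"state vector must have {N_STATES} entries, got {len(y)}")

    dt = sample_ms * 1e-3
    n_keep = int(round(keep_s / window))
    max_windows = settings.beats if paced else max(settings.beats // 2, n_keep + 2)
    kept_t: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    prev = None
    t0 = 0.0
    wall0 = _time.time()
    for w in range(max_windows):
        t_eval = t0 + np.arange(0.0, window, dt)
        sol = solve_ivp(
            _coupled_rhs, (t0, t0 + window), y,
            args=(epv, cev, protocol.amplitude, protocol.duration,
                  protocol.period, paced),
            method=settings.method, max_step=settings.max_step,
            first_step=settings.first_step, rtol=settings.rtol,
            atol=settings.atol, t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(
                f"solver failed at t={sol.t[-1] if len(sol.t) else t0:.3f}s "
                f"(window {w}): {sol.message}; |y|max={np.abs(y).max():.3g}")
        y = sol.y[:, -1].copy()
        if y[25] <= 0:  # sarcomere length
            raise RuntimeError(f"sarcomere length collapsed to {y[25]:.3g} um")
        t0 += window
        kept_t.append(sol.t)
        kept_y.append(sol.y)
        if len(kept_t) > max(n_keep, 2):
            kept_t.pop(0)
            kept_y.pop(0)
        if settings.qss and w >= 2:
            tt = kept_t[-1]
            tension = np.array([
                _coupled_outputs(kept_y[-1][:, i], epv, cev)[0]
                for i in range(0, kept_y[-1].shape[1], 10)])
            mb = _beat_metrics(kept_t[-1], kept_y[-1][0] * 1000.0,
                               kept_y[-1][16], tension)
            if mb is not None and prev is not None:
                rel = [abs(a - b) / max(abs(b), 1e-12) for a, b in zip(mb, prev)]
                if max(rel) < settings.qss_tol:
                    prev = mb
                    break
            prev = mb

    t = np.concatenate(kept_t)
    ys = np.concatenate(kept_y, axis=1)
    n = ys.shape[1]
    tension = np.empty(n)
    atpase = np.empty(n)
    jcb = np.empty(n)
    incx = np.empty(n)
    inak = np.empty(n)
    ical = np.empty(n)
    ipca = np.empty(n)
    for i in range(n):
        tension[i], atpase[i], jcb[i], incx[i], inak[i], ical[i], ipca[i] = (
            _coupled_outputs(ys[:, i], epv, cev))

    data = pd.DataFrame({
        "time_ms": (t - t[0]) * 1000.0,
        "Vm_mV": ys[0] * 1000.0,
        "Cai_mM": ys[16],
        "tension_kPa": tension,
        "atpase": atpase,
        "SL_um": ys[25],
        "jcb": jcb,
        "I_NCX": incx,
        "I_NaK": inak,
        "I_CaL": ical,
        "I_pCa": ipca,
        "Nai_mM": ys[15],
    })
    manifest = {
        "mode": mode.name,
        "protocol": asdict(protocol),
        "solver": asdict(settings),
        "windows_run": w + 1,
        "quasi_steady": bool(settings.qss and w + 1 < max_windows),
        "wall_s": round(_time.time() - wall0, 2),
        "code_version": __version__,
    }
    ts = TimeSeries(data=data, manifest=manifest)
    ts.final_state = y  # type: ignore[attr-defined]
    return ts


# ---------------------------------------------------------------------------
# Prescribed-Ca2+ driving of the contractile element alone
# ---------------------------------------------------------------------------


def prescribed_ca_driver(source, unit: str = "mM"):
    """Ca2+ waveform from a two-column (time_ms, concentration) table.

    Accepts a path to a delimited text file or an (N, 2) array.  The waveform
    is linearly interpolated and extended periodically; times must be strictly
    increasing.  Returns ``cai(t_s)`` in mM.
    """
    if isinstance(source, (str, Path)):
        arr = np.loadtxt(source)
    else:
        arr = np.asarray(source, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("expected two columns: time_ms, concentration")
    t_ms, ca = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t_ms) <= 0):
        raise ValueError("time column must be strictly increasing")
    scale = {"mM": 1.0, "uM": 1e-3, "nM": 1e-6}[unit]
    ca = ca * scale
    period = t_ms[-1] - t_ms[0]

    def cai(t_s: float | np.ndarray) -> float | np.ndarray:
        tm = np.asarray(t_s, dtype=float) * 1000.0
        tm = t_ms[0] + np.mod(tm - t_ms[0], period)
        out = np.interp(tm, t_ms, ca)
        return float(out) if out.ndim == 0 else out

    cai.period_ms = period  # type: ignore[attr-defined]
    return cai


def run_ce_prescribed(
    cai_fun,
    duration_s: float = 10.0,
    mode: ModeOverlay | None = None,
    p: CEParameters | None = None,
    met: MetaboliteState | None = None,
    isometric: bool = False,
    sample_ms: float = 1.0,
    sl: float | None = None,
) -> TimeSeries:
    """Drive the contractile element with a prescribed Ca2+ waveform."""
    mode = mode or ModeOverlay()
    p = p or CEParameters()
    met = met or MetaboliteState()
    cev = build_pv(p, met, mode)
    y0 = initial_ce_state(p)
    if sl is not None:
        y0[7] = sl
    t_eval = np.arange(0.0, duration_s, sample_ms * 1e-3)
    sol = solve_ivp(
        lambda t, y: _ce_rhs(y, max(cai_fun(t), 0.0), cev, isometric)[0],
        (0.0, duration_s), y0, method="LSODA", max_step=1e-3,
        rtol=1e-8, atol=1e-10, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"CE integration failed: {sol.message}")
    n = sol.y.shape[1]
    tension = np.empty(n)
    atpase = np.empty(n)
    jcb = np.empty(n)
    cai_v = np.array([max(cai_fun(tt), 0.0) for tt in sol.t])
    for i in range(n):
        _, tension[i], atpase[i], jcb[i] = _ce_rhs(sol.y[:, i], cai_v[i], cev,
                                                   isometric)
    data = pd.DataFrame({
        "time_ms": sol.t * 1000.0,
        "Cai_mM": cai_v,
        "tension_kPa": tension,
        "atpase": atpase,
        "SL_um": sol.y[7],
        "jcb": jcb,
    })
    manifest = {"mode": mode.name, "protocol": {"kind": "prescribed_ca"},
                "isometric": isometric, "code_version": __version__}
    return TimeSeries(data=data, manifest=manifest)
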