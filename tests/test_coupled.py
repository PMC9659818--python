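"""Coupled model: conservation, Ca2+ mass balance, drivers, trace round trips."""

import numpy as np
import pytest

from sarcomech.contractile import CEParameters, MetaboliteState, ModeOverlay, \
    build_pv, _ce_rhs
from sarcomech.coupled import (
    SolverSettings,
    TimeSeries,
    load_mode_snapshot,
    prescribed_ca_driver,
    run_ce_prescribed,
    run_simulation,
)
from sarcomech.io import synthetic_ca_waveform_file


@pytest.fixture(scope="module")
def short_paced():
    return run_simulation(ModeOverlay(), "paced",
                          SolverSettings(beats=6, qss=False), keep_s=4.0)


class TestCoupledRun:
    def test_occupancy_conservation_over_whole_run(self, short_paced):
        """P_XB + XB_preR + XB_pstR + N_XB = 1 by algebraic closure, and the
        integrated occupancies stay inside the probability simplex."""
        y = short_paced.final_state
        p, pre, pst = y[20], y[21], y[22]
        total = p + pre + pst + (1.0 - (p + pre + pst))
        assert total == 1.0
        assert -1e-9 <= p + pre + pst <= 1.0 + 1e-9

    def test_trajectories_finite_and_physiological(self, short_paced):
        d = short_paced.data
        assert np.isfinite(d.to_numpy()).all()
        assert d["SL_um"].min() > 1.4
        assert d["Cai_mM"].min() > 0.0
        assert d["tension_kPa"].max() > 0.0

    def test_paced_beats_follow_stimulus_period(self, short_paced):
        v = short_paced["Vm_mV"]
        t = short_paced["time_ms"]
        thr = v.min() + 0.5 * (v.max() - v.min())
        ups = np.where((v[:-1] < thr) & (v[1:] >= thr))[0]
        cls = np.diff(t[ups])
        assert np.allclose(cls, 1000.0, atol=20.0)

    def test_troponin_mass_balance_matches_jcb_integral(self):
        """Coupling symmetry: the time integral of jcb equals the change in
        overlap-weighted troponin-bound Ca2+ (mass balance to solver
        tolerance), checked on an isometric Ca2+-step transient."""
        from scipy.integrate import solve_ivp

        from sarcomech.contractile import (LEN_HBARE, LEN_THICK, LEN_THIN,
                                           initial_ce_state)
        p = CEParameters()
        pv = build_pv(p, MetaboliteState())
        y0 = initial_ce_state(p)
        y0[7] = 2.1
        cai = 4e-4  # mM step

        def buffer_content(y):
            sl = y[7]
            sovr_ze = min(LEN_THICK / 2, sl / 2)
            sovr_cle = max(sl / 2 - (sl - LEN_THIN), LEN_HBARE / 2)
            sovf_thin = (sovr_ze - sovr_cle) / LEN_THIN
            return p.trpn_conc * ((1 - sovf_thin) * y[0] + sovf_thin * y[1])

        sol = solve_ivp(lambda t, y: _ce_rhs(y, cai, pv, True)[0], (0.0, 2.0),
                        y0, method="LSODA", rtol=1e-10, atol=1e-13,
                        t_eval=np.linspace(0.0, 2.0, 4001))
        jcb = np.array([_ce_rhs(sol.y[:, i], cai, pv, True)[3]
                        for i in range(sol.y.shape[1])])
        integral = np.trapezoid(jcb, sol.t)
        delta_b = buffer_content(sol.y[:, -1]) - buffer_content(y0)
        # agreement limited by trapezoidal quadrature of the fast onset
        assert integral == pytest.approx(delta_b, rel=1e-3, abs=1e-9)

    def test_jcb_near_zero_over_a_periodic_beat(self, short_paced):
        """At quasi-steady pacing the per-beat integral of the troponin flux
        vanishes (the buffer returns to its diastolic load)."""
        d = short_paced.data
        t = d["time_ms"].to_numpy()
        jcb = d["jcb"].to_numpy()
        one_beat = t >= t[-1] - 1000.0
        beat_int = np.trapezoid(jcb[one_beat], t[one_beat] * 1e-3)
        assert abs(beat_int) < 0.05 * np.abs(jcb).max()

    def test_solver_failure_reports_context(self):
        bad = np.full(27, np.nan)
        with pytest.raises((RuntimeError, ValueError)):
            run_simulation(ModeOverlay(), "paced",
                           SolverSettings(beats=2, qss=False), y0=bad)

    def test_state_length_validated(self):
        with pytest.raises(ValueError, match="27"):
            run_simulation(ModeOverlay(), "paced", y0=np.zeros(5))


class TestSnapshots:
    def test_snapshots_shipped_for_all_modes(self):
        from sarcomech.modes import MODES
        for mode in MODES:
            for proto in ("paced", "spontaneous"):
                y = load_mode_snapshot(mode, proto)
                assert y is not None and len(y) == 27

    def test_snapshot_is_near_limit_cycle(self):
        """Restarting from the shipped snapshot changes the Ca2+-transient
        peak by well under 1% per beat."""
        ts = run_simulation(ModeOverlay(), "paced",
                            SolverSettings(beats=4, qss=False), keep_s=4.0)
        d = ts.data
        t = d["time_ms"].to_numpy()
        ca = d["Cai_mM"].to_numpy()
        peaks = [ca[(t >= k * 1000) & (t < (k + 1) * 1000)].max()
                 for k in range(3)]
        rel = np.abs(np.diff(peaks)) / peaks[0]
        assert rel.max() < 0.01


class TestPrescribedCa:
    def test_constant_file_gives_constant_clamp(self, tmp_path):
        path = tmp_path / "const.txt"
        np.savetxt(path, np.column_stack([np.arange(0, 1000.0, 10.0),
                                          np.full(100, 2e-4)]))
        cai = prescribed_ca_driver(path)
        assert cai(0.123) == pytest.approx(2e-4)
        assert cai(57.0) == pytest.approx(2e-4)

    def test_sine_recovered_within_interpolation_error(self):
        t = np.arange(0.0, 1000.0, 1.0)
        y = 2e-4 + 1e-4 * np.sin(2 * np.pi * t / 1000.0)
        cai = prescribed_ca_driver(np.column_stack([t, y]))
        probe = np.array([0.1234, 0.2517, 0.5001, 0.87654])  # s, off-grid
        exact = 2e-4 + 1e-4 * np.sin(2 * np.pi * probe)
        got = np.array([cai(x) for x in probe])
        # linear interpolation error bound: |f''| h^2 / 8
        h = 1e-3  # s
        bound = 1e-4 * (2 * np.pi) ** 2 * h**2 / 8
        assert np.all(np.abs(got - exact) <= bound + 1e-12)

    def test_periodic_extension(self):
        # table spans exactly one period, 0..1000 ms inclusive
        t = np.arange(0.0, 1000.0 + 0.5, 1.0)
        y = 1e-4 + 1e-4 * np.sin(2 * np.pi * t / 1000.0) ** 2
        cai = prescribed_ca_driver(np.column_stack([t, y]))
        assert cai(2.5) == pytest.approx(cai(0.5), rel=1e-9)

    def test_non_monotone_time_rejected(self):
        arr = np.array([[0.0, 1e-4], [10.0, 2e-4], [5.0, 1e-4]])
        with pytest.raises(ValueError, match="increasing"):
            prescribed_ca_driver(arr)

    def test_ce_twitch_from_waveform_file(self, tmp_path):
        path = synthetic_ca_waveform_file(tmp_path / "cat.txt")
        cai = prescribed_ca_driver(path)
        ts = run_ce_prescribed(cai, duration_s=3.0)
        ten = ts["tension_kPa"]
        assert ten.max() > 1e-4
        assert ts["SL_um"].min() < 1.9  # cell shortens


class TestTimeSeriesIO:
    def test_write_read_round_trip(self, short_paced, tmp_path):
        path = tmp_path / "trace.tsv"
        short_paced.write(path)
        back = TimeSeries.read(path)
        assert back.manifest["mode"] == "control"
        np.testing.assert_allclose(back["Vm_mV"], short_paced["Vm_mV"],
                                   rtol=1e-9)
        assert back.columns == short_paced.columns
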