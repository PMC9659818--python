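"""Spontaneous beating of the control hiPSC-CM and its biomarkers.

Runs the coupled electromechanical model without any stimulus (hiPSC-CMs are
automatic), extracts the standard action-potential, Ca2+-transient and
contraction biomarkers of the final beats, and prints them.  APD90 ~ 400 ms,
cycle length ~ 1.6-1.9 s, MDP ~ -75 mV and ~3% fractional shortening are the
hallmarks of these immature cardiomyocytes.
"""

from sarcomech.biomarkers import biomarker_report
from sarcomech.coupled import SolverSettings, run_simulation
from sarcomech.modes import load_overlay

ts = run_simulation(load_overlay("control"), "spontaneous",
                    SolverSettings(beats=40, qss=True), keep_s=8.0)
report = biomarker_report(ts)

print(f"windows simulated : {ts.manifest['windows_run']}")
for key in ("APA_mV", "MDP_mV", "CL_ms", "dVdt_max_V_per_s", "APD10_ms",
            "APD30_ms", "APD90_ms", "CaT_duration_ms", "CaT_tDecay90_10_ms",
            "AT_magnitude_kPa", "RT50_ms", "FS_pct"):
    print(f"{key:22s} {report[key]:10.3f}")
print("\nAPA/MDP describe the action potential; CaT times the Ca2+ transient;")
print("AT is peak active tension, RT50 its relaxation half-time, FS the")
print("percent sarcomere shortening per beat.")
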