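"""Regenerate per-mode steady-state snapshots for the coupled model.

Runs every registered mode to steady state (long pre-run: 800 paced beats at
1 Hz, and 600 s spontaneous) and stores the final state vectors in
``src/sarcomech/mode_snapshots.json``.  Run from the repository root:

    python scripts/make_snapshots.py [--beats 800] [--spont-s 600]
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

import numpy as np

from sarcomech.contractile import CEParameters, MetaboliteState
from sarcomech.coupled import SolverSettings, initial_state, run_simulation
from sarcomech.modes import MODES


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--beats", type=int, default=800)
    ap.add_argument("--spont-s", type=float, default=600.0)
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    out_path = (Path(args.out) if args.out else
                Path(__file__).resolve().parents[1]
                / "src" / "sarcomech" / "mode_snapshots.json")
    snaps: dict[str, list[float]] = {}
    if out_path.exists():
        snaps = json.loads(out_path.read_text())

    p = CEParameters()
    for mode_id, ov in MODES.items():
        for protocol, beats in (("paced", args.beats),
                                ("spontaneous", int(args.spont_s / 2))):
            t0 = time.time()
            ts = run_simulation(
                ov, protocol,
                SolverSettings(beats=beats, qss=False),
                p=p, y0=initial_state(p), keep_s=4.0,
            )
            y = ts.final_state
            snaps[f"{mode_id}:{protocol}"] = [float(v) for v in y]
            out_path.write_text(json.dumps(snaps, indent=1))
            print(f"{mode_id}:{protocol}: {beats} windows in "
                  f"{time.time() - t0:.0f}s -> {out_path.name}", flush=True)


if __name__ == "__main__":
    main()
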