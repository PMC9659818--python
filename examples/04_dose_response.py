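"""Dose-dependent depression of maximal isometric tension by BLEB and OM.

The dominant tension-governing variable of the crossbridge cycle is the
forward isomerisation rate (ap2); each drug concentration maps to an ap2
coefficient (an editable table - the shipped values are illustrative
interpolations anchored at the calibrated single doses).  The scan computes a
tension-pCa curve per dose and prints the T0-normalised maxima, which fall
monotonically with dose in an inverse-Hill pattern.
"""

import numpy as np

from sarcomech.pca import DOSE_AP2_TABLES, dose_response_scan

grid = np.round(np.arange(7.0, 4.19, -0.2), 2)
for drug in ("BLEB", "OM"):
    print(f"\n{drug} (ap2 coefficient table: {DOSE_AP2_TABLES[drug]})")
    curves = dose_response_scan(drug, pca_grid=grid)
    for dose, curve in curves.items():
        print(f"  {dose:5.1f} uM -> T/T0 = {curve.normalized.max():.3f}")
print("\nT/T0 is the maximal steady isometric tension normalised to the")
print("drug-free maximum; 1.0 means no inotropic depression.")
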