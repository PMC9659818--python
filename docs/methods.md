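# Methods

## Model structure

The cell model couples two subsystems through exactly two signals.

**Contractile element (CE).** Thin-filament activation: Ca²⁺ binds troponin's
low- and high-affinity regulatory sites (`K_on = 62.5×10³ mM⁻¹s⁻¹`,
`K_offL = 200 s⁻¹`, `K_offH = 25 s⁻¹`, both off-rates scaled by
`K_offmod = 0.5`); the overlap-weighted bound fraction (Tropreg) feeds a
cooperative permissive gate, `permtot = √(1/(1+(perm50/Tropreg)^n_perm))`
with `perm50 = 0.6`, `n_perm = 11.55`, which gates the non-permissive ↔
permissive exchange (`K_np = 550 s⁻¹`, `K_pn = 50 s⁻¹`, backward rate uses
`min(1/permtot, 100)`). Crossbridge cycling is the four-state scheme
(N_XB, P_XB, XB_preR, XB_pstR) with base rates `fap = 500`, `gap = 70`,
`h_f = 2000`, `hb = 400`, `gxb = 70 s⁻¹`, all scaled by the species factor
`xbmodsp = 0.2` and Q₁₀-style temperature factors (all equal 1 at 37 °C, the
default). Strain dependence: the forward isomerisation carries
`hfmd = exp(−sign(x_preR)·5·(x_preR/x₀)²)` and the detachment carries the
`max(gxbmd, 1)` modifier (σ⁺ = 8, σ⁻ = 1); mean strains obey first-order
relaxation laws weighted by the duty fractions of the clamped cycle
(King–Altman/spanning-tree solution) with the empirical scaler φ = 2 and
`x₀ = 7 nm`.

**Metabolite sensitivity.** Three transitions respond to the metabolic state,
each through a factor normalised to 1 at reference concentrations
(MgATP 5 mM, MgADP 36 µM, Pi = Pi_ref, pH 7.15):

* `am1 ∝ ([Pi]/Pi_ref)^pi_exp` (phosphate rebinding reverses attachment;
  `pi_exp = 1` by default),
* `am2 ∝ ([H⁺]/H_ref) · ((kdADP+MgADP_ref)/MgADP_ref) · ([MgADP]/(kdADP+[MgADP]))`
  (reverse power stroke from the ADP-bound post-stroke substate),
* `ap3 ∝ ([MgATP]/MgATP_ref) · (kdADP+MgADP_ref)/(kdADP+[MgADP])`
  (MgATP-induced detachment, competitively inhibited by MgADP).

`kdADP = 4 µM` is the ADP dissociation constant of the post-stroke
rapid-equilibrium substates (adopted from the metabolite-sensitive
crossbridge literature; it is not separately identifiable from the data this
package targets). A proton-competition factor
`(KdH + H_ref)/(KdH + [H⁺])` with `KdH = 2×10⁻⁴ mM` scales Ca²⁺ binding to
troponin C. The reverse of the detachment step (`am3`) is fixed by detailed
balance against the MgATP hydrolysis free energy (ΔG⁰′ = −30 kJ/mol plus the
concentration term); it is ~10⁻⁸ s⁻¹ under physiological conditions and
matters only for thermodynamic closure. The ATPase rate is the detachment
flux `ap3·XB_pstR`; a net-flux variant (`ap3·XB_pstR − am3·P_XB`) is
available via `CEParameters.atpase_net`.

**Force and length.** Active tension is
`kxb · SOVFThick(SL) · (x_pstR·XB_pstR + x_preR·XB_preR) / (x₀ · SS_max)`
with `kxb = 13.1` and `SS_max` the frozen zero-strain post-stroke duty
fraction of the control cycle (0.710), so tension is exactly linear in `kxb`
and overlays act only through the dynamics. Unloaded shortening follows
`m·d²SL/dt² = −F_active − F_passive + F_preload − visc·dSL/dt` with
`m = 2×10⁻⁵ s² µm⁻¹`, a titin-like parallel elastic element
`PCon_t·(e^{PExp_t|SL−1.85|}−1)` (sign-odd) plus a collagen-like element
beyond 2.25 µm, and a constant preload equal to the passive force at the
resting length `SL₀ = 1.9 µm`. `PCon_t = 0.008` and `visc = 0.01`
(normalised-force units) are the two free constants of the passive element;
they were calibrated once so that the control spontaneous fractional
shortening at the 800-beat steady state is ≈3.3%, and then frozen.

**Host electrophysiology.** A ventricular-like hiPSC-CM action-potential
model of the Paci family (INa, ICaL with Ca²⁺-dependent inactivation, IKr,
IKs, IK1, Ito, If, INaCa, INaK, IpCa, background currents; SERCA uptake, SR
leak and Ca²⁺-induced Ca²⁺ release; intracellular Na⁺ bookkeeping; fixed
K⁺). It beats spontaneously with cycle length ≈1.8 s, MDP ≈ −75 mV,
APD90 ≈ 380 ms. Because the original source could not be consulted while
this package was written, the formulation was reimplemented from its
published description; absolute biomarkers agree with the published lineage
to within ≈10% but not bit-for-bit. Coupling: cytosolic Ca²⁺ drives troponin
binding; the net troponin flux
`jcb = Trpn_tot · d/dt[(1−SOVFThin)·TropCaL + SOVFThin·TropCaH]`
(including the overlap term) is debited from the Ca²⁺ mass balance, so Ca²⁺
removed from the cytosol equals Ca²⁺ gained by troponin exactly.

## Modes

Overlays multiply the control parameter set (a dash in the published
modification tables means "leave at baseline"):

* `hcm_r403q` — Pi_ref 2→18.9 mM, MgADP 36→72 µM, ap2 coefficient 0.315,
  F1 = F2 = 1.3.
* `mava_0p5uM` — defined on the HCM variant (ap2 coefficient retained):
  A–E = (0.26, 0.4, 5.4, 0.4, 2.39), ap1/ap3 coefficients 1.45/0.28,
  F1 = F2 = 0.1, K_on ×1.048, n_perm ×0.688, metabolites restored to
  baseline.
* `bleb_5uM` — F1 = 5.015, F2 = 0.1, Tropreg coefficient 0.2, ap2/ap3/am2
  coefficients 0.012/0.03/0.25, perm50 ×1.33.
* `om_1uM` — F1 = 4.1, F2 = 0.1, Tropreg coefficient 0.2, ap2/ap3/am2
  coefficients 0.02/0.03/0.15, K_on ×1.28, n_perm ×1.182, perm50 ×1.33,
  K_pn ×0.2, K_np ×1.182, K_offmod ×0.52, K_offL ×1.75, K_offH ×0.6,
  h_f ×2.

## Design choices where the design was open

* **F1/F2 placement.** F1/F2 modulate the P_XB ↔ XB_preR transition in both
  state balances. Restricting them to the XB_preR balance alone makes the
  scheme non-conserving (occupancy is created at rate (F1−1)·ap1·P_XB) and
  diverges for the drug overlays, so the conserving form is used. The duty
  fractions (Eqs for the clamped cycle) use the bare rates.
* **Tropreg coefficient.** Implemented as a scaling of the permissive
  function itself (`knpT ∝ coef·permtot`, `kpnT ∝ min(1/(coef·permtot),100)`).
  Scaling the raw occupancy instead would put the gate threshold above the
  occupancy ceiling for the OM/BLEB overlays (perm50×1.33 = 0.8 against a
  ceiling of 0.2) and abolish activation, which contradicts the finite
  drug-mode tensions this calibration is built to produce.
* **Pi semantics of the HCM overlay.** The HCM entry raises the *reference*
  phosphate in the normalised detachment factor while the simulated Pi pool
  stays at its control value — the only reading consistent with the HCM
  phenotype (hypercontractility with prolonged relaxation); setting the pool
  itself to 18.9 mM accelerates detachment ~9× and collapses force.
* **RT50.** "Time from peak contraction to 50% of relaxation" is measured on
  the contraction signal (shortening, SL_rest − SL): peak shortening to 50%
  recovery. The tension-based variant is reported as `RT50_tension_ms` and
  used for isometric traces. The shortening reading reproduces both the
  control value (≈145 vs 158 ms) and the Mavacamten effect (−20.2% vs
  −20.9%), where the tension reading gives ≈95 ms and −36%.
* **APD baseline.** Repolarisation percentages are measured per beat between
  that beat's peak and its own maximum diastolic potential; beats segment at
  the mid-range upstroke crossing. The AP triangulation index is reported as
  (APD90−APD30)/APD30; its published definition was not available, so it is
  excluded from quantitative comparisons.
* **Isometric protocol.** Tension–pCa curves use SL = 2.2 µm (standard
  skinned-preparation length), a descending-pCa staircase with warm starts
  (continuation), and a steady-tension criterion of <10⁻⁶ relative change
  per second. Hill fits are unweighted least squares with positivity bounds.
* **Quasi-steady state.** Paced runs stop when APD90, the CaT peak and the
  tension peak each change <0.1% beat-to-beat (capped by `beats`). Shipped
  snapshots come from 800 paced beats / 600 s spontaneous per mode
  (`scripts/make_snapshots.py` regenerates them); acceptance runs restart
  from these and typically add only a handful of beats.

## Numerical notes

* LSODA (stiff-capable) with max step 1 ms, initial step 20 µs,
  rtol 10⁻⁷ / atol 10⁻⁹ for coupled runs; tighter (10⁻⁹/10⁻¹²) for clamped-Ca
  steady states. Trajectories are resampled at 1 ms for analysis; biomarker
  extraction is stable to finer resampling (<0.5% change).
* The strain-modifier exponents (`hfmd`, `gxbmd`) are clipped at e±³⁰:
  physically |x_preR| stays within a few x₀, and the clip prevents overflow
  when a transient visits an extreme strain.
* Degenerate inputs: all-zero rate sets (zero duty-fraction normaliser),
  negative concentrations, non-monotone waveform time columns, flat traces
  (no beat) and collapsing sarcomere length raise informative errors rather
  than propagating NaNs.
* The right-hand sides are compiled with numba; the first call in a fresh
  environment costs ~½–1 min of JIT compilation, after which a paced beat
  integrates in ~0.1 s.

## What the simulations do and do not show

The coupled simulations reproduce the qualitative pharmacology throughout —
every reported sign (HCM hypercontractility and slowed relaxation with
near-unchanged CaT; Mavacamten lowering ATPase, shortening and relaxation
time; OM shortening APD90 and accumulating Na⁺) — and most quantitative
effects: the Mavacamten fractional-shortening and RT50 reductions and the
OM/BLEB maximal-tension and OM Ca²⁺-sensitivity/cooperativity changes land
within ~15% of their published values. Quantitative gaps that remain are
documented honestly rather than tuned away: the HCM-vs-control RT50/%FS
increases and the HCM ATPase overshoot (the unprintable inherited phosphate
law dominates these; any stronger-than-linear softening inverts the
Mavacamten signs), the BLEB Hill-coefficient reduction (−32% vs −50%), the
absolute twitch-tension scale (≈0.13 vs 0.055 kPa, traceable to the
reimplemented host model's CaT amplitude and the inherited force
normalisation), and the OM Ca²⁺-transient-peak and I_NCX-amplitude increases
(sub-percent in this implementation). The synthetic waveform generators used
in tests (trapezoidal APs, linear-rise/exponential-decay transients) validate
the *analysis* code against closed forms; they do not stand in for simulated
physiology.
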