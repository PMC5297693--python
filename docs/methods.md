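# Methods

## Model structure and assumptions

The network has four conserved species (active + inactive = total): the ER
stress sensors PERK and IRE-1 and the lumped autophagy and apoptosis
inducers.  Assumptions baked into the equations:

- **Conservation, no synthesis/degradation.**  Activation draws on the
  inactive pool, so every variable is confined to `[0, total]` and the box is
  forward-invariant (activation vanishes at the top face, inactivation at the
  bottom face).  There are no basal activation terms: the fully inactive
  state is an exact equilibrium at zero stress.
- **Sensor layer: mass action.**  Stress and the partner sensor activate the
  inactive pool bilinearly; inactivation is first order.  For any stress > 0
  the sensor pair has a unique equilibrium (the composed nullcline map is
  concave and increasing).  At stress 0 the origin coexists with a
  self-sustained state whenever the positive-feedback loop gain
  `(k_ip·IRE1_T/k_di)·(k_pi·PERK_T/k_dp)` exceeds 1.  With the default totals
  this gain is 25/9 ≈ 2.8, so the intact sensor loop stays on after stress
  removal; either knockdown (×0.2 or ×0.1) pulls the gain below 1.  This is
  the mechanistic seat of irreversibility: the "point of no return" is the
  sensor loop keeping the toggle's death side energised at zero stress.
  A corollary is that at exactly zero stress the resting origin is an
  unstable equilibrium of the default model, coexisting with the survival
  and death attractors.
- **Inducer layer: saturating (Goldbeter–Koshland-type) fluxes.**  Each
  inducer is activated by a weighted sensor sum and inactivated at a rate
  raised by the *other* inducer — the double-negative toggle.  The apoptosis
  leg operates in the zero-order regime (`J_ap_* ≈ 0.01–0.02 ≪ 1`), which
  supplies the ultrasensitivity that makes the loop bistable.  The autophagy
  *activation* flux is deliberately Michaelian (`J_a_on ≈ 1`): a graded
  autophagy level transmits the strength of the IRE-1 arm into the apoptosis
  threshold.  With both legs zero-order the autophagy high state pins at its
  total regardless of drive, the default and IRE-1-knockdown networks then
  share the same apoptosis activation threshold, and the observed *leftward*
  threshold shift under IRE-1 loss is structurally unattainable (the
  knockdown curve degenerates into a graded monostable response or an
  unreachable isola).  This is the one place the package's functional form
  departs from a pure zero-order toggle, and it is load-bearing.

Out of scope by design: the translational (eiF2α) machinery, CHOP/Gadd34
feedback, spatial effects and molecular stochasticity.

## Parameters

Defaults (a.u., dimensionless time) were calibrated, not fitted: no
quantitative time-course data exist for this readout, so the reference set is
required to satisfy eight qualitative constraints distilled from the
experimental phenotypes:

1. a bistable window (two attractors separated by a saddle);
2. irreversibility of the intact switch (death branch persists to stress 0);
3. activation threshold between the survivable and lethal scenario levels,
   25 < SN_on < 40;
4. a transient apoptosis excursion at stress 25 that crosses 5 % of total and
   recedes below it;
5. siPERK (PERK_T × 0.2): SN_on > 40 and SN_off > 0;
6. IRE-1 inhibition (IRE1_T × 0.1): SN_on below the default and SN_off > 0;
7. mutual exclusion — no scanned stable state has both inducers above half
   total;
8. at stress 40 the autophagy peak precedes the apoptosis half-activation.

Calibration proceeded by staged random search (log-uniform draws screened
first on cheap branch-existence tests, then on dynamics) followed by 1-D
refinement of the PERK/IRE-1 apoptosis drives and fold-preserving rescaling
of the three layers' timescales (sensors fastest, autophagy intermediate,
apoptosis slowest; rescaling a whole right-hand side moves no equilibria, so
the fold structure survives while the race from the resting state is won by
autophagy).  The shipped set yields SN_on = 37.1, siPERK SN_off = 57.9,
IRE-1-low window [12.2, 31.2], commitment at t ≈ 3 under stress 40.

Parameters that matter most: `k_pap`/`k_iap` (apoptosis drive; sets SN_on),
`k_x_apa` (toggle leg; sets the window width), `k_ip·k_pi` vs `k_dp·k_di`
(sensor loop gain; sets irreversibility and its loss under knockdown), and
`J_a_on` (autophagy gradedness; sets the knockdown shift direction).  The
±10 % robustness table (`calibration.robustness_table`) shows the
fold-placement constraints (3, 5, 6) are the fragile ones — single-parameter
changes to the apoptosis drive can move SN_on outside the (25, 40) bracket —
while bistability, irreversibility and exclusion are robust.  The table is
emitted, failures included: the model claims qualitative behaviour, and the
brackets 25/40 are themselves arbitrary printed scenario levels.

## Numerical choices

- **Steady states** exploit model structure: the sensor pair reduces to a
  1-D concave fixed point (bisection); given sensor levels each inducer
  nullcline is exactly quadratic in its own variable, so all toggle
  equilibria are found by following the quadratic branches and bracketing
  sign changes (no stochastic multi-starts).  Dedup tolerance 1e-6 (max
  norm); stable iff max Re eigenvalue < −1e-9.
- **Folds** are located by bisection on stable-branch existence to stress
  resolution 0.01 — robust, needs no second derivatives.  Branch columns are
  assembled into curves by nearest-neighbour continuation, ties resolved by
  the smallest state-space jump.
- **Integration**: LSODA, rtol 1e-8 / atol 1e-10, with restarts at stress
  discontinuities (no interpolation across a step).  A trajectory is
  "settled" when `|rhs| < 1e-6` at the horizon.  Default horizon 60 time
  units (all scenarios settle well inside it), sampling step 0.25.
- **Hysteresis ramps** use rate 0.002 stress per time unit; slower rates
  change the jump location by < 0.05.  The residual up-jump lag (~0.1) is
  the delayed-bifurcation transit, well inside the 2-grid-step comparison
  band.
- **Commitment time** = first time apoptosis exceeds 90 % of the death-branch
  value (branch-referenced, hence unambiguous); wash-out switches stress to 0
  five time units after commitment.
- **Degenerate inputs**: an empty equilibrium list raises (a continuous flow
  on a compact forward-invariant box must have an equilibrium); series
  shorter than the sustain run length are rejected as undetermined; fold
  statuses distinguish "found" from "above scan" / "below scan".

## Phenotype calling

Features: time-above-threshold window, first *sustained* crossing (K = 3
consecutive samples ≥ half the scale — rejects single-sample noise spikes at
the default sampling density), and a transient flag (crossed 5 % of scale,
receded below it).  On model trajectories the scale is the conserved total
and the call is: death iff sustained apoptosis onset, delayed death iff the
onset lags the reference by more than one sampling step, survival otherwise.
Calls are unchanged for sustained thresholds anywhere in [0.4, 0.6] of total.

On synthetic densitometry panels every marker is normalised to its own series
maximum, which destroys absolute scale: a 4 %-of-total apoptosis plateau
normalises to a high plateau.  Marker-mode calls therefore use the
survival/death *contrast*: sustained autophagy markers at the end of the
horizon signal survival; otherwise the apoptosis-marker onset classifies
death versus delayed death.  Markers map to variables as LC3-II and
ULK-555-P → autophagy; cleaved PARP, CHOP, JNK-P → apoptosis; eiF2α-P → PERK;
spliced XBP1 → IRE-1 (CHOP is treated purely as an apoptosis proxy; its
possible dual role is not modelled).

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical shape* of blot densitometry:
fixed-interval sampling (default every 0.5 time units, labelled as 15-minute
analogues at the cosmetic 30 min-per-time-unit mapping, which places the
high-stress death switch near the 90–120 min region of the panels),
per-series max normalisation, multiplicative lognormal noise with chosen CV
(unit mean; replicates get independent spawned sub-seeds, so the output is
deterministic in the seed), and the three-replicate design.  It does **not**
emulate transfection-efficiency variation, cell-population heterogeneity,
loading-control error structure, blot saturation, or background subtraction.
Passing recovery tests therefore show the *pipeline* tolerates
signal-proportional noise at blot-like magnitudes (recovery 1.0 at cv = 0.1,
degrading smoothly by cv = 0.4); they do not certify performance on real
densitometry, where errors are neither independent nor purely multiplicative.

## Known limitations

- The fold positions are calibrated to dimensionless scenario levels (25/40);
  rescaling stress units rescales all thresholds.
- Near-threshold stress (just above SN_on) produces arbitrarily slow
  commitment (critical slowing); the settled flag guards analyses against
  unconverged horizons.
- The ±10 % robustness table shows threshold placement is parameter-
  sensitive; conclusions should rest on the ordering/shift *directions*, not
  on fold coordinates.
- The .ode parser reads the exporter's own dialect, not arbitrary XPP files.
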