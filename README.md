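# uprfate

A small dynamical-systems package for the **life-and-death decision under
endoplasmic-reticulum (ER) stress**.  It implements a four-variable ODE model
of the unfolded protein response (UPR) in which the stress sensors **PERK**
and **IRE-1** activate each other (a positive feedback loop) and drive two
lumped effectors — an **autophagy (survival) inducer** and an **apoptosis
(death) inducer** — that inhibit one another (a double-negative feedback
loop, i.e. a toggle switch).  The package is for systems biologists who want
to interrogate how this wiring turns a graded stress signal into an
all-or-none, and in the intact network irreversible, cell-fate commitment.

## Model

With state `(P, I, A, Y)` = active PERK, active IRE-1, active autophagy and
apoptosis inducers, each conserved with total `X_T`:

```
dP/dt = (k_sp·S + k_ip·I)(PERK_T − P) − k_dp·P
dI/dt = (k_si·S + k_pi·P)(IRE1_T − I) − k_di·I
dA/dt = (k_pa·P + k_ia·I)·(A_T − A)/(J_a_on + A_T − A) − (k_da + k_x_aa·Y)·A/(J_a_off + A)
dY/dt = (k_pap·P + k_iap·I)·(Y_T − Y)/(J_ap_on + Y_T − Y) − (k_dap + k_x_apa·A)·Y/(J_ap_off + Y)
```

where `S` is the dimensionless ER-stress signal.  The IRE-1 arm couples
strongly to autophagy (`k_ia ≫ k_pa`) and the PERK arm strongly to apoptosis
(`k_pap ≫ k_iap`).  The Goldbeter–Koshland-type saturating fluxes of the
apoptosis leg make the toggle ultrasensitive; the mutual inhibition makes the
steady-state response of `Y` versus `S` an S-shaped curve with two saddle-node
(fold) points: the activation threshold `SN_on` and the deactivation
threshold `SN_off`.  The shipped calibrated parameters place `SN_on` between
the survivable (`S = 25`) and lethal (`S = 40`) scenario levels and push
`SN_off` below zero stress, making commitment to apoptosis a point of no
return; knocking down either sensor (PERK_T × 0.2 or IRE1_T × 0.1) breaks the
sensor positive feedback and makes the switch reversible.

## Worked example

```
$ python examples/03_knockdowns.py
default:        SN_on = 37.08, irreversible
siPERK (PERKT=0.2): SN_on = beyond scan (> 60) (shift +inf), SN_off = 57.87, reversible
IRE-1 low (IRE1T=0.1): SN_on = 31.16 (shift -5.92), SN_off = 12.23, reversible
siPERK_high_stress: phenotype=survival, onset=none (reference 2.50)
IRE1low_high_stress: phenotype=death, onset=2.00 (reference 2.50)
```

Reading: the intact network switches on apoptosis at stress 37.1 and can
never switch it off again (irreversible).  Silencing PERK moves the
activation threshold beyond the scanned range — at lethal stress 40 the cell
keeps surviving by autophagy.  Inhibiting IRE-1 moves the threshold left
(shift −5.9) and death arrives *earlier* (onset 2.0 vs 2.5 time units).
Both knockdowns give the switch a positive deactivation threshold, i.e. the
suicide decision becomes reversible.

Other examples: `01_signal_response.py` (branch scan and folds),
`02_stress_scenarios.py` (survival / death / wash-out time courses),
`04_synthetic_blots.py` (noisy densitometry-style marker panels and
phenotype recovery), `05_calibration_and_robustness.py` (constraint suite,
parameter search, ±10 % robustness).

A thin CLI mirrors the library: `uprfate simulate|bifurcate|calibrate|synth|
phenotype|export-ode|pipeline` (see `uprfate --help`).  Parameter sets can be
round-tripped to XPP `.ode` files with `export-ode` / `uprfate.parse_ode`.

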