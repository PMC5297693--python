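"""In-silico sensor knockdowns: threshold shifts and loss of irreversibility.

Reducing total PERK to 20% (siPERK) removes the strong drive onto the
apoptosis inducer: the activation threshold moves right, past the lethal
stress level, and death is delayed or absent.  Reducing IRE-1 to 10% starves
the autophagy inducer: the threshold moves left and death comes early.
Either knockdown breaks the PERK<->IRE-1 positive feedback, so the switch
also becomes reversible (SN_off moves to positive stress).
"""
import uprfate as uf

curve = uf.signal_response(uf.DEFAULT_PARAMS, n_points=241)
print(f"default:        SN_on = {curve.sn_on:.2f}, {uf.classify_reversibility(curve)}")

for label, preset_name in (("siPERK (PERKT=0.2)", "siPERK"),
                           ("IRE-1 low (IRE1T=0.1)", "IRE1-inhibited")):
    kd = uf.signal_response(uf.preset(preset_name), n_points=241)
    shift = uf.threshold_shift(curve, kd)
    on = "beyond scan (> 60)" if kd.sn_on_status == "above_scan" else f"{kd.sn_on:.2f}"
    print(f"{label}: SN_on = {on} (shift {shift:+.2f}), "
          f"SN_off = {kd.sn_off:.2f}, {uf.classify_reversibility(kd)}")

ref = uf.phenotype_of_trajectory(uf.run_scenario("high_stress")).apop_onset
for scen in ("siPERK_high_stress", "IRE1low_high_stress"):
    call = uf.phenotype_of_trajectory(uf.run_scenario(scen), reference_onset=ref)
    onset = f"{call.apop_onset:.2f}" if call.apop_onset else "none"
    print(f"{scen}: phenotype={call.phenotype}, onset={onset} (reference {ref:.2f})")
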