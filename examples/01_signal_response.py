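"""Signal-response curve of the death switch and its fold points.

Scans the steady states of the apoptosis inducer against ER stress, prints
the saddle-node thresholds and the reversibility class.  The activation
threshold (SN_on) is where the survival branch disappears — below it cells
can persist in the autophagy-high state; the deactivation threshold (SN_off)
is where the death branch disappears on the way down.  An SN_off at or below
zero stress means commitment to death cannot be undone by removing the
stressor.
"""
import uprfate as uf

curve = uf.signal_response(uf.DEFAULT_PARAMS, stress_range=(0.0, 60.0), n_points=241)
s = curve.summary()
print(f"coexisting stable states (max over scan): {s['max_coexisting_stable_states']}")
print(f"activation threshold SN_on  = {s['sn_on']:.2f}  (survivable 25 < SN_on < lethal 40)")
print(f"deactivation threshold SN_off: {s['sn_off_status']}"
      + (f" ({s['sn_off']:.2f})" if s['sn_off'] is not None else ""))
print(f"switch class: {s['reversibility']}")

df = curve.to_frame()
df.to_csv("signal_response.csv", index=False)
print(f"\nwrote signal_response.csv ({len(df)} branch points); "
      "stable rows are the solid branches, unstable rows the separating saddle")
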