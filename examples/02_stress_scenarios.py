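"""Time courses under survivable and lethal ER stress, and stressor wash-out.

Reproduces the three canonical simulations: at stress 25 autophagy switches
on and a small apoptosis excursion is quickly downregulated (survival); at
stress 40 the autophagy window is transient and the apoptosis inducer
switches on and stays on (death); washing the stressor out after commitment
does not rescue the cell — the point of no return.
"""
import numpy as np

import uprfate as uf

for name in ("low_stress", "high_stress", "washout"):
    traj = uf.run_scenario(name)
    call = uf.phenotype_of_trajectory(traj)
    auto, apop = traj.series("auto"), traj.series("apop")
    print(f"{name:12s} phenotype={call.phenotype:9s} "
          f"autophagy: peak {auto.max():.2f} @ t={traj.time[np.argmax(auto)]:.2f}, "
          f"final {auto[-1]:.2f} | apoptosis: peak {apop.max():.2f}, final {apop[-1]:.2f}"
          + (f", onset t={call.apop_onset:.2f}" if call.apop_onset else ""))

t_commit = uf.commitment_time()
print(f"\ncommitment time at stress 40 (apoptosis > 90% of death branch): t = {t_commit:.2f}")
print("after wash-out the apoptosis inducer stays high: the intact network is irreversible")
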