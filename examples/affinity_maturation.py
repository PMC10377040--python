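"""Affinity maturation: hypermutation rescues a weak response to a
foreign antigen.

Only the weakest-binding class is seeded.  Under strong stimulation
(k4 = 1.1) but without mutation it simply decays; with p = 0.5 its mutant
offspring climb the affinity ladder and expand.
"""

import numpy as np

from abdyn import preset, run

out = run(preset("shm_foreign"))
for label, (traj, summ) in out.items():
    comp = summ.composition[-1]
    strong = np.nansum(comp[5:])
    print(f"{label}: total antibody {summ.total_antibody[0]:.3g} -> "
          f"{summ.total_antibody[-1]:.4g}; classes 6-9 hold "
          f"{100 * strong:.1f}% at the horizon "
          f"(dominant class {summ.dominant_class[-1]})")
print("\nWithout mutation the weak clone is eliminated; with it, "
      "high-affinity classes emerge and proliferate - maturation out of a "
      "poor starting repertoire.")
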