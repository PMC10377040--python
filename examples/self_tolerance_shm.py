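"""Somatic hypermutation speeds up elimination of a strong self-binder.

A clone seeded in the strongest-binding class faces a self-antigen with
moderate stimulation (k4 = 0.6); the SHM rate p is swept over 0.1-0.4.
"""

from abdyn import preset, run

out = run(preset("shm_self_tolerance"))
for label, (traj, summ) in out.items():
    t99 = summ.time_to_fraction(9, 0.01)
    t99 = f"{t99:g}" if t99 is not None else "never (clone grows)"
    print(f"{label}: total antibody at horizon {summ.total_antibody[-1]:.4g},"
          f" strong binder down to 1% at t = {t99}")
print("\nHigher mutation rates divert production away from the "
      "self-reactive class, so total antibody is lower and the dangerous "
      "clone disappears sooner - hypermutation enforces self-tolerance.")
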