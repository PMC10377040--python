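"""Repertoire aging: the antibody distribution drifts toward
self-reactivity.

A naive repertoire (normal composition over the nine classes) faces a
persistent self-antigen with k4 = 0.7.  The SHM rate is swept over
{0, 0.2, 0.5}; the p = 0.2 member is reported along its time ladder.
"""

from abdyn import preset, run

spec = preset("aging_sweep")
out = run(spec)
for label, (_, summ) in out.items():
    print(f"{label}: total antibody at t={spec.t_end:g} = "
          f"{summ.total_antibody[-1]:.4g}")

print("\ncomposition drift at p = 0.2:")
summ = out["p=0.2"][1]
for t in spec.report_times:
    snap = summ.at_time(t)
    strong = sum(snap["composition"][6:])
    print(f"  t={snap['time']:5g}: dominant class {snap['dominant_class']}, "
          f"classes 7-9 share {100 * strong:.1f}%")
print("\nStrong self-binders out-compete the rest because complexes drive "
      "regeneration; hypermutation slows the drift (class 7 rather than 9 "
      "dominates) but cannot reverse it - an immune-kinetic account of "
      "aging.")
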