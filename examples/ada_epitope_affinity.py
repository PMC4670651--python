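"""Why epitope affinity, not antigen processing speed, gates ADA.

Runs the epitope-affinity preset: a uM-affinity baseline (epitopes with
MHC II Kd of 1230 and 850 nM) against two aggregate mimics -- a 16.6-fold
faster internalization rate, and the induction of one extra high-affinity
epitope (Kd = 38 nM).  Surface presentation is supply-saturated, so
faster uptake changes nothing, while a single high-affinity epitope
multiplies cumulative ADA several-fold.
"""

from aggimmuno.scenarios import run_preset

results = run_preset("epitope-affinity")
for name in ("low-affinity", "low-affinity-ir-x16.6", "plus-high-affinity"):
    r = results[name]
    fold = r.fold_change if r.fold_change is not None else 1.0
    peak_m = r.trajectory.surface_complexes.max(axis=0)
    print(f"{name:22s} cumulative ADA {r.cumulative_ada:10.4g} pM*day  "
          f"fold {fold:6.3g}  peak MHC II complexes {peak_m.round(0)}")
print("-> the 38 nM epitope lifts presentation ~14-fold and cumulative ADA")
print("   >4-fold; a 16.6x faster internalization rate leaves both flat.")
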