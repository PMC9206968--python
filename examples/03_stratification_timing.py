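"""When do recovery subtypes become identifiable from a single timepoint?

Builds the rank-one symptom-symptom graph of each patient at each timepoint
and trains a fresh two-layer graph convolutional classifier per timepoint to
predict the full-trajectory subtype. High accuracy at a timepoint means the
subtypes are already separated there; here the archetypes are constructed to
diverge only from t=2 onward, so accuracy jumps from chance to near-perfect
at exactly that point.
"""

import numpy as np

import tpcstroke as tp

# two archetypes identical (uniformly mild) at t=0,1, diverging at t>=2
nv, nt = 15, 5
base = np.full((nv, nt), 0.08)
a, b = base.copy(), base.copy()
a[0:5, 2:] = 0.9    # archetype A: items 0-4 severe from t=2
b[8:13, 2:] = 0.9   # archetype B: items 8-12 severe from t=2
cohort, truth = tp.generate_cohort(
    tp.SimConfig(
        n_patients=200,
        templates=[tp.ArchetypeTemplate("late A", a, 0.5),
                   tp.ArchetypeTemplate("late B", b, 0.5)],
        treatment_fraction=0.0, treatment_recovery_boost=0.0, seed=11,
    )
)

partition = tp.run_tpc(cohort, seed=5)
print(f"TPC finds {partition.n_reportable} subtypes from the full trajectories")

curve = tp.stratification_analysis(
    cohort, partition, tp.StratifyConfig(replicates=10, seed=3)
)
print("timepoint  mean accuracy  stderr   (chance = 0.50)")
for t in curve.timepoints:
    print(f"    t={t}       {curve.accuracy['all'][t]:.3f}      "
          f"{curve.stderr['all'][t]:.3f}")
gain = curve.accuracy["all"][4] - curve.accuracy["all"][0]
print(f"accuracy gain t=0 -> t=4: {gain:.3f} — stratification emerges only "
      f"once the planted archetypes diverge")
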