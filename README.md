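# tpc-stroke

Recovery after stroke is heterogeneous: patients differ in which symptoms
they have, how severe they are, and how fast they resolve. `tpc-stroke`
implements **trajectory profile clustering (TPC)** — a network method that
groups patients by the *pattern* of their symptom evolution rather than by a
summary score — together with a per-timepoint **graph-convolutional
classifier** that measures *when* those recovery subtypes become
identifiable. It is aimed at clinical researchers working with longitudinal
ordinal assessments such as the 15-item NIH Stroke Scale (NIHSS), and ships
a synthetic cohort generator so the whole pipeline is testable end to end
without any patient data.

## The method

Given scores `X[i, v, t]` for patient *i*, item *v* (maximum `max(v)`),
timepoint *t*:

1. **Binarize.** `T^i[v, t] = 1` iff `X[i, v, t] > max(v) · κ` (default
   κ = 0.5; a score exactly at the threshold maps to 0). `T^i` marks the
   symptoms a patient *severely* expresses at each time.
2. **Agreement network.** `P[i, j] = Σ_{v,t} w[v,t] · [T^i[v,t] = T^j[v,t]]`
   counts positions where two profiles agree (uniform unit weights by
   default; self-similarities are zeroed).
3. **Cluster.** Louvain community detection maximizes Newman–Girvan
   modularity `Q = (1/2m) Σ_{ij} (P_ij − k_i k_j / 2m) δ(c_i, c_j)` on `P`.
   The number of subtypes `L` is an output of the optimization.
4. **Subtype profiles.** `S^l[v, t]` is the mean of member profiles — the
   fraction of the subtype severely affected by item *v* at time *t*.
   Communities with fewer than 10 patients are flagged non-reportable.
5. **Stratification timing.** For each timepoint, each patient's binary
   symptom vector `v` defines a rank-one symptom–symptom graph `G = v vᵀ`.
   A two-layer GCN (symmetric degree-normalized adjacency with
   self-connections, ReLU, mean readout, softmax; trained with full-batch
   ADAM on a 70/30 stratified split) predicts the full-trajectory subtype
   from that single-timepoint graph. Held-out accuracy per timepoint shows
   when the subtypes separate.

## Worked example

```sh
python examples/02_cluster_subtypes.py
```

```
found L=3 communities (3 with >= 10 patients)
community sizes: [110, 98, 92]
modularity Q = 0.0425 (the all-in-one partition scores exactly 0)
adjusted Rand index vs planted archetypes: 1.000 (1 = identical)
subtype 0 (n=110): most affected at baseline: motor_left_arm (0.95), extinction (0.88), motor_left_leg (0.85)
subtype 1 (n=98): most affected at baseline: extinction (0.18), loc (0.15), motor_right_leg (0.14)
subtype 2 (n=92): most affected at baseline: motor_right_arm (0.95), motor_right_leg (0.90), language (0.89)
```

On a 300-patient synthetic cohort, modularity maximization finds exactly the
three planted archetypes: a left-motor subtype (left limb weakness with
hemineglect and gaze deviation — a right-hemisphere syndrome), a right-motor
subtype (right limb weakness with aphasia — a left-hemisphere syndrome), and
a mildly affected group. The adjusted Rand index of 1.0 means the recovered
grouping matches the planted one patient for patient.
`examples/03_stratification_timing.py` shows the timing analysis: with
archetypes constructed to diverge only from t = 2 onward, per-timepoint GCN
accuracy is at chance (≈0.5) for t = 0,1 and ≈0.98 for t ≥ 2.

The same stages are available from the shell:

```sh
tpc-stroke simulate --n-patients 300 --seed 42 --outdir sim
tpc-stroke tpc sim/cohort.csv sim/items.csv --kappa 0.5 --outdir out
tpc-stroke stratify sim/cohort.csv sim/items.csv --out accuracy.csv
tpc-stroke run-all --seed 42 --outdir run   # full pipeline + JSON manifest
```

Input format: long CSV `patient,item,timepoint,score[,arm]` plus an item
table `item,display_name,max_score`. Every (patient, item, timepoint) triple
must appear exactly once; scores are validated against the item maxima.

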