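# Methods

## Model and assumptions

The package treats a longitudinal cohort as an integer tensor
`X[i, v, t]` of ordinal severity scores (patient × item × timepoint), each
item with a known maximum. Time is a sequence of discrete ranks 0..M−1;
absolute intervals between ranks are not used anywhere, only order, so
unevenly spaced assessments (admission, 2 h, 24 h, 7–10 days, 3 months) are
admissible. Scores must be complete — the loader rejects missing cells
rather than imputing, because imputation distorts per-patient change
patterns, which are exactly what the method clusters.

Trajectory profile clustering assumes that what characterizes a recovery
subtype is the *set of severely expressed symptoms over time*, not graded
severity. Binarization at a fraction κ of each item's maximum deliberately
discards within-severe gradation; two patients agree at a position when both
are severe or both are not. The agreement count is therefore bounded by
V·M and is highest for patients with identical severe-symptom sets,
including jointly unaffected positions — mildly affected patients cluster
together by shared absence of severe symptoms, which is the intended
behavior.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| κ (kappa) | 0.5 | severity cutoff as a fraction of the item maximum; a score equal to `max·κ` is *not* severe (strict inequality) |
| threshold mode | `fraction` | `median` instead binarizes against the per-item, per-timepoint population median |
| agreement weights `w[v,t]` | uniform 1 | optional clinical weighting of items/timepoints; uniform absent consensus |
| Louvain restarts | 20 | best-modularity partition kept; seeds fan out from one master seed |
| min report size | 10 | communities below this are kept in the labels but flagged non-reportable |
| hidden units | 64 | GCN hidden width (16 also reasonable for this problem size) |
| learning rate / optimizer | 0.01, ADAM (β₁ 0.9, β₂ 0.999, ε 1e−8) | full-batch updates; the per-timepoint datasets are small |
| split / epochs / replicates | 0.7 / 100 / 10 | stratified seeded split; replicate seeds give the standard-error bars |
| node features | one-hot identity | lets the model learn item-specific roles; `degree` mode provided |

## Numerical and design choices

- **Threshold boundary.** Severity is strict: `score > max·κ`. With κ = 0.5
  and an item maximum of 5, the threshold is 2.5, so {0,1,2} → 0 and
  {3,4,5} → 1.
- **Diagonal policy.** Self-agreements (always Σw) are zeroed before
  community detection; self-loops carry no inter-patient information and
  bias modularity.
- **Louvain.** The dense weighted agreement network is clustered as-is (no
  sparsification) via networkx's Louvain implementation; modularity itself
  is computed by this package and used both to select the best restart and
  to report Q. The number of communities is never supplied. Labels are
  canonicalized by descending community size (ties: smallest member index),
  so identical runs are bit-identical and permuting the patient order
  permutes labels equivalently.
- **Degenerate networks.** An all-zero network (impossible under the
  agreement construction unless empty) raises an error. A *uniform*
  off-diagonal network — e.g. κ = 1 makes every profile all-zero and every
  pair agree everywhere — carries no structure; it deterministically yields
  a single community with Q = 0, and the downstream classification stage
  then refuses to run for lack of a second class.
- **GCN.** Propagation uses `D^{-1/2}(G+I)D^{-1/2}` (self-connections
  added), so isolated symptoms propagate their own features and an empty
  graph still produces a valid probability vector. Two ReLU layers, output
  width = number of reportable subtypes, mean readout over nodes, softmax,
  cross-entropy. Gradients are analytic NumPy expressions verified against
  central finite differences (relative error < 1e−4 in the suite). Weights
  are Glorot-uniform from a seeded generator; no biases. Patients in
  non-reportable communities are excluded from classification; an arm slice
  is only classified if it retains at least two subtypes with ≥4 members
  (a stratified 70/30 split needs at least that).
- **Seed fan-out.** One master seed maps to per-stage seeds via CRC32 of
  `"<stage>:<seed>"` modulo 2³¹ — stable across platforms and sessions,
  unlike Python's salted `hash`.

## The synthetic cohort generator

The generator defines the reference study conditions: 300 patients, the
15-item catalog (maxima 2–4), 5 timepoints, three planted archetypes with
uniform prevalence, a 50% treated arm, per-timestep treatment decay 0.05 of
the severe-expression probability, latent noise sd 0.05, seed 42.

Each archetype is a template `severity[v, t]` giving the probability that a
member severely expresses item v at time t. The left-motor template is high
(≥ 0.8 at baseline) on left arm/leg motor, extinction and gaze with
essentially no right-sided motor involvement; the right-motor template
mirrors it with language and command-following deficits; the mild template
is ≤ 0.2 everywhere. All templates decay linearly in time (to 55% of the
baseline level by the last timepoint; 30% for the mild group), so severity
is non-increasing — recovery without relapse.

Scores are drawn in three steps: a Bernoulli severe/mild indicator at
probability `clip(severity − boost·t·arm, 0, 1)`; a latent severity level of
0.9 (severe) or 0.1 (mild) plus Gaussian noise, clamped to [0, 1], with
degenerate probabilities (0 or 1) pinned to the scale ends so deterministic
configurations saturate exactly; and rounding of `latent · max(v)` to an
integer score. The 0.9/0.1 levels keep every item ≥ 3 noise-sd away from
its κ = 0.5 binarization boundary at the default noise, so the realized
affected fraction tracks the template probability (verified by Monte Carlo
in the suite). Treatment accelerates recovery without changing archetype
membership, mirroring the assumption that arms share subtypes but differ in
severity.

What the generator does **not** emulate: real NIHSS marginal distributions,
within-patient temporal autocorrelation of the noise (draws are independent
across cells given the archetype), dropout or death, ceiling effects from
comorbidity, or inter-item correlation beyond what the archetype templates
impose. Passing tests on this cohort therefore demonstrate that the
implementation recovers structure *of the kind the method assumes*, not
that real stroke cohorts contain exactly three subtypes.

## Problem sizes used in the checks

The reproduction script and test suite run at desk scale: the reference
cohort has 300 patients (recovery of the three archetypes, adjusted Rand
index ≥ 0.9), the Monte-Carlo generator check uses 2 000, the
late-separation timing fixture 200 patients with 10 replicate seeds, and the
exhaustive modularity oracle enumerates all 4 140 partitions of an
8-patient network. These sizes were chosen so each property is decided with
comfortable statistical margin while the whole suite completes in a few
minutes.

## Known limitations

- Modularity values on dense agreement networks are small in absolute terms
  (the network is nearly complete; Q ≈ 0.04 on the reference cohort), so Q
  is comparable across runs on the same data but not across datasets.
- Louvain is greedy; restarts mitigate but do not eliminate local optima.
- The GCN sees rank-one graphs, so per-timepoint information is exactly the
  severe-symptom set; accuracy curves measure separation of those sets, and
  arm-specific curves slice a pooled-label classification rather than
  re-clustering per arm.
- With strong treatment effects, treated patients' late-time profiles
  approach the mild pattern, which can *reduce* late-timepoint accuracy on
  synthetic data — visible in the reference run as a dip at t = 4.
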