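"""Synthetic longitudinal stroke cohorts with planted recovery archetypes.

The generator emulates the structure the downstream analysis assumes: a
15-item ordinal symptom battery observed at 5 discrete timepoints, three
planted recovery archetypes (left-motor, right-motor, mildly affected),
severity that decays over time, and a binary treatment arm whose effect is an
extra per-timestep decay of the probability of severe expression.

Each archetype is a template of probabilities ``severity[v, t]``: the chance
a member severely expresses item *v* at time *t*.  A patient's score is drawn
by a Bernoulli severe/mild indicator at that probability, a latent severity
level for the chosen state (0.9 severe / 0.1 mild) plus Gaussian noise,
clamped to [0, 1], scaled by the item maximum and rounded to an integer.
True archetype labels are returned separately from the cohort so downstream
stages cannot consume them by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTensor, ItemMeta, default_nihss_catalog

__all__ = [
    "ArchetypeTemplate",
    "SimConfig",
    "SimulationError",
    "default_templates",
    "generate_cohort",
    "empirical_affected_fraction",
]

# Latent severity level drawn for severe vs mild expression, before noise.
# Chosen so that at default noise (sd 0.05) the level sits >= 3 sd away from
# every item's kappa=0.5 binarization boundary, keeping the realized
# affected fraction close to the template probability.
SEVERE_LEVEL = 0.9
MILD_LEVEL = 0.1


class SimulationError(ValueError):
    """Raised for degenerate simulation configurations."""


@dataclass(frozen=True)
class ArchetypeTemplate:
    """A planted recovery archetype.

    severity[v, t] is the probability that a member of this archetype is
    severely affected by item v at timepoint t; prevalence is the mixing
    proportion of the archetype in the cohort.
    """

    name: str
    severity: np.ndarray
    prevalence: float

    def __post_init__(self) -> None:
        sev = np.asarray(self.severity, dtype=float)
        object.__setattr__(self, "severity", sev)
        if sev.ndim != 2:
            raise SimulationError("severity must be an [item, timepoint] matrix")
        if sev.min() < 0 or sev.max() > 1:
            raise SimulationError("severity entries must lie in [0, 1]")
        if not (0 <= self.prevalence <= 1):
            raise SimulationError("prevalence must lie in [0, 1]")


@dataclass
class SimConfig:
    """Simulation parameters (defaults define the reference study conditions)."""

    n_patients: int = 300
    templates: list[ArchetypeTemplate] = field(default_factory=lambda: default_templates())
    items: list[ItemMeta] = field(default_factory=default_nihss_catalog)
    treatment_fraction: float = 0.5
    treatment_recovery_boost: float = 0.05
    noise_sd: float = 0.05
    seed: int = 42


def _ramp(v_idx: np.ndarray, high: dict[int, float], base: float,
          n_items: int, n_timepoints: int, final_fraction: float = 0.55) -> np.ndarray:
    """Severity template: per-item start level decaying linearly to a fraction of it."""
    start = np.full(n_items, base)
    for v, p in high.items():
        start[v] = p
    t = np.arange(n_timepoints) / max(n_timepoints - 1, 1)
    decay = 1.0 - (1.0 - final_fraction) * t
    return start[:, None] * decay[None, :]


def default_templates(n_timepoints: int = 5) -> list[ArchetypeTemplate]:
    """Three archetypes over the 15-item default catalog.

    'left motor': left arm/leg weakness with extinction (hemineglect) and
    gaze deviation — the right-hemisphere syndrome; right-sided motor items
    essentially absent.  'right motor': the mirror image with language and
    command-following deficits — the left-hemisphere syndrome.  'mildly
    affected': uniformly low severity.  All severities decay over time
    (recovery); uniform prevalences.
    """
    catalog = default_nihss_catalog()
    idx = {it.item_id: v for v, it in enumerate(catalog)}
    nv = len(catalog)

    left = _ramp(
        np.arange(nv),
        {
            idx["motor_left_arm"]: 0.92,
            idx["motor_left_leg"]: 0.90,
            idx["extinction"]: 0.85,
            idx["gaze"]: 0.82,
            idx["sensory"]: 0.55,
            idx["visual"]: 0.45,
            idx["palsy"]: 0.45,
            idx["motor_right_arm"]: 0.04,
            idx["motor_right_leg"]: 0.04,
            idx["language"]: 0.06,
            idx["loc_commands"]: 0.06,
        },
        base=0.18,
        n_items=nv,
        n_timepoints=n_timepoints,
    )
    right = _ramp(
        np.arange(nv),
        {
            idx["motor_right_arm"]: 0.92,
            idx["motor_right_leg"]: 0.90,
            idx["language"]: 0.85,
            idx["loc_commands"]: 0.82,
            idx["loc_questions"]: 0.55,
            idx["dysarthria"]: 0.45,
            idx["palsy"]: 0.45,
            idx["motor_left_arm"]: 0.04,
            idx["motor_left_leg"]: 0.04,
            idx["extinction"]: 0.08,
            idx["gaze"]: 0.08,
        },
        base=0.18,
        n_items=nv,
        n_timepoints=n_timepoints,
    )
    mild = _ramp(
        np.arange(nv), {}, base=0.12, n_items=nv, n_timepoints=n_timepoints,
        final_fraction=0.3,
    )

    return [
        ArchetypeTemplate("left motor", left, 1 / 3),
        ArchetypeTemplate("right motor", right, 1 / 3),
        ArchetypeTemplate("mildly affected", mild, 1 / 3),
    ]


def generate_cohort(config: SimConfig) -> tuple[CohortTensor, np.ndarray]:
    """Draw a synthetic cohort; returns ``(cohort, true_archetype_labels)``.

    Each patient draws an archetype by prevalence and an arm by
    ``treatment_fraction``.  The severe-expression probability at time t is
    ``clip(severity[v, t] - boost * t * arm, 0, 1)``; the realized latent
    severity (severe/mild level + Gaussian noise) is clamped to [0, 1],
    scaled by the item maximum, and rounded.  Identical seeds give identical
    cohorts.
    """
    if config.n_patients < 2:
        raise SimulationError("need at least 2 patients")
    if not config.templates:
        raise SimulationError("need at least one archetype template")
    prev = np.array([t.prevalence for t in config.templates], dtype=float)
    if not np.isclose(prev.sum(), 1.0):
        raise SimulationError(f"prevalences must sum to 1, got {prev.sum():.4f}")
    shapes = {t.severity.shape for t in config.templates}
    if len(shapes) != 1:
        raise SimulationError("all templates must share one severity shape")
    (nv, nt) = shapes.pop()
    if nv != len(config.items):
        raise SimulationError(
            f"template item dimension {nv} != catalog size {len(config.items)}"
        )

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    labels = rng.choice(len(config.templates), size=n, p=prev)
    arm = (rng.random(n) < config.treatment_fraction).astype(int)

    sev = np.stack([t.severity for t in config.templates])  # (K, V, M)
    p = sev[labels]  # (N, V, M)
    t_ranks = np.arange(nt)
    p = np.clip(
        p - config.treatment_recovery_boost * t_ranks[None, None, :] * arm[:, None, None],
        0.0,
        1.0,
    )
    severe = rng.random((n, nv, nt)) < p
    latent = np.where(severe, SEVERE_LEVEL, MILD_LEVEL)
    # degenerate probabilities pin the latent to the scale ends so that
    # severity 1.0 saturates at max_score and 0.0 stays at zero
    latent = np.where(p >= 1.0, 1.0, latent)
    latent = np.where(p <= 0.0, 0.0, latent)
    if config.noise_sd > 0:
        latent = latent + rng.normal(0.0, config.noise_sd, size=latent.shape)
    latent = np.clip(latent, 0.0, 1.0)

    maxima = np.array([it.max_score for it in config.items])
    scores = np.rint(latent * maxima[None, :, None]).astype(np.int64)

    patients = [f"P{i:04d}" for i in range(n)]
    cohort = CohortTensor(scores, patients, list(config.items), list(range(nt)), arm)
    return cohort, labels


def empirical_affected_fraction(
    cohort: CohortTensor, labels: np.ndarray, kappa: float
) -> np.ndarray:
    """Per-archetype fraction of patients whose binarized score is 1.

    Returns an array (n_archetypes, V, M); converges to the template severity
    as n grows and noise_sd -> 0.  A validation aid for the generator.
    """
    labels = np.asarray(labels)
    if labels.shape != (cohort.n_patients,):
        raise SimulationError("labels must cover every patient exactly once")
    maxima = cohort.max_scores
    binary = cohort.scores > (maxima[None, :, None] * kappa)
    uniq = np.unique(labels)
    out = np.empty((len(uniq), cohort.n_items, cohort.n_timepoints))
    for k, lab in enumerate(uniq):
        out[k] = binary[labels == lab].mean(axis=0)
    return out
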