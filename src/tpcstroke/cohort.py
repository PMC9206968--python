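"""Data model and I/O for longitudinal ordinal cohort data.

A cohort is a dense integer tensor ``X[i, v, t]``: the score of patient *i*
on ordinal item *v* at discrete timepoint *t*.  Each item has a known maximum
score, so every entry satisfies ``0 <= X[i, v, t] <= max_score(v)``.  The
per-timepoint slice ``X[:, :, t]`` is the biadjacency matrix of the bipartite
patient-item network at that timepoint.

Files are plain CSV in long format (``patient,item,timepoint,score[,arm]``)
with a companion item-metadata table (``item,display_name,max_score``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ItemMeta",
    "CohortTensor",
    "CohortValidationError",
    "default_nihss_catalog",
    "load_cohort",
    "write_cohort",
]


class CohortValidationError(ValueError):
    """Raised when cohort data violates the data-model invariants."""


@dataclass(frozen=True)
class ItemMeta:
    """One ordinal assessment item.

    Parameters
    ----------
    item_id : str
        Short unique key, e.g. ``"motor_left_arm"``.
    display_name : str
        Human-readable label.
    max_score : int
        Largest attainable score (severity ceiling); must be >= 1.
    """

    item_id: str
    display_name: str
    max_score: int

    def __post_init__(self) -> None:
        if self.max_score < 1:
            raise CohortValidationError(
                f"item {self.item_id!r}: max_score must be >= 1, got {self.max_score}"
            )


@dataclass
class CohortTensor:
    """Dense longitudinal ordinal cohort: integer scores [patient, item, timepoint].

    Attributes
    ----------
    scores : ndarray of int, shape (N, V, M)
    patients : list of patient ids (length N), sorted ascending
    items : list of ItemMeta (length V), catalog order
    timepoints : list of int ranks 0..M-1
    arm : optional ndarray of int (length N); 1 = treated, 0 = placebo
    """

    scores: np.ndarray
    patients: list
    items: list[ItemMeta]
    timepoints: list[int]
    arm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if not np.issubdtype(self.scores.dtype, np.integer):
            raise CohortValidationError("scores must be integers (ordinal, no rescaling)")
        n, v, m = self.scores.shape
        if len(self.patients) != n or len(self.items) != v or len(self.timepoints) != m:
            raise CohortValidationError("axis labels do not match tensor shape")
        if v < 1 or m < 2 or n < 2:
            raise CohortValidationError(
                f"need N >= 2, V >= 1, M >= 2; got N={n}, V={v}, M={m}"
            )
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate item_id in catalog")
        if self.scores.min() < 0:
            raise CohortValidationError("negative score")
        maxima = np.array([it.max_score for it in self.items])
        over = self.scores > maxima[None, :, None]
        if over.any():
            i, vv, t = np.argwhere(over)[0]
            raise CohortValidationError(
                f"score {self.scores[i, vv, t]} exceeds max_score "
                f"{maxima[vv]} for item {self.items[vv].item_id!r} "
                f"(patient {self.patients[i]!r}, timepoint {self.timepoints[t]})"
            )
        if self.arm is not None:
            self.arm = np.asarray(self.arm)
            if self.arm.shape != (n,) or not set(np.unique(self.arm)) <= {0, 1}:
                raise CohortValidationError("arm must be a binary vector of length N")

    @property
    def n_patients(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.scores.shape[2]

    @property
    def max_scores(self) -> np.ndarray:
        """Per-item maxima, shape (V,)."""
        return np.array([it.max_score for it in self.items])

    def timepoint_slice(self, t: int) -> np.ndarray:
        """Bipartite patient-item adjacency at timepoint ``t`` (shape N x V)."""
        return self.scores[:, :, t]


#: The 15 NIHSS item subscores with their standard score ceilings.
#: Coordination/speech/extinction/gaze/sensory and the two simple LOC probes
#: run 0-2, consciousness/language/visual-field/facial-palsy run 0-3, and the
#: four limb-motor items run 0-4.
_NIHSS_ITEMS: list[tuple[str, str, int]] = [
    ("ataxia", "Coordination", 2),
    ("loc", "Level of consciousness", 3),
    ("dysarthria", "Speech (slurring)", 2),
    ("extinction", "Spatial perception", 2),
    ("gaze", "Eye movements", 2),
    ("language", "Language", 3),
    ("loc_commands", "Command following", 2),
    ("loc_questions", "Question answering", 2),
    ("motor_left_arm", "Left arm strength", 4),
    ("motor_left_leg", "Left leg strength", 4),
    ("motor_right_arm", "Right arm strength", 4),
    ("motor_right_leg", "Right leg strength", 4),
    ("palsy", "Facial weakness", 3),
    ("sensory", "Skin sensation (pain/pinprick)", 2),
    ("visual", "Visual fields", 3),
]


def default_nihss_catalog() -> list[ItemMeta]:
    """The 15-item NIH Stroke Scale catalog with standard per-item maxima."""
    return [ItemMeta(i, d, m) for i, d, m in _NIHSS_ITEMS]


def load_cohort(scores_path, meta_path) -> CohortTensor:
    """Read a long-format cohort CSV plus an item-metadata CSV into a tensor.

    The scores table must contain exactly one row for every
    (patient, item, timepoint) triple; timepoint labels are mapped to ranks
    0..M-1 in ascending order, patients sorted ascending, items kept in
    metadata order.  An optional ``arm`` column (constant per patient)
    carries the binary treatment label.
    """
    meta = pd.read_csv(meta_path)
    for col in ("item", "max_score"):
        if col not in meta.columns:
            raise CohortValidationError(f"item-metadata table lacks column {col!r}")
    if "display_name" not in meta.columns:
        meta["display_name"] = meta["item"]
    items = [
        ItemMeta(str(r.item), str(r.display_name), int(r.max_score))
        for r in meta.itertuples()
    ]

    df = pd.read_csv(scores_path)
    for col in ("patient", "item", "timepoint", "score"):
        if col not in df.columns:
            raise CohortValidationError(f"scores table lacks column {col!r}")
    known = {it.item_id for it in items}
    unknown = set(df["item"].astype(str)) - known
    if unknown:
        raise CohortValidationError(f"items absent from metadata: {sorted(unknown)}")
    if not np.issubdtype(df["score"].dtype, np.integer):
        # reject 2.5-style entries instead of silently truncating
        as_float = df["score"].astype(float)
        if not np.all(as_float == np.round(as_float)):
            raise CohortValidationError("non-integer score value in table")
        df["score"] = as_float.astype(int)

    patients = sorted(df["patient"].unique().tolist())
    tp_labels = sorted(df["timepoint"].unique().tolist())
    if len(tp_labels) < 2:
        raise CohortValidationError("cohort must span at least 2 timepoints")
    p_idx = {p: i for i, p in enumerate(patients)}
    v_idx = {it.item_id: i for i, it in enumerate(items)}
    t_idx = {t: i for i, t in enumerate(tp_labels)}

    dup = df.duplicated(subset=["patient", "item", "timepoint"])
    if dup.any():
        r = df[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate triple (patient={r['patient']!r}, item={r['item']!r}, "
            f"timepoint={r['timepoint']!r})"
        )

    n, v, m = len(patients), len(items), len(tp_labels)
    filled = np.zeros((n, v, m), dtype=bool)
    scores = np.zeros((n, v, m), dtype=np.int64)
    ii = df["patient"].map(p_idx).to_numpy()
    jj = df["item"].astype(str).map(v_idx).to_numpy()
    kk = df["timepoint"].map(t_idx).to_numpy()
    scores[ii, jj, kk] = df["score"].to_numpy()
    filled[ii, jj, kk] = True
    if not filled.all():
        i, j, k = np.argwhere(~filled)[0]
        raise CohortValidationError(
            f"incomplete cohort: missing cell (patient={patients[i]!r}, "
            f"item={items[j].item_id!r}, timepoint={tp_labels[k]!r})"
        )

    arm = None
    if "arm" in df.columns:
        per_patient = df.groupby("patient")["arm"].nunique()
        if (per_patient > 1).any():
            bad = per_patient[per_patient > 1].index[0]
            raise CohortValidationError(f"inconsistent arm label for patient {bad!r}")
        arm_series = df.groupby("patient")["arm"].first()
        arm = arm_series.loc[patients].to_numpy().astype(int)

    return CohortTensor(scores, patients, items, list(range(m)), arm)


def write_cohort(cohort: CohortTensor, scores_path, meta_path=None) -> None:
    """Write a cohort to long-format CSV (and optionally its item metadata).

    ``load_cohort(write_cohort(c))`` reproduces ``c`` exactly.
    """
    n, v, m = cohort.scores.shape
    ii, jj, kk = np.meshgrid(np.arange(n), np.arange(v), np.arange(m), indexing="ij")
    df = pd.DataFrame(
        {
            "patient": [cohort.patients[i] for i in ii.ravel()],
            "item": [cohort.items[j].item_id for j in jj.ravel()],
            "timepoint": [cohort.timepoints[k] for k in kk.ravel()],
            "score": cohort.scores.ravel(),
        }
    )
    if cohort.arm is not None:
        df["arm"] = cohort.arm[ii.ravel()]
    df.to_csv(scores_path, index=False)
    if meta_path is not None:
        pd.DataFrame(
            {
                "item": [it.item_id for it in cohort.items],
                "display_name": [it.display_name for it in cohort.items],
                "max_score": [it.max_score for it in cohort.items],
            }
        ).to_csv(meta_path, index=False)
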