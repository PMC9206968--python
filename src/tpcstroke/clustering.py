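"""Trajectory profile clustering (TPC).

Pipeline: binarize each patient's item-by-timepoint score matrix against a
fraction ``kappa`` of each item's maximum (the *trajectory profile* T^i),
count profile agreements between every patient pair to form a weighted
patient-patient network P, maximize Newman-Girvan modularity on P with the
Louvain method (the number of communities L is an output, not an input), and
average member profiles within each community to obtain *subtype profiles*
S^l whose entries are affected fractions in [0, 1].

Communities smaller than ``min_report_size`` patients keep their labels but
are flagged non-reportable, matching the convention of omitting tiny
clusters from subtype reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cohort import CohortTensor

__all__ = [
    "TrajectoryProfile",
    "PatientNetwork",
    "SubtypePartition",
    "DegenerateNetworkError",
    "binarize",
    "patient_similarity",
    "newman_girvan_modularity",
    "louvain_cluster",
    "subtype_profiles",
    "run_tpc",
]

DEFAULT_KAPPA = 0.5
DEFAULT_RESTARTS = 20
MIN_REPORT_SIZE = 10


class DegenerateNetworkError(ValueError):
    """Raised when the patient network carries no clusterable structure."""


@dataclass
class TrajectoryProfile:
    """Binary item-by-timepoint severity indicator matrix for one patient."""

    matrix: np.ndarray  # (V, M), entries in {0, 1}
    patient_id: object
    kappa: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not set(np.unique(self.matrix)) <= {0, 1}:
            raise ValueError("trajectory profile entries must be binary")


@dataclass
class PatientNetwork:
    """Symmetric patient-patient agreement network.

    ``matrix[i, j]`` is the (optionally weighted) count of item-timepoint
    positions where profiles i and j agree; ``diagonal_zeroed`` records
    whether self-similarities were removed before community detection.
    """

    matrix: np.ndarray
    patient_ids: list
    weights: np.ndarray | None = None
    diagonal_zeroed: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("patient network must be square")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("patient network must be symmetric")
        if self.matrix.min() < 0:
            raise ValueError("agreement weights must be nonnegative")


@dataclass
class SubtypePartition:
    """A community partition of the patient network with subtype profiles."""

    labels: np.ndarray  # per-patient community index, 0..L-1
    communities: list[list]  # patient ids per community
    modularity: float
    patient_ids: list
    sizes: np.ndarray = field(init=False)
    subtype_profiles: list[np.ndarray] | None = None
    reportable: np.ndarray | None = None
    min_report_size: int = MIN_REPORT_SIZE
    kappa: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.sizes = np.array([len(c) for c in self.communities])
        if self.sizes.sum() != len(self.labels):
            raise ValueError("communities must partition the patient set")
        self.reportable = self.sizes >= self.min_report_size

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    @property
    def n_reportable(self) -> int:
        return int(self.reportable.sum())


def binarize(cohort: CohortTensor, kappa: float = DEFAULT_KAPPA,
             mode: str = "fraction") -> list[TrajectoryProfile]:
    """Threshold scores into binary trajectory profiles.

    ``mode="fraction"`` (default): entry is 1 iff score > max_score * kappa —
    strict inequality, so a score exactly at the threshold maps to 0.
    ``mode="median"``: entry is 1 iff score > the per-item population median
    at that timepoint (an alternative severity cutoff; kappa is ignored).
    """
    if mode == "fraction":
        if not (0 < kappa <= 1):
            raise ValueError(f"kappa must lie in (0, 1], got {kappa}")
        thresh = cohort.max_scores[None, :, None] * kappa
    elif mode == "median":
        thresh = np.median(cohort.scores, axis=0)[None, :, :]
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    binary = (cohort.scores > thresh).astype(np.int8)
    return [
        TrajectoryProfile(binary[i], cohort.patients[i], kappa)
        for i in range(cohort.n_patients)
    ]


def patient_similarity(
    profiles: list[TrajectoryProfile],
    weights: np.ndarray | None = None,
    zero_diagonal: bool = True,
) -> PatientNetwork:
    """Agreement-count network: P_ij = sum_vt w_vt * [T^i_vt == T^j_vt].

    With uniform unit weights P_ij is the integer count of matching
    positions, bounded by V*M.  Self-similarities (the diagonal, equal to
    the total weight) are zeroed by default before community detection.
    """
    shapes = {p.matrix.shape for p in profiles}
    if len(shapes) != 1:
        raise ValueError(f"profiles have mismatched shapes: {sorted(shapes)}")
    shape = shapes.pop()
    stack = np.stack([p.matrix for p in profiles]).astype(float)  # (N, V, M)
    n = stack.shape[0]
    flat = stack.reshape(n, -1)
    if weights is None:
        w = np.ones(flat.shape[1])
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != shape:
            raise ValueError(f"weights shape {weights.shape} != profile shape {shape}")
        if weights.min() < 0:
            raise ValueError("weights must be nonnegative")
        w = weights.ravel()
    # agreement = both 1 or both 0
    p = (flat * w) @ flat.T + ((1 - flat) * w) @ (1 - flat).T
    p = (p + p.T) / 2  # exact symmetry against float round-off
    if zero_diagonal:
        np.fill_diagonal(p, 0.0)
    return PatientNetwork(
        p,
        [pr.patient_id for pr in profiles],
        weights=weights,
        diagonal_zeroed=zero_diagonal,
    )


def newman_girvan_modularity(network: PatientNetwork, labels) -> float:
    """Newman-Girvan modularity of a labeling on a weighted network.

    Q = (1/2m) * sum_ij (P_ij - k_i k_j / 2m) * [c_i == c_j], with k the
    weighted degree and 2m the total edge weight.
    """
    a = network.matrix
    labels = np.asarray(labels)
    if a.size == 0:
        raise DegenerateNetworkError("empty network")
    two_m = a.sum()
    if two_m <= 0:
        raise DegenerateNetworkError("network has zero total weight")
    k = a.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    q = ((a - np.outer(k, k) / two_m) * same).sum() / two_m
    return float(q)


def _relabel_canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities by descending size; ties by smallest member index."""
    uniq = np.unique(labels)
    order = sorted(
        uniq,
        key=lambda c: (-int((labels == c).sum()), int(np.argmax(labels == c))),
    )
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in labels])


def louvain_cluster(
    network: PatientNetwork,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    min_report_size: int = MIN_REPORT_SIZE,
) -> SubtypePartition:
    """Louvain modularity maximization with seeded restarts.

    Runs Louvain ``n_restarts`` times with seeds fanned out from ``seed`` and
    keeps the labeling with the highest Newman-Girvan modularity.  The number
    of communities is whatever maximizes modularity, never an input.  Labels
    are canonical: descending community size, ties broken by smallest member
    index.  A network that is all-zero after diagonal removal raises
    :class:`DegenerateNetworkError`; a uniform off-diagonal network (no
    structure, e.g. all profiles identical) returns a single community.
    """
    a = network.matrix
    n = a.shape[0]
    off = a[~np.eye(n, dtype=bool)]
    if a.sum() <= 0:
        raise DegenerateNetworkError(
            "patient network is all-zero after diagonal removal"
        )
    if np.allclose(off, off[0]):
        # complete uniform graph: modularity cannot exceed 0, one community
        labels = np.zeros(n, dtype=int)
        return SubtypePartition(
            labels,
            [list(network.patient_ids)],
            0.0,
            list(network.patient_ids),
            min_report_size=min_report_size,
        )

    g = nx.from_numpy_array(a)
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best_labels, best_q = None, -np.inf
    for s in run_seeds:
        comms = nx.community.louvain_communities(g, weight="weight", seed=int(s))
        labels = np.empty(n, dtype=int)
        for c, members in enumerate(comms):
            labels[list(members)] = c
        q = newman_girvan_modularity(network, labels)
        if q > best_q:
            best_q, best_labels = q, labels

    labels = _relabel_canonical(best_labels)
    communities = [
        [network.patient_ids[i] for i in np.flatnonzero(labels == c)]
        for c in range(labels.max() + 1)
    ]
    return SubtypePartition(
        labels,
        communities,
        best_q,
        list(network.patient_ids),
        min_report_size=min_report_size,
    )


def subtype_profiles(
    profiles: list[TrajectoryProfile], partition: SubtypePartition
) -> SubtypePartition:
    """Attach subtype profiles S^l: the element-wise mean of member profiles."""
    if len(profiles) != len(partition.labels):
        raise ValueError("partition does not cover the profile list")
    stack = np.stack([p.matrix for p in profiles]).astype(float)
    out = []
    for c in range(partition.n_communities):
        members = partition.labels == c
        if not members.any():
            raise ValueError(f"community {c} is empty")
        out.append(stack[members].mean(axis=0))
    partition.subtype_profiles = out
    return partition


def run_tpc(
    cohort: CohortTensor,
    kappa: float = DEFAULT_KAPPA,
    weights: np.ndarray | None = None,
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    min_report_size: int = MIN_REPORT_SIZE,
    threshold_mode: str = "fraction",
) -> SubtypePartition:
    """Full TPC run: binarize -> similarity network -> Louvain -> profiles."""
    profiles = binarize(cohort, kappa, mode=threshold_mode)
    network = patient_similarity(profiles, weights=weights)
    partition = louvain_cluster(
        network, seed=seed, n_restarts=n_restarts, min_report_size=min_report_size
    )
    partition.kappa = kappa
    return subtype_profiles(profiles, partition)
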