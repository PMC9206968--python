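"""TPC core: binarization, agreement network, modularity, Louvain, profiles.

The derived expectations are checked against independent brute-force
oracles: a double-loop agreement counter, a direct double-sum modularity,
direct averaging for subtype profiles, and exhaustive partition enumeration
for small-network Louvain quality.
"""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tpcstroke as tp
from tpcstroke.clustering import DegenerateNetworkError, TrajectoryProfile

from conftest import make_cohort


def _profiles(mats):
    return [TrajectoryProfile(np.asarray(m), i, 0.5) for i, m in enumerate(mats)]


# ---------------------------------------------------------------- binarize


def test_binarize_worked_example_max5():
    """Item with maximum 5, kappa=0.5: threshold 2.5; 0-2 -> 0, 3-5 -> 1."""
    scores = np.array([[[0, 1, 2], [3, 4, 5]]] * 2)  # 2 patients, 2 items, 3 tps
    cohort = make_cohort(scores, [5, 5])
    profs = tp.binarize(cohort, kappa=0.5)
    np.testing.assert_array_equal(profs[0].matrix, [[0, 0, 0], [1, 1, 1]])


def test_binarize_boundary_score_equal_to_threshold_is_zero():
    # max 4, kappa 0.5: score exactly 2 sits on the threshold and maps to 0
    cohort = make_cohort(np.full((2, 1, 2), 2), [4])
    assert (tp.binarize(cohort, 0.5)[0].matrix == 0).all()


def test_binarize_extremes_and_parameter_validation():
    cohort = make_cohort(np.array([[[1, 0]], [[4, 2]]]), [4])
    # tiny kappa: any positive score is severe
    np.testing.assert_array_equal(tp.binarize(cohort, 1e-9)[0].matrix, [[1, 0]])
    # all-zero cohort stays all-zero
    zeros = make_cohort(np.zeros((2, 2, 2), dtype=int), [2, 2])
    assert all((p.matrix == 0).all() for p in tp.binarize(zeros, 0.5))
    for bad in (0.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            tp.binarize(cohort, bad)


def test_binarize_median_mode():
    # population median per item/timepoint as the severity cutoff
    scores = np.array([[[0]], [[1]], [[3]], [[4]]])[:, :, [0, 0]]
    cohort = make_cohort(scores.reshape(4, 1, 2), [4])
    profs = tp.binarize(cohort, mode="median")  # median = 2 -> scores > 2 severe
    got = np.array([p.matrix[0, 0] for p in profs])
    np.testing.assert_array_equal(got, [0, 0, 1, 1])


# ---------------------------------------------------- patient similarity


def _agreement_oracle(a, b, w=None):
    """Element-by-element double loop over all item/timepoint positions."""
    total = 0.0
    for v in range(a.shape[0]):
        for t in range(a.shape[1]):
            if a[v, t] == b[v, t]:
                total += 1.0 if w is None else w[v, t]
    return total


def test_similarity_trivial_pairs():
    m = np.array([[1, 0], [0, 1], [1, 1]])
    net = tp.patient_similarity(_profiles([m, m, 1 - m]))
    assert net.matrix[0, 1] == m.size  # identical profiles: full agreement V*M
    assert net.matrix[0, 2] == 0  # complementary profiles: zero agreement
    assert net.matrix[0, 0] == 0  # diagonal zeroed by default


def test_similarity_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        a = (rng.random((15, 5)) < 0.5).astype(int)
        b = (rng.random((15, 5)) < 0.5).astype(int)
        net = tp.patient_similarity(_profiles([a, b]))
        assert net.matrix[0, 1] == _agreement_oracle(a, b)


def test_weighted_similarity_matches_oracle():
    rng = np.random.default_rng(2)
    for _ in range(50):
        a = (rng.random((6, 4)) < 0.5).astype(int)
        b = (rng.random((6, 4)) < 0.5).astype(int)
        w = rng.random((6, 4)) * 2
        net = tp.patient_similarity(_profiles([a, b]), weights=w)
        assert net.matrix[0, 1] == pytest.approx(_agreement_oracle(a, b, w))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2**63 - 1), st.integers(3, 8), st.integers(1, 6), st.integers(2, 5))
def test_similarity_symmetry_and_bounds(seed, n, v, m):
    """P is symmetric with integer entries in [0, V*M] under unit weights."""
    rng = np.random.default_rng(seed)
    mats = (rng.random((n, v, m)) < rng.random()).astype(int)
    net = tp.patient_similarity(_profiles(list(mats)))
    p = net.matrix
    np.testing.assert_array_equal(p, p.T)
    off = p[~np.eye(n, dtype=bool)]
    assert off.min() >= 0 and off.max() <= v * m
    assert (off == off.astype(int)).all()


def test_similarity_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        tp.patient_similarity(_profiles([np.zeros((2, 2)), np.zeros((3, 2))]))


# ----------------------------------------------------------- modularity


def _modularity_oracle(a, labels):
    two_m = a.sum()
    k = a.sum(axis=1)
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def _network(a):
    return tp.PatientNetwork(a, list(range(a.shape[0])))


def _two_cliques(k):
    a = np.zeros((2 * k, 2 * k))
    a[:k, :k] = 1.0
    a[k:, k:] = 1.0
    np.fill_diagonal(a, 0.0)
    return a


def test_modularity_closed_forms():
    rng = np.random.default_rng(3)
    a = rng.random((10, 10))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    # one community: Q = 0 exactly
    assert tp.newman_girvan_modularity(_network(a), np.zeros(10)) == pytest.approx(0, abs=1e-12)
    # two disconnected equal cliques split apart: Q = 1/2
    labels = np.repeat([0, 1], 5)
    assert tp.newman_girvan_modularity(_network(_two_cliques(5)), labels) == pytest.approx(0.5)


def test_modularity_matches_double_sum_oracle_and_networkx():
    rng = np.random.default_rng(4)
    for _ in range(25):
        a = rng.random((12, 12)) * (rng.random((12, 12)) < 0.5)
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        labels = rng.integers(0, 3, 12)
        q = tp.newman_girvan_modularity(_network(a), labels)
        assert q == pytest.approx(_modularity_oracle(a, labels), abs=1e-12)
        g = nx.from_numpy_array(a)
        comms = [set(np.flatnonzero(labels == c)) for c in range(3)]
        comms = [c for c in comms if c]
        assert q == pytest.approx(nx.community.modularity(g, comms), abs=1e-9)


def test_modularity_degenerate_inputs():
    with pytest.raises(DegenerateNetworkError):
        tp.newman_girvan_modularity(_network(np.zeros((3, 3))), np.zeros(3))


# -------------------------------------------------------------- louvain


def _set_partitions(items):
    """Enumerate all partitions of a list (exhaustive oracle)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1:]
        yield [[first]] + partition


def test_louvain_recovers_disconnected_cliques():
    part = tp.louvain_cluster(_network(_two_cliques(10)), seed=0)
    assert part.n_communities == 2
    assert len(set(part.labels[:10])) == 1 and len(set(part.labels[10:])) == 1
    assert part.labels[0] != part.labels[10]
    assert part.modularity == pytest.approx(0.5)


def test_louvain_deterministic_under_seed():
    rng = np.random.default_rng(5)
    a = rng.random((30, 30)) * (rng.random((30, 30)) < 0.3)
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0)
    p1 = tp.louvain_cluster(_network(a), seed=9)
    p2 = tp.louvain_cluster(_network(a), seed=9)
    np.testing.assert_array_equal(p1.labels, p2.labels)
    assert p1.modularity == p2.modularity


def _eight_patient_network(rng):
    """Agreement network of 8 patients drawn from 2 archetypes with 15% bit flips."""
    arch = (rng.random((2, 15, 5)) < 0.5).astype(int)
    mats = []
    for i in range(8):
        m = arch[i % 2]
        flip = rng.random(m.shape) < 0.15
        mats.append(np.where(flip, 1 - m, m))
    return tp.patient_similarity(_profiles(mats))


def test_louvain_near_exhaustive_optimum_on_8_nodes():
    """Louvain modularity >= 0.95 x the exhaustive maximum over all 4140 partitions."""
    rng = np.random.default_rng(6)
    for trial in range(3):
        net = _eight_patient_network(rng)
        best = -np.inf
        count = 0
        for partition in _set_partitions(list(range(8))):
            count += 1
            labels = np.empty(8, dtype=int)
            for c, members in enumerate(partition):
                labels[members] = c
            best = max(best, tp.newman_girvan_modularity(net, labels))
        assert count == 4140  # Bell(8)
        got = tp.louvain_cluster(net, seed=trial).modularity
        assert got >= 0.95 * best


def test_louvain_degenerate_and_uniform_networks():
    with pytest.raises(DegenerateNetworkError):
        tp.louvain_cluster(_network(np.zeros((4, 4))), seed=0)
    # uniform complete network (e.g. all profiles identical): one community
    a = np.ones((6, 6)) - np.eye(6)
    part = tp.louvain_cluster(_network(a), seed=0)
    assert part.n_communities == 1 and part.modularity == 0.0


def test_louvain_canonical_labels_sorted_by_size():
    a = np.zeros((7, 7))
    a[:2, :2] = 1  # small clique on nodes 0-1
    a[2:, 2:] = 1  # large clique on nodes 2-6
    np.fill_diagonal(a, 0)
    part = tp.louvain_cluster(_network(a), seed=0)
    assert part.sizes.tolist() == [5, 2]  # descending
    assert part.labels[2] == 0 and part.labels[0] == 1


# ------------------------------------------------------ subtype profiles


def test_subtype_profiles_trivial_and_oracle():
    rng = np.random.default_rng(7)
    m = (rng.random((4, 3)) < 0.5).astype(int)
    profs = _profiles([m, 1 - m, m])
    part = tp.SubtypePartition(
        np.array([0, 0, 1]), [[0, 1], [2]], 0.1, [0, 1, 2], min_report_size=1
    )
    part = tp.subtype_profiles(profs, part)
    # complementary members average to 0.5 everywhere
    np.testing.assert_allclose(part.subtype_profiles[0], 0.5)
    # singleton community equals that patient's profile
    np.testing.assert_array_equal(part.subtype_profiles[1], m)

    # direct-averaging oracle on random partitions
    for _ in range(30):
        n = int(rng.integers(3, 10))
        mats = (rng.random((n, 5, 4)) < 0.5).astype(int)
        labels = rng.integers(0, 3, n)
        labels[:3] = [0, 1, 2]  # no empty community
        comms = [list(np.flatnonzero(labels == c)) for c in range(3)]
        part = tp.SubtypePartition(labels, comms, 0.0, list(range(n)), min_report_size=1)
        part = tp.subtype_profiles(_profiles(list(mats)), part)
        for c in range(3):
            expected = mats[labels == c].mean(axis=0)
            np.testing.assert_allclose(part.subtype_profiles[c], expected)
            assert part.subtype_profiles[c].min() >= 0
            assert part.subtype_profiles[c].max() <= 1


# --------------------------------------------------------------- run_tpc


def test_run_tpc_identical_patients_collapse_to_one_community():
    scores = np.tile(np.array([[0, 2], [4, 1]])[None], (6, 1, 1))
    cohort = make_cohort(scores, [2, 4])
    part = tp.run_tpc(cohort, seed=0)
    assert part.n_communities == 1


def test_run_tpc_kappa_one_documented_single_community():
    # kappa=1: profiles all-zero, agreement network uniform -> one community
    cohort = make_cohort(np.array([[[1, 2]], [[0, 2]], [[2, 1]]]), [2])
    part = tp.run_tpc(cohort, kappa=1.0, seed=0)
    assert part.n_communities == 1 and part.modularity == 0.0


def test_run_tpc_permutation_equivariance():
    cohort, truth = tp.generate_cohort(tp.SimConfig(n_patients=60, seed=9))
    part = tp.run_tpc(cohort, seed=2, n_restarts=5)
    rng = np.random.default_rng(10)
    perm = rng.permutation(cohort.n_patients)
    shuffled = tp.CohortTensor(
        cohort.scores[perm],
        [cohort.patients[i] for i in perm],
        cohort.items,
        cohort.timepoints,
        cohort.arm[perm],
    )
    part2 = tp.run_tpc(shuffled, seed=2, n_restarts=5)
    # same grouping of the same patients, up to community numbering
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(part.labels[perm], part2.labels) == 1.0


def test_run_tpc_modularity_beats_trivial_partition(default_run):
    _, _, partition = default_run
    assert partition.modularity > 0  # all-in-one partition scores exactly 0
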