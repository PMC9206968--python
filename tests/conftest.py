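import numpy as np
import pytest

import tpcstroke as tp


@pytest.fixture(scope="session")
def default_run():
    """Default synthetic cohort with its planted truth and a full TPC run.

    Session-scoped: the cohort (n=300, seed 42) and the 20-restart Louvain
    clustering are shared by every test that needs the reference conditions.
    """
    cohort, truth = tp.generate_cohort(tp.SimConfig())
    partition = tp.run_tpc(cohort, kappa=0.5, seed=0, n_restarts=20)
    return cohort, truth, partition


def make_cohort(scores, maxima, arm=None):
    """Small helper: build a CohortTensor from a raw (N, V, M) integer array."""
    scores = np.asarray(scores, dtype=np.int64)
    n, v, m = scores.shape
    items = [tp.ItemMeta(f"item{j}", f"Item {j}", int(maxima[j])) for j in range(v)]
    return tp.CohortTensor(
        scores, [f"P{i}" for i in range(n)], items, list(range(m)), arm
    )


@pytest.fixture
def small_cohort():
    """2 patients x 2 items (maxima 2, 4) x 2 timepoints."""
    scores = np.array([[[0, 1], [3, 4]], [[2, 2], [0, 1]]])
    return make_cohort(scores, [2, 4])
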