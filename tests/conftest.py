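import warnings

import numpy as np
import pandas as pd
import pytest

import dfncstates as d

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def default_partition():
    return d.NetworkPartition.default()


@pytest.fixture(scope="session")
def tiny_partition():
    """Four components in two networks, for fast windowing tests."""
    ids = ("c1", "c2", "c3", "c4")
    return d.NetworkPartition(ids, {"c1": "A", "c2": "A", "c3": "B", "c4": "B"})


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-subject default-configuration cohort shared across slow tests."""
    cfg = d.CohortConfig(group_sizes={"OCD": 7, "UFDR": 6, "HC": 7}, T=240)
    cohort, truth = d.simulate_cohort(cfg, seed=3)
    return cohort, truth


@pytest.fixture(scope="session")
def small_fnc(small_cohort):
    cohort, _ = small_cohort
    prepped = d.prep_cohort(cohort)
    return d.compute_dfnc(prepped)


@pytest.fixture(scope="session")
def small_model(small_fnc):
    return d.fit_states(small_fnc, k=2, seed=0)


def single_state_cohort(partition, cov, T=240, n_subjects=1, seed=0, group="HC"):
    """Cohort whose every subject stays in one state the whole scan."""
    seq = np.ones(T, dtype=int)
    data = np.stack(
        [d.simulate_subject([cov], seq, seed=seed + i) for i in range(n_subjects)]
    )
    ids = [f"sub-{i + 1:03d}" for i in range(n_subjects)]
    manifest = pd.DataFrame({"subject_id": ids, "group": [group] * n_subjects})
    return d.CohortTimecourses(ids, data, manifest, partition)
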