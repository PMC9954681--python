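import numpy as np
import pytest

import qeegnorm as q

GROUPS = ("20-30", "31-40", "41-50", "51-60", "61-70")


def balanced_sizes(n_per_group: int) -> dict[str, tuple[int, int]]:
    half = n_per_group // 2
    return {g: (half, n_per_group - half) for g in GROUPS}


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects (8 per age group) with default healthy parameters."""
    records, subjects, truth = q.generate_cohort(
        q.hc_spec(group_sizes=balanced_sizes(8)), seed=42)
    return records, subjects, truth


@pytest.fixture(scope="session")
def small_db(small_cohort):
    records, _, _ = small_cohort
    return q.build_norms(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230218)
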