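import numpy as np
import pandas as pd
import pytest

from mbtemporal import profiling
from mbtemporal.io_cohort import CohortTable
from mbtemporal.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-participant, 20-day, 40-genus cohort with ground truth."""
    spec = CohortSpec(n_participants=6, n_days=20, n_genera=40, seed=7,
                      read_depth=20000)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_qmp(small_cohort):
    cohort, _ = small_cohort
    build = profiling.build_qmp(cohort.table, cohort.copy_numbers,
                                cohort.meta["load"], seed=3)
    return build


def make_table(abundance: np.ndarray, participants, days, unit="reads",
               genus_prefix="g"):
    """Small helper to build a CohortTable from raw pieces."""
    n, g = abundance.shape
    sids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    ab = pd.DataFrame(abundance, index=sids,
                      columns=[f"{genus_prefix}{j}" for j in range(g)])
    samples = pd.DataFrame({"participant_id": participants, "day": days}, index=sids)
    return CohortTable(abundance=ab, unit=unit, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
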