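import numpy as np
import pandas as pd
import pytest

import morscreen as ms


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast synthetic cohort with two planted abundant markers."""
    config = ms.SimulationConfig(
        n_assays=120, n_reference=4, n_abundant=20,
        planted=(("mir-010", -1.5), ("mir-011", 1.5)),
        seed=42,
    )
    cq, meta, truth = ms.simulate_cohort(config)
    return cq, meta, truth


@pytest.fixture(scope="session")
def joined(small_cohort):
    cq, meta, _ = small_cohort
    return ms.join_metadata(cq, meta)


def toy_cq(values, cutoff=34.0, samples=None, assays=None, pool=None):
    """Build a CqMatrix from a nested list (None = missing well)."""
    arr = np.array([[np.nan if v is None else float(v) for v in row]
                    for row in values])
    assays = assays or [f"a{i+1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(arr.shape[1])]
    frame = pd.DataFrame(arr, index=assays, columns=samples)
    pool_s = pd.Series(pool, index=assays) if pool is not None else None
    return ms.CqMatrix(frame, pool_s, cutoff)


def toy_meta(groups, samples=None, **extra):
    samples = samples or [f"s{j+1}" for j in range(len(groups))]
    table = pd.DataFrame({"group": groups}, index=samples)
    for key, vals in extra.items():
        table[key] = vals
    return ms.CohortMetadata(table)
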