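import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from baldeconv import (
    BetaMatrix,
    SampleSheet,
    generate_profiles,
    sample_individuals,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def profiles():
    """Ground-truth profiles: 4 cell types, 60 planted probes per direction
    per type, separation 0.5."""
    return generate_profiles(2000, n_signature_per_type=60, delta=0.5, seed=11)


@pytest.fixture(scope="session")
def exact_reference(profiles):
    """Two noiseless reference samples per cell type (betas equal the
    cell-type means exactly)."""
    return sample_individuals(profiles, n_per_type=2, precision=np.inf, seed=12)


@pytest.fixture(scope="session")
def noisy_reference(profiles):
    """Three reference samples per type at precision 100 (realistic noise)."""
    return sample_individuals(profiles, n_per_type=3, precision=100.0, seed=13)


@pytest.fixture(scope="session")
def high_precision_reference(profiles):
    """Three reference samples per type at precision 1e4 (near-noiseless)."""
    return sample_individuals(profiles, n_per_type=3, precision=1e4, seed=14)


@pytest.fixture()
def small_beta():
    data = pd.DataFrame(
        {
            "s1": [0.1, 0.5, 0.9],
            "s2": [0.2, 0.6, 0.8],
        },
        index=["cg1", "cg2", "cg3"],
    )
    return BetaMatrix(data)


def make_sheet(assignments, role="reference"):
    """Build a sample sheet from {sample_id: cell_type} (None -> mixture)."""
    rows = []
    for sid, ct in assignments.items():
        rows.append(
            {
                "sample_id": sid,
                "role": "mixture" if ct is None else role,
                "cell_type": ct,
                "pool_size": 1,
                "batch": "",
            }
        )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture()
def sheet_factory():
    return make_sheet
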