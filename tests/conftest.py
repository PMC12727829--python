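import numpy as np
import pandas as pd
import pytest

from silis import simulate


@pytest.fixture
def quant_df() -> pd.DataFrame:
    """A tiny well-formed long-format quantification table (3 records)."""
    return pd.DataFrame({
        "run_id": ["r1", "r1", "r2"],
        "study_id": ["s1"] * 3,
        "matrix": ["EDTA"] * 3,
        "platform_id": ["p1"] * 3,
        "sample_id": ["a", "a", "b"],
        "group": ["healthy", "healthy", "mild"],
        "protein_group": ["P1"] * 3,
        "stripped_seq": ["SPELQAEAK"] * 3,
        "modified_seq": ["SPELQAEAK"] * 3,
        "charge": [2, 2, 2],
        "channel": ["L", "H", "L"],
        "intensity": [4.0, 2.0, 6.0],
        "rt": [10.0, 10.0, 10.1],
        "fragment_id": [np.nan] * 3,
        "fragment_intensity": [np.nan] * 3,
    })


@pytest.fixture
def library_df() -> pd.DataFrame:
    """Light-channel spectral library for two peptides, b and y fragments."""
    rows = []
    for pep in ("SPELQAEAK", "AGLLDLAGR", "AEGPEVDVN"):
        for frag, mz in (("b2_1", 200.1), ("y3_1", 350.2), ("y5_2", 280.7)):
            rows.append({
                "ModifiedSequence": pep, "PrecursorCharge": 2,
                "FragmentId": frag, "FragmentMz": mz,
                "ExcludeFromAssay": False, "Channel": "L",
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pools_sim():
    """Default study-pool simulation, shared across tests (seeded)."""
    return simulate.simulate_study_pools(seed=11)


@pytest.fixture(scope="session")
def cohort_sim():
    """Default cohort simulation, shared across tests (seeded)."""
    return simulate.simulate_cohort(seed=11)
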