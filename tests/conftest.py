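import numpy as np
import pandas as pd
import pytest

from oataxia.synthdata import CohortConfig, make_toy_atlas, simulate_cohort


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas()


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort, shared across the session."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def simple_trials():
    """A small hand-built two-subject trial table (single rater)."""
    rows = []
    for subj, scores in [("s1", [0, 1, 2, 3]), ("s2", [0, 0, 0, 0])]:
        for hand in ("left", "right"):
            for space in ("left", "right"):
                for viewing in ("foveal", "peripheral"):
                    for i, s in enumerate(scores):
                        rows.append(
                            {
                                "subject_id": subj,
                                "trial_id": f"{hand[0]}{space[0]}{viewing[0]}{i}",
                                "hand": hand,
                                "space": space,
                                "viewing": viewing,
                                "raw_score": s,
                                "valid": True,
                            }
                        )
    return pd.DataFrame(rows)
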