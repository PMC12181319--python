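import numpy as np
import pandas as pd
import pytest

import cogbattery as cb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def mst_trials():
    """One deterministic MST record (study + test phases)."""
    return cb.simulate_mst(cb.MstResponderParams(), seed=42, participant_id="pA")


@pytest.fixture(scope="session")
def mst_test_trials(mst_trials):
    return mst_trials[mst_trials["task"] == "mst_test"].reset_index(drop=True)


@pytest.fixture(scope="session")
def sst_trials():
    return cb.simulate_sst(
        cb.RaceModelParams(mu=500, sigma=50, tau=100, true_ssrt_ms=250),
        seed=7,
        participant_id="pA",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Survey + trials for a small full-battery cohort (all tasks forced)."""
    cfg = cb.CohortConfig(n_infected=30, n_uninfected=20, seed=3, health_flag_p={})
    survey, trials, log = cb.simulate_cohort(
        cfg, tasks={"mst", "alertness", "corsi_fwd", "corsi_bwd", "nback",
                    "taskswitch", "gonogo", "sst"}
    )
    return survey, trials, log


def make_mst_trials_from_counts(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    """Construct an mst_test frame realizing exact response counts."""
    rows = []
    i = 0
    for (item_type, response), n in counts.items():
        for _ in range(n):
            rows.append(
                {
                    "participant_id": "pX",
                    "task": "mst_test",
                    "block": 0,
                    "trial_index": i,
                    "condition": item_type,
                    "stimulus_id": f"s{i}",
                    "response": response,
                    "correct": None,
                    "rt_ms": np.nan if response == "none" else 1000.0,
                    "ssd_ms": np.nan,
                    "participation_index": 0,
                }
            )
            i += 1
    return pd.DataFrame(rows)
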