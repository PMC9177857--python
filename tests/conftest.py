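import numpy as np
import pandas as pd
import pytest

from olfrl.task import TaskConfig, generate_trial_sequence


@pytest.fixture(scope="session")
def training_seq():
    return generate_trial_sequence(TaskConfig(seed=101))


@pytest.fixture(scope="session")
def scanner_seq():
    return generate_trial_sequence(TaskConfig(n_trials=120, seed=202))


def make_seq(cs_list, rewarded, iti=11.0):
    """Hand-built trial table for small deterministic examples."""
    n = len(cs_list)
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "cs": cs_list,
            "rewarded": [bool(r) for r in rewarded],
            "onset": 10.0 + iti * np.arange(n),
        }
    )


@pytest.fixture
def hand_seq():
    return make_seq
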