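import numpy as np
import pandas as pd
import pytest

from c1race.epochs import EpochSet
from c1race.montage import MontageMirrorMap


def build_epochs(data, channels=("O1", "O2", "Pz"), srate=500.0, tmin=-100.0,
                 table=None, **table_overrides):
    """Small EpochSet builder for unit tests."""
    data = np.asarray(data, dtype=float)
    n_trials, n_ch, n_samp = data.shape
    times = tmin + np.arange(n_samp) * 1000.0 / srate
    if table is None:
        table = pd.DataFrame({
            "participant": "P01",
            "condition": "V",
            "visual_field": "LVF",
            "visual_side": "right",
            "sound_side": "none",
            "is_target": False,
            "response_latency_ms": np.nan,
        }, index=range(n_trials))
    for col, val in table_overrides.items():
        table[col] = val
    return EpochSet(data=data, times=times, channel_names=channels,
                    trial_table=table, srate=srate)


@pytest.fixture
def small_mirror_map():
    return MontageMirrorMap(pairs=(("O1", "O2"),), midline=("Pz",))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
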