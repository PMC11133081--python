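import numpy as np
import pandas as pd
import pytest

from vocscram.audio import AudioSignal
from vocscram.synthetic import (
    SyntheticSpec,
    default_effect_spec,
    make_ratings,
    make_stimulus_set,
    stimulus_metadata,
)

SR = 22050


def tone(freq: float, duration: float = 1.0, sr: int = SR, amp: float = 1.0):
    t = np.arange(int(round(duration * sr))) / sr
    return AudioSignal(samples=amp * np.sin(2 * np.pi * freq * t), sample_rate=sr)


@pytest.fixture(scope="session")
def sine_220():
    return tone(220.0)


@pytest.fixture(scope="session")
def small_stimulus_set():
    """Six synthetic bursts (2 speakers x 3 valences) at a light sample rate."""
    spec = SyntheticSpec(n_speakers=2, sample_rate=SR, seed=11)
    return make_stimulus_set(spec)


@pytest.fixture(scope="session")
def trials_df():
    """A full-design synthetic rating dataset (60 participants)."""
    spec = SyntheticSpec(seed=1)
    # metadata only; waveforms are not needed for the rating pipeline
    meta = pd.DataFrame(
        [
            {
                "stimulus_id": sid,
                "valence_category": v,
                "speaker_sex": "female" if sid.startswith("f") else "male",
            }
            for sid in ("f45", "f46", "f53", "f58", "f60", "m6", "m42", "m55", "m59", "m61")
            for v in ("neutral", "anger", "happiness")
        ]
    )
    return make_ratings(meta, default_effect_spec(seed=7))


@pytest.fixture(scope="session")
def stimulus_meta(trials_df):
    return (
        trials_df[["stimulus_id", "valence_category"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
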