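import numpy as np
import pytest

from aad.io_preprocess import EEGRecording, Trial, Window
from aad.synthetic import SyntheticSpec, simulate_eeg


@pytest.fixture(scope="session")
def small_recording():
    """Desk-scale synthetic recording: 4 planted states, 16 channels, snr 10."""
    spec = SyntheticSpec(n_channels=16, K=4, n_trials_per_class=3,
                         trial_length_s=8.0, seed=42)
    rec, truth = simulate_eeg(spec)
    return rec, truth, spec


@pytest.fixture()
def random_recording():
    rng = np.random.default_rng(7)
    data = rng.standard_normal((6, 1024))
    return EEGRecording(
        data=data, sfreq=128.0,
        channel_names=["Fz", "Cz", "Pz", "Oz", "TP7", "TP8"],
        trials=[Trial(0, 512, "SPK1"), Trial(512, 1024, "SPK2")],
    )


def shuffle_trial_labels(fm, seed=0):
    """Permute class labels across trials (label consistency kept per trial)."""
    import pandas as pd

    from aad.features import FeatureMatrix

    rng = np.random.default_rng(seed)
    tids = fm.trial_ids.to_numpy()
    labels = fm.labels.to_numpy().copy()
    trials = pd.unique(tids)
    trial_label = {t: labels[tids == t][0] for t in trials}
    permuted = rng.permutation([trial_label[t] for t in trials])
    new_map = dict(zip(trials, permuted))
    new_labels = np.array([new_map[t] for t in tids])
    return FeatureMatrix(df=fm.df, labels=pd.Series(new_labels),
                         trial_ids=fm.trial_ids,
                         window_length_s=fm.window_length_s)


def make_window(data, sfreq=128.0, label="SPK1"):
    data = np.asarray(data, dtype=float)
    return Window(data=data, sfreq=sfreq, start_s=0.0,
                  length_s=data.shape[1] / sfreq, label=label)
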