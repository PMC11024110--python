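"""Synthetic EEG with planted microstate structure and class-dependent dynamics.

The generator emulates the statistical skeleton the attention-decoding
pipeline relies on: a small set of fixed orthonormal scalp topographies
that switch every ~60-120 ms (a semi-Markov state sequence), a half-sine
amplitude envelope per state run (so GFP peaks fall mid-state, where the
topography is cleanest), and additive Gaussian sensor noise.  The class
signal lives purely in the *dynamics*: trials where the listener attends
speaker 1 use a longer mean state duration than speaker-2 trials, so the
two classes share topographies but differ in occurrence/duration — and
hence in the recurrence structure of the GFP series.

What it does not emulate: volume-conducted 1/f background, artifacts,
inter-subject topography variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import EEGRecording, Trial

__all__ = ["SyntheticSpec", "make_templates", "simulate_eeg",
           "make_toy_series", "make_separable_features"]


@dataclass
class SyntheticSpec:
    """Study conditions for the simulated two-speaker attention experiment.

    Mean state durations straddle the 80-120 ms quasi-stability range
    reported for resting microstates; attending speaker 2 is modelled as a
    faster-switching regime.
    """

    n_channels: int = 64
    K: int = 4
    sfreq: float = 256.0
    mean_duration_ms: dict = field(
        default_factory=lambda: {"SPK1": 100.0, "SPK2": 60.0})
    duration_jitter: float = 0.25   # sd of run duration, fraction of the mean
    snr: float = 10.0               # clean-signal RMS over noise sd
    n_trials_per_class: int = 20
    trial_length_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.K > self.n_channels:
            raise ValueError("need K <= n_channels")
        min_ms = 2 / self.sfreq * 1e3
        if min(self.mean_duration_ms.values()) < min_ms:
            raise ValueError("mean duration must cover at least 2 samples")


def make_templates(K: int, n_channels: int, seed: int = 0) -> np.ndarray:
    """K orthonormal, zero-channel-mean topographies (QR of a seeded Gaussian)."""
    if K > n_channels:
        raise ValueError("need K <= n_channels")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_channels, K))
    g -= g.mean(axis=0, keepdims=True)  # zero-mean maps; QR keeps the subspace
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))  # deterministic sign convention
    return q.T  # K x n_channels


def _state_sequence(rng: np.random.Generator, n_samples: int, K: int,
                    mean_dur_samp: float, jitter: float) -> np.ndarray:
    """Semi-Markov label sequence: uniform next state != current,
    truncated-normal run durations (>= 2 samples)."""
    labels = np.empty(n_samples, dtype=np.int64)
    pos, state = 0, int(rng.integers(K))
    while pos < n_samples:
        dur = int(round(rng.normal(mean_dur_samp, jitter * mean_dur_samp)))
        dur = max(dur, 2)
        labels[pos:pos + dur] = state
        pos += dur
        nxt = int(rng.integers(K - 1))
        state = nxt if nxt < state else nxt + 1
    return labels


def simulate_eeg(spec: SyntheticSpec) -> tuple[EEGRecording, dict]:
    """Simulate the two-class attention experiment.

    Returns ``(recording, ground_truth)`` where ``ground_truth`` has
    ``state_labels`` (per-sample planted state), ``trial_classes`` and
    ``templates``.
    """
    rng = np.random.default_rng(spec.seed)
    templates = make_templates(spec.K, spec.n_channels, seed=spec.seed)
    n_trial = int(round(spec.trial_length_s * spec.sfreq))
    classes = ["SPK1", "SPK2"] * spec.n_trials_per_class

    data_parts, trials, all_labels = [], [], []
    pos = 0
    for cls in classes:
        mean_samp = spec.mean_duration_ms[cls] * 1e-3 * spec.sfreq
        labels = _state_sequence(rng, n_trial, spec.K, mean_samp,
                                 spec.duration_jitter)
        env = np.empty(n_trial)
        start = 0
        for i in range(1, n_trial + 1):
            if i == n_trial or labels[i] != labels[start]:
                t = np.arange(i - start)
                env[start:i] = np.sin(np.pi * (t + 0.5) / (i - start))
                start = i
        clean = templates[labels].T * env[None, :]  # channels x samples
        rms = np.sqrt(np.mean(clean ** 2))
        noise = rng.standard_normal(clean.shape) * (rms / spec.snr)
        data_parts.append(clean + noise)
        trials.append(Trial(pos, pos + n_trial, cls))
        all_labels.append(labels)
        pos += n_trial

    rec = EEGRecording(
        data=np.concatenate(data_parts, axis=1),
        sfreq=spec.sfreq,
        channel_names=[f"CH{i:02d}" for i in range(spec.n_channels)],
        trials=trials,
    )
    truth = {
        "state_labels": np.concatenate(all_labels),
        "trial_classes": classes,
        "templates": templates,
    }
    return rec, truth


def make_toy_series(kind: str, n: int, params: dict | None = None,
                    seed: int = 0) -> np.ndarray:
    """Small scalar test series for recurrence analysis.

    CONSTANT (``value``), PERIODIC square/sine (``period``, ``wave``),
    NOISE (seeded standard Gaussian), LOGISTIC map (``r``, ``x0``).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    params = params or {}
    kind = kind.upper()
    rng = np.random.default_rng(seed)
    if kind == "CONSTANT":
        return np.full(n, float(params.get("value", 1.0)))
    if kind == "PERIODIC":
        period = int(params.get("period", 2))
        if period < 2:
            raise ValueError("period must be >= 2")
        t = np.arange(n)
        if params.get("wave", "square") == "sine":
            return np.sin(2 * np.pi * t / period)
        return (t % period < period / 2).astype(float)
    if kind == "NOISE":
        return rng.standard_normal(n)
    if kind == "LOGISTIC":
        r = float(params.get("r", 4.0))
        if not 0 < r <= 4:
            raise ValueError("logistic r must be in (0, 4]")
        x = float(params.get("x0", 0.3))
        out = np.empty(n)
        for i in range(n):
            out[i] = x
            x = r * x * (1 - x)
        return out
    raise ValueError(f"unknown toy-series kind {kind!r}")


def make_separable_features(n_per_class: int, dim: int = 8,
                            separation_sd: float = 4.0, seed: int = 0,
                            trial_size: int = 10):
    """Two Gaussian classes separated by ``separation_sd``·σ along a random
    direction; rows are grouped into pseudo-trials for trial-level splits.

    Returns a :class:`aad.features.FeatureMatrix`.
    """
    from .features import FeatureMatrix

    if n_per_class < 10:
        raise ValueError("need n_per_class >= 10")
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(dim)
    direction /= np.linalg.norm(direction)
    x1 = rng.standard_normal((n_per_class, dim))
    x2 = rng.standard_normal((n_per_class, dim)) + separation_sd * direction
    x = np.vstack([x1, x2])
    labels = np.array(["SPK1"] * n_per_class + ["SPK2"] * n_per_class)
    trial_ids = np.concatenate([
        np.arange(n_per_class) // trial_size,
        1000 + np.arange(n_per_class) // trial_size,
    ])
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(dim)])
    return FeatureMatrix(df=df, labels=pd.Series(labels),
                         trial_ids=pd.Series(trial_ids), window_length_s=1.0)
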