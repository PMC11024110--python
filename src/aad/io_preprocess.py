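"""Reading EEG recordings and the standard preprocessing chain.

The pipeline mirrors common practice for scalp EEG prior to microstate
analysis: resample to a common rate (256 Hz), zero-phase FIR band-pass
0.5-70 Hz, and re-reference to the average of two mastoid-adjacent
electrodes (TP7/TP8).  Trials carry an attended-speaker label
(``SPK1``/``SPK2``) used downstream for attention decoding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "Trial",
    "EEGRecording",
    "Window",
    "load_recording",
    "save_npz",
    "resample",
    "bandpass_filter",
    "rereference",
    "segment_windows",
    "reject_artifact_windows",
]

#: Valid attended-speaker labels.
LABELS = ("SPK1", "SPK2", "NONE")


@dataclass(frozen=True)
class Trial:
    """Half-open sample interval ``[start, end)`` with an attended label."""

    start: int
    end: int
    label: str = "NONE"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown trial label {self.label!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("trial interval must satisfy 0 <= start < end")


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples, in microvolts."""

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal n_channels")
        prev_end = None
        for t in self.trials:
            if t.end > self.n_samples:
                raise ValueError("trial extends past the recording")
            if prev_end is not None and t.start < prev_end:
                raise ValueError("trials must be non-overlapping and ordered")
            prev_end = t.end
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN/Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class Window:
    """A fixed-length analysis segment cut from one trial."""

    data: np.ndarray
    sfreq: float
    start_s: float
    length_s: float
    label: str = "NONE"
    trial_index: int = 0

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# readers / writers

def _read_sidecar(path: Path, sfreq: float) -> list[Trial]:
    with open(path) as fh:
        entries = json.load(fh)
    trials = []
    for e in entries:
        trials.append(
            Trial(
                start=int(round(e["start_s"] * sfreq)),
                end=int(round(e["end_s"] * sfreq)),
                label=e.get("label", "NONE"),
            )
        )
    return trials


def load_recording(path: str | Path, fmt: str | None = None,
                   labels: str | Path | None = None) -> EEGRecording:
    """Load an EEG recording from EDF, BDF, FIF or the internal NPZ bundle.

    ``fmt`` defaults to the file extension.  Trial labels are taken from a
    JSON sidecar (list of ``{start_s, end_s, label}``); if ``labels`` is not
    given, ``<path>.labels.json`` is tried.  Without a sidecar the recording
    is returned with a single all-``NONE`` trial spanning the data and a
    warning is emitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt == "NPZ":
        with np.load(path, allow_pickle=False) as npz:
            data = npz["data"]
            sfreq = float(npz["sfreq"])
            names = [str(c) for c in npz["channel_names"]]
            trials = []
            if "trial_bounds" in npz:
                bounds = npz["trial_bounds"]
                tl = [str(x) for x in npz["trial_labels"]]
                trials = [Trial(int(s), int(e), lab)
                          for (s, e), lab in zip(bounds, tl)]
    elif fmt in ("EDF", "BDF", "FIF"):
        import mne

        try:
            if fmt == "EDF":
                raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            elif fmt == "BDF":
                raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
            else:
                raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        except Exception as exc:  # noqa: BLE001 - normalize reader errors
            raise IOError(f"could not parse {path} as {fmt}: {exc}") from exc
        data = raw.get_data() * 1e6  # volts -> microvolts
        sfreq = float(raw.info["sfreq"])
        names = list(raw.ch_names)
        trials = []
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    sidecar = Path(labels) if labels else path.with_suffix(path.suffix + ".labels.json")
    if sidecar.exists():
        trials = _read_sidecar(sidecar, sfreq)
    if not trials:
        warnings.warn(f"no trial labels for {path.name}; labelling all NONE")
        trials = [Trial(0, data.shape[1], "NONE")]
    return EEGRecording(data=data, sfreq=sfreq, channel_names=names, trials=trials)


def save_npz(rec: EEGRecording, path: str | Path) -> None:
    """Write the internal NPZ bundle (round-trips through load_recording)."""
    np.savez(
        Path(path),
        data=rec.data,
        sfreq=rec.sfreq,
        channel_names=np.array(rec.channel_names),
        trial_bounds=np.array([[t.start, t.end] for t in rec.trials], dtype=np.int64),
        trial_labels=np.array([t.label for t in rec.trials]),
    )


# ---------------------------------------------------------------------------
# preprocessing

def resample(rec: EEGRecording, target_sfreq: float) -> EEGRecording:
    """Polyphase resampling to ``target_sfreq`` (anti-aliased on the way down)."""
    if target_sfreq <= 0:
        raise ValueError("target_sfreq must be positive")
    if target_sfreq == rec.sfreq:
        return replace(rec, data=rec.data.copy())
    ratio = Fraction(target_sfreq / rec.sfreq).limit_denominator(1000)
    data = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    scale = target_sfreq / rec.sfreq
    n_new = data.shape[1]
    trials = [
        Trial(min(int(round(t.start * scale)), n_new - 1),
              min(int(round(t.end * scale)), n_new), t.label)
        for t in rec.trials
    ]
    return EEGRecording(data=data, sfreq=target_sfreq,
                        channel_names=list(rec.channel_names), trials=trials)


def _fir_taps(lo: float, hi: float, sfreq: float, n_samples: int) -> np.ndarray:
    # Hamming-window FIR; order set by the narrower transition band
    # (25% of the edge, floored at 2 Hz, capped at the edge itself).
    l_trans = min(max(0.25 * lo, 2.0), lo)
    h_trans = min(max(0.25 * hi, 2.0), sfreq / 2 - hi)
    trans = min(l_trans, h_trans)
    numtaps = int(np.ceil(3.3 / (trans / sfreq)))
    # never let the filter outgrow the data it is applied to
    numtaps = min(numtaps, max(3, n_samples // 3))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=sfreq)


def bandpass_filter(rec: EEGRecording, lo: float = 0.5, hi: float = 70.0) -> EEGRecording:
    """Zero-phase FIR band-pass; channel means are removed first."""
    nyq = rec.sfreq / 2
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"hi={hi} must be below the Nyquist rate {nyq}")
    taps = _fir_taps(lo, hi, rec.sfreq, rec.n_samples)
    demeaned = rec.data - rec.data.mean(axis=1, keepdims=True)
    padlen = min(3 * len(taps), rec.n_samples - 1)
    data = signal.filtfilt(taps, [1.0], demeaned, axis=1, padlen=padlen)
    return replace(rec, data=data)


def rereference(rec: EEGRecording, ref_channels: tuple[str, ...] = ("TP7", "TP8")) -> EEGRecording:
    """Subtract the mean of ``ref_channels`` from every channel, per sample."""
    try:
        idx = [rec.channel_names.index(c) for c in ref_channels]
    except ValueError as exc:
        raise KeyError(f"reference channel not found: {exc}") from exc
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    return replace(rec, data=rec.data - ref)


def segment_windows(rec: EEGRecording, length_s: float, overlap: float = 0.0) -> list[Window]:
    """Tile each trial with fixed-length windows (never across trial edges).

    Trailing partial windows are dropped; each window inherits its trial's
    attended label.  ``overlap`` is the fraction shared by adjacent windows.
    """
    win = int(round(length_s * rec.sfreq))
    if win < 2:
        raise ValueError("window must cover at least 2 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(win * (1 - overlap))))
    out: list[Window] = []
    for ti, t in enumerate(rec.trials):
        if t.end - t.start < win:
            warnings.warn(
                f"trial [{t.start},{t.end}) shorter than {length_s}s window; skipped")
            continue
        for start in range(t.start, t.end - win + 1, step):
            out.append(
                Window(
                    data=rec.data[:, start:start + win],
                    sfreq=rec.sfreq,
                    start_s=start / rec.sfreq,
                    length_s=win / rec.sfreq,
                    label=t.label,
                    trial_index=ti,
                )
            )
    return out


def reject_artifact_windows(windows: list[Window],
                            threshold_uv: float = 100.0) -> list[Window]:
    """Drop windows whose peak absolute amplitude exceeds ``threshold_uv``.

    A deterministic, automatable proxy for manual artifact screening
    (blinks, movement); not applied by default anywhere in the pipeline.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    kept = [w for w in windows if np.abs(w.data).max() <= threshold_uv]
    if len(kept) < len(windows):
        warnings.warn(f"rejected {len(windows) - len(kept)} windows above "
                      f"{threshold_uv} uV")
    return kept
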