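"""Filtering, channel selection and epoching of continuous EEG recordings.

All filters are applied forward-backward (zero phase).  Epoching is pure
slicing: sample values are preserved bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

CLASS_NAMES: tuple[str, ...] = ("left_hand", "right_hand", "feet", "tongue")
CANONICAL_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4")
DEFAULT_FS = 250.0
TRIAL_SAMPLES = 500

__all__ = [
    "CLASS_NAMES",
    "CANONICAL_CHANNELS",
    "DEFAULT_FS",
    "TRIAL_SAMPLES",
    "Recording",
    "TrialSet",
    "notch_filter",
    "bandpass_filter",
    "select_channels",
    "epoch",
    "concat_trialsets",
]


@dataclass
class Recording:
    """Continuous multichannel signal (µV) with event markers."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float = DEFAULT_FS
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS
    events: list[tuple[int, int]] = field(default_factory=list)  # (onset_sample, label)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")


@dataclass
class TrialSet:
    """Epoched trials: (n, 3, 500) tensor with labels and domain ids.

    Channels are in canonical order (C3, Cz, C4); labels index
    :data:`CLASS_NAMES`; ``domain_ids`` identify the session or subject each
    trial came from.
    """

    trials: np.ndarray  # (n, 3, TRIAL_SAMPLES)
    labels: np.ndarray  # (n,) ints in [0, 4)
    domain_ids: np.ndarray  # (n,) ints
    runs: np.ndarray | None = None  # (n,) run index within session
    fs: float = DEFAULT_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.domain_ids = np.asarray(self.domain_ids, dtype=np.int64)
        if self.trials.ndim != 3 or self.trials.shape[1] != 3:
            raise ValueError("trials must have shape (n, 3, n_samples)")
        if self.trials.shape[2] != TRIAL_SAMPLES:
            raise ValueError(f"trial length must be {TRIAL_SAMPLES} samples")
        n = self.trials.shape[0]
        if self.labels.shape != (n,) or self.domain_ids.shape != (n,):
            raise ValueError("labels/domain_ids must align with trials")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(CLASS_NAMES)):
            raise ValueError("labels must be in the 4-class set")
        if self.runs is not None:
            self.runs = np.asarray(self.runs, dtype=np.int64)

    def __len__(self) -> int:
        return self.trials.shape[0]

    def subset(self, idx: np.ndarray) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(
            trials=self.trials[idx],
            labels=self.labels[idx],
            domain_ids=self.domain_ids[idx],
            runs=None if self.runs is None else self.runs[idx],
            fs=self.fs,
            meta=dict(self.meta),
        )


def concat_trialsets(sets: list[TrialSet]) -> TrialSet:
    if not sets:
        raise ValueError("no trial sets to concatenate")
    runs = None
    if all(s.runs is not None for s in sets):
        runs = np.concatenate([s.runs for s in sets])
    return TrialSet(
        trials=np.concatenate([s.trials for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        domain_ids=np.concatenate([s.domain_ids for s in sets]),
        runs=runs,
        fs=sets[0].fs,
        meta={"concatenated": len(sets)},
    )


def notch_filter(rec: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at ``freq`` Hz (line-noise suppression)."""
    if not 0 < freq < rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz must lie in (0, {rec.fs / 2}) Hz")
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return replace(rec, data=out)


def bandpass_filter(rec: Recording, lo: float = 7.0, hi: float = 30.0, order: int = 4) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (default 7-30 Hz)."""
    if not 0 < lo < hi < rec.fs / 2:
        raise ValueError(f"invalid band ({lo}, {hi}) Hz for fs={rec.fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def select_channels(rec: Recording, names: tuple[str, ...] = CANONICAL_CHANNELS) -> Recording:
    """Pick channels by name, reordering into the requested (canonical) order."""
    missing = [n for n in names if n not in rec.channel_names]
    if missing:
        raise KeyError(f"missing channel(s): {', '.join(missing)}")
    idx = [rec.channel_names.index(n) for n in names]
    return replace(rec, data=rec.data[idx], channel_names=tuple(names))


def epoch(rec: Recording, offset_s: float = 0.5, length: int = TRIAL_SAMPLES) -> TrialSet:
    """Slice one trial per event: window [onset + offset, onset + offset + length).

    Sample indexing is 0-based and windows are half-open.
    """
    if rec.data.shape[0] != 3:
        raise ValueError("recording must have exactly the 3 canonical channels; "
                         "apply select_channels first")
    offset = int(round(offset_s * rec.fs))
    n_samples = rec.data.shape[1]
    trials, labels = [], []
    for k, (onset, label) in enumerate(rec.events):
        start = onset + offset
        stop = start + length
        if start < 0 or stop > n_samples:
            raise IndexError(
                f"event {k} (onset {onset}): window [{start}, {stop}) exceeds recording "
                f"of {n_samples} samples"
            )
        trials.append(rec.data[:, start:stop])
        labels.append(label)
    n = len(trials)
    domain = int(rec.meta.get("domain_id", 0))
    return TrialSet(
        trials=np.asarray(trials).reshape(n, 3, length),
        labels=np.asarray(labels, dtype=np.int64),
        domain_ids=np.full(n, domain, dtype=np.int64),
        fs=rec.fs,
        meta=dict(rec.meta),
    )
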