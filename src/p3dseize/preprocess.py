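"""Filtering, windowing, SPH labeling and class balancing.

Labeling convention: a 6-s window is *positive* (preictal) when it lies
entirely inside the seizure prediction horizon, 15 down to 5 minutes before
an onset; *negative* (interictal) when its whole extent is at least
15 minutes away from every onset. Windows in neither zone — ictal data, the
last 5 minutes before onset, and anything straddling a boundary — are
discarded so every retained window is homogeneous in label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synth import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelSpec:
    """SPH labeling geometry, in seconds relative to seizure onset."""

    sph_pre_start_s: float = 900.0
    sph_pre_end_s: float = 300.0
    negative_exclusion_s: float = 900.0
    window_len_s: float = 6.0
    step_len_s: float = 3.0

    def __post_init__(self):
        if not (self.sph_pre_start_s > self.sph_pre_end_s >= 0):
            raise ValueError("require sph_pre_start_s > sph_pre_end_s >= 0")
        if self.window_len_s != 2 * self.step_len_s:
            raise ValueError("window_len_s must equal 2 * step_len_s")


@dataclass
class WindowSet:
    """Labeled, non-overlapping windows pooled across recordings."""

    windows: np.ndarray  # (n, channels, window_samples)
    labels: np.ndarray  # (n,) in {0, 1}; 1 = preictal/SPH
    start_times_s: np.ndarray  # (n,)
    subject_ids: np.ndarray  # (n,) str
    fs: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.start_times_s = np.asarray(self.start_times_s, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.windows.shape[0]

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.windows[idx], self.labels[idx], self.start_times_s[idx],
            self.subject_ids[idx], self.fs, self.channel_names,
        )


def bandpass_filter(
    recording: Recording,
    low_hz: float = 0.5,
    high_hz: float = 75.0,
    order: int = 4,
    notch_hz: float | None = None,
) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward (``sosfiltfilt``) so window boundaries suffer no group
    delay. ``notch_hz`` optionally adds a powerline notch (off by default).
    """
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyq} Hz (fs={recording.fs} Hz)"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.fs,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, recording.signal, axis=1)
    if notch_hz is not None:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=recording.fs)
        filtered = sps.filtfilt(b, a, filtered, axis=1)
    return replace(recording, signal=filtered)


def label_windows(recording: Recording, spec: LabelSpec = LabelSpec()) -> WindowSet:
    """Tile the recording with non-overlapping windows and assign SPH labels."""
    wlen = int(round(spec.window_len_s * recording.fs))
    if wlen % 2:
        raise ValueError("window length must be an even number of samples")
    n_windows = recording.n_samples // wlen

    kept, labels, starts = [], [], []
    for w in range(n_windows):
        t0 = w * spec.window_len_s
        t1 = t0 + spec.window_len_s
        positive = any(
            (onset - spec.sph_pre_start_s) <= t0 and t1 <= (onset - spec.sph_pre_end_s)
            for onset in recording.onsets_s
        )
        negative = all(
            t1 <= onset - spec.negative_exclusion_s
            or t0 >= onset + spec.negative_exclusion_s
            for onset in recording.onsets_s
        )
        if positive:
            kept.append(w)
            labels.append(1)
            starts.append(t0)
        elif negative:
            kept.append(w)
            labels.append(0)
            starts.append(t0)

    if kept:
        windows = np.stack(
            [recording.signal[:, w * wlen:(w + 1) * wlen] for w in kept]
        )
    else:
        windows = np.empty((0, recording.signal.shape[0], wlen))
    return WindowSet(
        windows=windows,
        labels=np.array(labels, dtype=np.int64),
        start_times_s=np.array(starts, dtype=np.float64),
        subject_ids=np.array([recording.subject_id] * len(kept), dtype=object),
        fs=recording.fs,
        channel_names=recording.channel_names,
    )


def concatenate_window_sets(sets: list[WindowSet]) -> WindowSet:
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no non-empty window sets to concatenate")
    fs = sets[0].fs
    names = sets[0].channel_names
    if any(s.fs != fs or s.channel_names != names for s in sets):
        raise ValueError("window sets differ in fs or channel names")
    return WindowSet(
        np.concatenate([s.windows for s in sets]),
        np.concatenate([s.labels for s in sets]),
        np.concatenate([s.start_times_s for s in sets]),
        np.concatenate([s.subject_ids for s in sets]),
        fs, names,
    )


def balance_classes(ws: WindowSet, seed: int = 0) -> WindowSet:
    """Subsample the majority class to a 1:1 ratio, seeded, without replacement.

    The subsample is allocated across subjects proportionally to each
    subject's share of the majority class (largest-remainder rounding), so
    per-subject balance is preserved when possible.
    """
    n_pos = int((ws.labels == 1).sum())
    n_neg = int((ws.labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        return ws

    rng = np.random.default_rng(seed)
    majority = 1 if n_pos > n_neg else 0
    target = min(n_pos, n_neg)
    maj_idx = np.flatnonzero(ws.labels == majority)

    subjects = np.asarray([str(s) for s in ws.subject_ids[maj_idx]])
    uniq = sorted(set(subjects))
    counts = np.array([(subjects == s).sum() for s in uniq], dtype=float)
    quota = counts / counts.sum() * target
    alloc = np.floor(quota).astype(int)
    remainder = target - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    for i in order[:remainder]:
        alloc[i] += 1

    chosen = []
    for s, k in zip(uniq, alloc):
        pool = maj_idx[subjects == s]
        chosen.append(rng.choice(pool, size=min(k, len(pool)), replace=False))
    chosen = np.concatenate(chosen)
    keep = np.sort(np.concatenate([np.flatnonzero(ws.labels != majority), chosen]))
    return ws.subset(keep)


def split_steps(ws: WindowSet) -> np.ndarray:
    """View each window as two consecutive steps: (n, 2, channels, step_samples)."""
    n, c, s = ws.windows.shape
    if s % 2:
        raise ValueError("window sample count must be even to split into two steps")
    return ws.windows.reshape(n, c, 2, s // 2).swapaxes(1, 2)
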