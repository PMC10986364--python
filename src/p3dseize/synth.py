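"""Synthetic multichannel scalp EEG with seizure annotations.

Real preictal EEG tends to show reduced signal complexity relative to
interictal baseline — the property the nonlinear features downstream are
designed to pick up. The generator emulates exactly that statistical
structure: each regime is a sinusoidal rhythm plus 1/f^alpha colored noise,
with the preictal regime rhythm-dominated (low complexity) and the
interictal regime noise-dominated (high complexity). Everything else about
real EEG (seizure morphology, artifacts, nonstationarity) is out of scope.

The preictal regime occupies the seizure prediction horizon: 15 down to
5 minutes before each annotated onset. Regime transitions are joined by a
short linear cross-fade so the signal has no step discontinuities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: The 23 referential electrode labels used throughout (10-20 system).
CHB_CHANNELS = (
    "AF7", "AF3", "AF4", "AF8", "FT9", "FT7", "FC3", "FCz", "FC4", "FT8",
    "FT10", "T7", "T8", "TP7", "CP3", "CPz", "CP4", "TP8", "P8", "PO7",
    "PO3", "PO4", "PO8",
)

#: Preictal zone relative to onset, seconds: [onset-900, onset-300).
SPH_PRE_START_S = 900.0
SPH_PRE_END_S = 300.0


@dataclass(frozen=True)
class RegimeDynamics:
    """Spectral recipe for one brain state.

    sine_amp and noise_amp are in µV; noise_color_exponent is the alpha of
    the 1/f^alpha noise power shaping (0 = white).
    """

    sine_freq_hz: float = 10.0
    sine_amp: float = 10.0
    noise_amp: float = 20.0
    noise_color_exponent: float = 1.0

    def validate(self) -> None:
        if self.sine_amp < 0 or self.noise_amp < 0:
            raise ValueError("dynamics amplitudes must be non-negative")
        if self.sine_freq_hz < 0:
            raise ValueError("sine_freq_hz must be non-negative")


#: Interictal baseline: weak alpha rhythm buried in strong pink noise.
DEFAULT_INTERICTAL = RegimeDynamics(
    sine_freq_hz=10.0, sine_amp=10.0, noise_amp=20.0, noise_color_exponent=1.0
)
#: Preictal: strong rhythm, weak whiter noise — lower-complexity signal.
DEFAULT_PREICTAL = RegimeDynamics(
    sine_freq_hz=10.0, sine_amp=30.0, noise_amp=6.0, noise_color_exponent=0.5
)


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic recording; output is a pure function of it."""

    n_channels: int = 23
    channel_names: tuple[str, ...] = CHB_CHANNELS
    fs: float = 256.0
    duration_s: float = 3600.0
    seizure_onsets_s: tuple[float, ...] = ()
    interictal_dynamics: RegimeDynamics = DEFAULT_INTERICTAL
    preictal_dynamics: RegimeDynamics = DEFAULT_PREICTAL
    crossfade_s: float = 2.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "seizure_onsets_s", tuple(self.seizure_onsets_s))
        if self.n_channels != len(self.channel_names):
            raise ValueError(
                f"n_channels={self.n_channels} != len(channel_names)="
                f"{len(self.channel_names)}"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s < 0:
            raise ValueError("duration_s must be non-negative")
        for t in self.seizure_onsets_s:
            if not (0 <= t <= self.duration_s):
                raise ValueError(f"onset {t} s outside [0, {self.duration_s}] s")
        if self.crossfade_s < 0:
            raise ValueError("crossfade_s must be non-negative")
        self.interictal_dynamics.validate()
        self.preictal_dynamics.validate()


@dataclass
class Recording:
    """Multichannel signal (µV) with channel names, rate and onset annotations."""

    signal: np.ndarray  # (channels, samples)
    channel_names: tuple[str, ...]
    fs: float
    onsets_s: tuple[float, ...] = ()
    subject_id: str = "S000"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        self.onsets_s = tuple(sorted(self.onsets_s))
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError("signal row count must equal number of channel names")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _colored_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    if alpha == 0 or n < 4:
        out = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        gain = np.zeros_like(freqs)
        gain[1:] = freqs[1:] ** (-alpha / 2.0)  # DC removed
        out = np.fft.irfft(spec * gain, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _regime_weight(config: SynthConfig) -> np.ndarray:
    """Per-sample preictal weight in [0, 1] with linear cross-fades at zone edges."""
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    w = np.zeros(n)
    for onset in config.seizure_onsets_s:
        start = onset - SPH_PRE_START_S
        end = onset - SPH_PRE_END_S
        if onset < SPH_PRE_START_S:
            logger.warning(
                "onset at %.1f s is closer than %.0f s to recording start; "
                "preictal span truncated",
                onset, SPH_PRE_START_S,
            )
            start = max(start, 0.0)
        if end <= 0:
            continue
        zone = np.clip(
            np.minimum(t - start, end - t) / max(config.crossfade_s, 1.0 / config.fs),
            0.0, 1.0,
        )
        w = np.maximum(w, zone)
    return w


def generate_recording(config: SynthConfig, subject_id: str = "S000") -> Recording:
    """Synthesize one recording under the regime plan implied by the onsets.

    Samples inside [onset-900 s, onset-300 s) follow ``preictal_dynamics``;
    everything else follows ``interictal_dynamics`` (the zones the labeler
    later discards are interictal-shaped, which is irrelevant downstream).
    Channel amplitudes are jittered by a seeded per-channel gain in [0.8, 1.2].
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    w = _regime_weight(config)

    gains = rng.uniform(0.8, 1.2, size=config.n_channels)
    signal = np.empty((config.n_channels, n))
    di, dp = config.interictal_dynamics, config.preictal_dynamics
    for c in range(config.n_channels):
        phase_i, phase_p = rng.uniform(0, 2 * np.pi, size=2)
        s_inter = di.sine_amp * np.sin(2 * np.pi * di.sine_freq_hz * t + phase_i)
        s_inter += di.noise_amp * _colored_noise(rng, n, di.noise_color_exponent)
        s_pre = dp.sine_amp * np.sin(2 * np.pi * dp.sine_freq_hz * t + phase_p)
        s_pre += dp.noise_amp * _colored_noise(rng, n, dp.noise_color_exponent)
        signal[c] = gains[c] * ((1.0 - w) * s_inter + w * s_pre)

    return Recording(
        signal=signal,
        channel_names=config.channel_names,
        fs=config.fs,
        onsets_s=config.seizure_onsets_s,
        subject_id=subject_id,
    )


def generate_dataset(config: SynthConfig, n_recordings: int) -> list[Recording]:
    """Independent recordings with seeds ``config.seed + i`` and unique subject ids."""
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    out = []
    for i in range(n_recordings):
        cfg_i = replace(config, seed=config.seed + i)
        out.append(generate_recording(cfg_i, subject_id=f"S{i:03d}"))
    return out
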