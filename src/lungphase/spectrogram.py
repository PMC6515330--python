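"""Cropped log-magnitude spectrograms of lung-sound recordings.

Recordings are converted to a time-frequency image: short-time Fourier
transform with a 4096-sample Hann window and 3200-sample overlap at
44,100 Hz, magnitudes in dB relative to the file maximum with a -80 dB
floor, and all bins at or above 2000 Hz discarded (chest-wall lung sounds
carry essentially no energy above that).  The image convention (single
channel replicated to three, low frequencies at the bottom) matches what
image-based object detectors consume.

Frames are taken without padding: the first window starts at sample 0, so
a signal of N samples yields floor((N - 4096)/896) + 1 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import signal

__all__ = [
    "SpectrogramParams",
    "SpectrogramImage",
    "compute_spectrogram",
    "to_image",
    "time_to_column",
    "column_to_time",
    "load_wav",
]


@dataclass(frozen=True)
class SpectrogramParams:
    sample_rate: float = 44100.0
    segment_length: int = 4096
    overlap: int = 3200
    max_frequency: float = 2000.0
    log_floor_db: float = -80.0
    window: str = "hann"

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.segment_length:
            raise ValueError("need 0 < overlap < segment_length")
        if not 0 < self.max_frequency <= self.sample_rate / 2:
            raise ValueError("need 0 < max_frequency <= Nyquist")

    @property
    def hop(self) -> int:
        return self.segment_length - self.overlap

    def n_frames(self, n_samples: int) -> int:
        """Closed-form column count for an n-sample signal."""
        if n_samples < self.segment_length:
            raise ValueError("signal shorter than one segment")
        return (n_samples - self.segment_length) // self.hop + 1


@dataclass(frozen=True)
class SpectrogramImage:
    """Log-magnitude matrix (rows = frequency low→high, columns = time
    frames) with axis metadata."""

    values: np.ndarray
    frame_times: np.ndarray
    bin_frequencies: np.ndarray
    params: SpectrogramParams = field(default_factory=SpectrogramParams)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def compute_spectrogram(
    waveform: np.ndarray, params: SpectrogramParams | None = None
) -> SpectrogramImage:
    """Magnitude STFT, cropped below ``max_frequency``, in dB re file max.

    The dB conversion is relative to the largest magnitude in the retained
    band and clipped at ``log_floor_db``, giving values in
    [log_floor_db, 0] regardless of absolute recording level.
    """
    params = params or SpectrogramParams()
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim == 2:  # stereo: average channels
        x = x.mean(axis=1)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D) or stereo (2-D)")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    if x.size < params.segment_length:
        raise ValueError(
            f"waveform of {x.size} samples shorter than one "
            f"{params.segment_length}-sample segment"
        )
    freqs, times, zxx = signal.stft(
        x,
        fs=params.sample_rate,
        window=params.window,
        nperseg=params.segment_length,
        noverlap=params.overlap,
        boundary=None,
        padded=False,
    )
    keep = freqs < params.max_frequency
    mag = np.abs(zxx[keep, :])
    ref = mag.max()
    if ref == 0.0:
        db = np.full_like(mag, params.log_floor_db)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mag / ref)
        db = np.maximum(db, params.log_floor_db)
    return SpectrogramImage(
        values=db,
        frame_times=times,
        bin_frequencies=freqs[keep],
        params=params,
    )


def to_image(spec: SpectrogramImage, path) -> None:
    """Write an 8-bit RGB PNG: min-max scaled to 0-255, one channel
    replicated into three, low frequencies at the bottom.  A constant
    spectrogram (zero dynamic range) maps to 0."""
    v = spec.values
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        scaled = np.round((v - lo) / (hi - lo) * 255.0).astype(np.uint8)
    else:
        scaled = np.zeros_like(v, dtype=np.uint8)
    rgb = np.repeat(np.flipud(scaled)[:, :, None], 3, axis=2)
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")


def column_to_time(spec: SpectrogramImage, c: int) -> float:
    """Center time of frame ``c``: (c*hop + segment_length/2) / sample_rate."""
    if not 0 <= c < spec.n_columns:
        raise ValueError(f"column {c} outside [0, {spec.n_columns})")
    p = spec.params
    return (c * p.hop + p.segment_length / 2) / p.sample_rate


def time_to_column(spec: SpectrogramImage, t: float) -> int:
    """Nearest frame column to time ``t`` seconds, clamped to valid range."""
    p = spec.params
    duration = (
        (spec.n_columns - 1) * p.hop + p.segment_length
    ) / p.sample_rate
    if not 0 <= t <= duration:
        raise ValueError(f"time {t} outside [0, {duration}]")
    c = round((t * p.sample_rate - p.segment_length / 2) / p.hop)
    return int(min(max(c, 0), spec.n_columns - 1))


def load_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file to float64 in [-1, 1]; stereo is downmixed by
    averaging.  Returns (waveform, sample_rate)."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    x = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        x /= float(np.iinfo(data.dtype).max)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return x, float(rate)
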