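"""Baseline breathing-phase detector.

The pipeline's detector stage is a contract: any callable mapping a
waveform to an :class:`~lungphase.annotations.AnnotationSet` whose
intervals all carry confidences in [0, 1] can be plugged in (e.g. an
image-based object detector running on the spectrogram representation).

This module ships a deliberately simple non-learned implementation of
that contract so the full chain — audio → detections → post-processing →
agreement evaluation — can be exercised end to end.  It band-passes the
signal to the lung-sound band, computes a smoothed RMS energy envelope,
segments it by hysteresis thresholding, and labels candidates by
alternation with the louder member of each adjacent pair taken as
inspiration (chest-wall expiration is quieter, sometimes nearly silent).
Confidence is the candidate's mean envelope relative to the file's peak
envelope, on a square-root-compressed scale so that clearly audible but
quiet phases are not scored as near-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .annotations import EXPIRATION, INSPIRATION, AnnotationSet, PhaseInterval

__all__ = ["DetectorConfig", "baseline_energy_detector", "energy_envelope"]


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds of the baseline energy detector.

    ``on_fraction``/``off_fraction`` are hysteresis thresholds relative to
    the file's peak envelope: a candidate opens when the envelope rises
    above on_fraction and closes when it falls below off_fraction.
    """

    band_low_hz: float = 100.0
    band_high_hz: float = 1500.0
    smooth_window_s: float = 0.15
    on_fraction: float = 0.18
    off_fraction: float = 0.10
    min_phase_s: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if not 0 < self.off_fraction <= self.on_fraction < 1:
            raise ValueError("need 0 < off_fraction <= on_fraction < 1")


def energy_envelope(
    waveform: np.ndarray, sample_rate: float, config: DetectorConfig | None = None
) -> np.ndarray:
    """Band-passed RMS envelope, smoothed over ``smooth_window_s``."""
    config = config or DetectorConfig()
    x = np.asarray(waveform, dtype=np.float64)
    nyq = sample_rate / 2.0
    high = min(config.band_high_hz, 0.95 * nyq)
    sos = signal.butter(
        4, [config.band_low_hz / nyq, high / nyq], btype="bandpass", output="sos"
    )
    y = signal.sosfiltfilt(sos, x)
    win = max(int(round(config.smooth_window_s * sample_rate)), 1)
    power = uniform_filter1d(y * y, size=win, mode="constant")
    return np.sqrt(np.maximum(power, 0.0))


def _hysteresis_segments(env: np.ndarray, on: float, off: float) -> list[tuple[int, int]]:
    """[start, end) sample index runs where env crosses on and stays above off."""
    segments = []
    active = False
    start = 0
    for i, v in enumerate(env):
        if not active and v >= on:
            active = True
            # walk back to where the envelope last rose above the off level
            j = i
            while j > 0 and env[j - 1] >= off:
                j -= 1
            start = j
        elif active and v < off:
            active = False
            segments.append((start, i))
    if active:
        segments.append((start, len(env)))
    # walking back can make a segment reach into the previous one; merge
    merged: list[tuple[int, int]] = []
    for s, e in segments:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def baseline_energy_detector(
    waveform: np.ndarray,
    sample_rate: float,
    config: DetectorConfig | None = None,
    *,
    recording_id: str = "recording",
    source_id: str = "baseline-detector",
) -> AnnotationSet:
    """Detect breathing-phase candidates from the energy envelope.

    Silent (all-zero) input yields an empty annotation set.  Deterministic:
    no randomness anywhere in the chain.
    """
    config = config or DetectorConfig()
    x = np.asarray(waveform, dtype=np.float64)
    if x.size < sample_rate:
        raise ValueError("waveform must be at least 1 s long")
    duration = x.size / sample_rate
    if not np.any(x):
        return AnnotationSet(recording_id, duration, source_id, ())

    env = energy_envelope(x, sample_rate, config)
    peak = env.max()
    if peak <= 0:
        return AnnotationSet(recording_id, duration, source_id, ())
    segments = _hysteresis_segments(
        env, on=config.on_fraction * peak, off=config.off_fraction * peak
    )
    min_len = int(round(config.min_phase_s * sample_rate))
    segments = [(s, e) for s, e in segments if e - s >= min_len]
    if not segments:
        return AnnotationSet(recording_id, duration, source_id, ())

    means = np.array([env[s:e].mean() for s, e in segments])
    labels = _alternation_labels(means)
    intervals = []
    for (s, e), mean, label in zip(segments, means, labels):
        conf = float(np.sqrt(np.clip(mean / peak, 0.0, 1.0)))
        intervals.append(
            PhaseInterval(s / sample_rate, min(e / sample_rate, duration), label, conf)
        )
    return AnnotationSet(recording_id, duration, source_id, tuple(intervals))


def _alternation_labels(means: np.ndarray) -> list[str]:
    """Label candidates assuming inspiration/expiration alternation:
    within each adjacent pair the louder member is inspiration; a trailing
    unpaired candidate continues the alternation."""
    labels: list[str] = []
    n = len(means)
    for k in range(0, n - 1, 2):
        if means[k] >= means[k + 1]:
            labels += [INSPIRATION, EXPIRATION]
        else:
            labels += [EXPIRATION, INSPIRATION]
    if len(labels) < n:  # odd count
        if labels:
            labels.append(
                INSPIRATION if labels[-1] == EXPIRATION else EXPIRATION
            )
        else:
            labels.append(INSPIRATION)
    return labels
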