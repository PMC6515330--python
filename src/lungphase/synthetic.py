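"""Synthetic lung-sound recordings with ground-truth phase annotations.

Real chest-wall lung sound is band-limited noise-like turbulence whose
level follows the breathing cycle: inspiration is loud, expiration quieter
(sometimes nearly silent), with short silent pauses between phases.  The
generator emulates exactly that structure — a schedule of alternating
inspiration/expiration intervals with per-cycle Gaussian duration jitter,
rendered as 100–1200 Hz band-passed white noise under a smooth amplitude
envelope — plus an imperfect-annotator model (boundary jitter, missed
phases, spurious phases) for agreement studies.

Defaults mimic a resting adult breathing deeply with an open mouth into a
chest microphone: 15 breaths/min, I:E ratio 1:1.5, 15 s files at
44,100 Hz, expiration at 0.4 of inspiration amplitude.  A nearly silent
expiration (gain 0.05) profile is available to stress-test detectors.

Everything is deterministic given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .annotations import (
    EXPIRATION,
    INSPIRATION,
    AnnotationSet,
    PhaseInterval,
)

__all__ = [
    "BreathingProfile",
    "AnnotatorNoise",
    "generate_schedule",
    "synthesize_audio",
    "corrupt_annotations",
    "simulate_corpus",
    "write_wav",
]


@dataclass(frozen=True)
class BreathingProfile:
    """Parameters of one synthetic recording."""

    respiratory_rate: float = 15.0  # breaths / minute
    ie_ratio: float = 1.0 / 1.5  # inspiration : expiration duration
    pause_fraction: float = 0.15  # fraction of each cycle that is silent
    expiration_gain: float = 0.4  # amplitude ratio expiration / inspiration
    cycle_jitter_sd: float = 0.1  # seconds, per-phase duration jitter
    duration: float = 15.0  # seconds
    sample_rate: float = 44100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.respiratory_rate, self.ie_ratio, self.duration,
               self.sample_rate) <= 0:
            raise ValueError("rate, ratio, duration, sample_rate must be positive")
        if not 0 <= self.pause_fraction < 1:
            raise ValueError("pause_fraction must lie in [0, 1)")
        if not 0 < self.expiration_gain <= 1:
            raise ValueError("expiration_gain must lie in (0, 1]")

    @property
    def cycle_length(self) -> float:
        return 60.0 / self.respiratory_rate

    def phase_durations(self) -> tuple[float, float, float]:
        """(inspiration, expiration, pause) seconds per cycle; the pause
        budget is split into two half-pauses, one after each phase."""
        breathing = self.cycle_length * (1.0 - self.pause_fraction)
        insp = breathing * self.ie_ratio / (1.0 + self.ie_ratio)
        exp = breathing - insp
        pause = self.cycle_length * self.pause_fraction
        if min(insp, exp) <= 0:
            raise ValueError("infeasible profile: nonpositive phase duration")
        return insp, exp, pause


@dataclass(frozen=True)
class AnnotatorNoise:
    """Imperfect-annotator model."""

    boundary_jitter_sd: float = 0.1  # seconds
    miss_prob: float = 0.0  # probability a phase is dropped
    spurious_rate: float = 0.0  # expected spurious phases per file
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.miss_prob <= 1:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.boundary_jitter_sd < 0 or self.spurious_rate < 0:
            raise ValueError("jitter sd and spurious rate must be >= 0")


def generate_schedule(
    profile: BreathingProfile,
    *,
    recording_id: str = "synthetic",
    source_id: str = "truth",
) -> AnnotationSet:
    """Ground-truth phase schedule: alternating inspiration/expiration
    with Gaussian per-phase duration jitter, a half-pause after each
    phase, truncated at the recording duration."""
    insp, exp, pause = profile.phase_durations()
    half_pause = pause / 2.0
    rng = np.random.default_rng(profile.seed)
    intervals: list[PhaseInterval] = []
    t = 0.0
    min_phase = 0.05  # floor so jitter can never produce a degenerate phase
    while t < profile.duration:
        for phase, nominal in ((INSPIRATION, insp), (EXPIRATION, exp)):
            length = max(
                nominal + rng.normal(0.0, profile.cycle_jitter_sd), min_phase
            )
            end = min(t + length, profile.duration)
            if end - t >= min_phase:
                intervals.append(PhaseInterval(t, end, phase))
            t = end + half_pause
            if t >= profile.duration:
                break
    return AnnotationSet(
        recording_id=recording_id,
        duration=profile.duration,
        source_id=source_id,
        intervals=tuple(intervals),
    )


def synthesize_audio(
    schedule: AnnotationSet, profile: BreathingProfile
) -> np.ndarray:
    """Render a schedule as band-limited noise under a smooth envelope.

    White noise is band-passed to 100–1200 Hz (well inside the <2000 Hz
    spectrogram crop), then multiplied by an envelope that is 1 during
    inspiration, ``expiration_gain`` during expiration, and a -40 dB floor
    during pauses; the envelope edges are smoothed over 50 ms so phase
    onsets are not clicks.
    """
    from scipy import signal
    from scipy.ndimage import uniform_filter1d

    sr = profile.sample_rate
    n = int(round(profile.duration * sr))
    rng = np.random.default_rng(profile.seed + 1)  # independent of schedule
    noise = rng.standard_normal(n)
    nyq = sr / 2.0
    sos = signal.butter(4, [100.0 / nyq, 1200.0 / nyq], "bandpass", output="sos")
    noise = signal.sosfilt(sos, noise)
    noise /= max(np.abs(noise).max(), 1e-12)

    env = np.full(n, 10.0 ** (-40.0 / 20.0))  # pause floor
    for iv in schedule.intervals:
        gain = 1.0 if iv.phase == INSPIRATION else profile.expiration_gain
        i0 = int(round(iv.start * sr))
        i1 = int(round(iv.end * sr))
        env[i0:i1] = gain
    smooth = max(int(round(0.05 * sr)), 1)
    env = uniform_filter1d(env, size=smooth, mode="nearest")
    return noise * env


def corrupt_annotations(
    truth: AnnotationSet, noise: AnnotatorNoise, *, source_id: str = "annotator"
) -> AnnotationSet:
    """Simulate an imperfect annotator reading a recording.

    Boundaries get independent Gaussian jitter, clipped so intervals stay
    valid, inside the recording, and non-overlapping; phases are dropped
    with ``miss_prob``; Poisson(``spurious_rate``) spurious short phases
    are inserted into silent gaps.  Zero noise reproduces the input
    exactly.
    """
    rng = np.random.default_rng(noise.seed)
    ivs = list(truth.intervals)
    kept: list[PhaseInterval] = []
    for idx, iv in enumerate(ivs):
        if noise.miss_prob > 0 and rng.random() < noise.miss_prob:
            continue
        start, end = iv.start, iv.end
        if noise.boundary_jitter_sd > 0:
            lo_prev = kept[-1].end if kept else 0.0
            hi_next = ivs[idx + 1].start if idx + 1 < len(ivs) else truth.duration
            mid = (start + end) / 2.0
            start = _clip(
                start + rng.normal(0.0, noise.boundary_jitter_sd),
                lo_prev, mid - 1e-3,
            )
            end = _clip(
                end + rng.normal(0.0, noise.boundary_jitter_sd),
                mid + 1e-3, max(hi_next, mid + 2e-3),
            )
            end = min(end, truth.duration)
        kept.append(PhaseInterval(start, end, iv.phase))

    if noise.spurious_rate > 0:
        n_spurious = rng.poisson(noise.spurious_rate)
        for _ in range(n_spurious):
            gap = _pick_gap(kept, truth.duration, rng)
            if gap is None:
                break
            g0, g1 = gap
            length = min(rng.uniform(0.2, 0.5), (g1 - g0) * 0.8)
            start = rng.uniform(g0, g1 - length)
            phase = INSPIRATION if rng.random() < 0.5 else EXPIRATION
            kept.append(PhaseInterval(start, start + length, phase))
    return AnnotationSet(
        recording_id=truth.recording_id,
        duration=truth.duration,
        source_id=source_id,
        intervals=tuple(sorted(kept)),
    )


def _clip(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


def _pick_gap(intervals, duration, rng):
    """A silent gap of at least 0.25 s, chosen uniformly among candidates."""
    ivs = sorted(intervals)
    edges = [0.0]
    for iv in ivs:
        edges += [iv.start, iv.end]
    edges.append(duration)
    gaps = [
        (edges[i], edges[i + 1])
        for i in range(0, len(edges), 2)
        if edges[i + 1] - edges[i] >= 0.25
    ]
    if not gaps:
        return None
    return gaps[rng.integers(len(gaps))]


def simulate_corpus(
    n_files: int,
    profile: BreathingProfile | None = None,
    noise: AnnotatorNoise | None = None,
    *,
    seed: int = 0,
    annotator_id: str = "annotator-1",
) -> list[tuple[AnnotationSet, AnnotationSet, np.ndarray, BreathingProfile]]:
    """Generate an n-file corpus.

    Returns, per file, (truth, corrupted annotation, waveform, profile);
    the corrupted annotation equals truth when ``noise`` is None.  Each
    file gets its own sub-seed derived from ``seed``.
    """
    base = profile or BreathingProfile()
    out = []
    for k in range(n_files):
        prof = replace(base, seed=seed * 100_003 + k)
        truth = generate_schedule(prof, recording_id=f"rec{k:03d}")
        wav = synthesize_audio(truth, prof)
        if noise is not None:
            ann = corrupt_annotations(
                truth,
                replace(noise, seed=seed * 200_003 + k),
                source_id=annotator_id,
            )
        else:
            ann = AnnotationSet(
                truth.recording_id, truth.duration, annotator_id, truth.intervals
            )
        out.append((truth, ann, wav, prof))
    return out


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a mono 16-bit PCM WAV, peak-normalized to 0.9 full scale."""
    from scipy.io import wavfile

    x = np.asarray(waveform, dtype=np.float64)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * 0.9
    wavfile.write(path, int(sample_rate), (x * 32767).astype(np.int16))
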