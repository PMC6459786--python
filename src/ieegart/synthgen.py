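"""Synthetic iEEG segment generator.

Emulates the four gold-standard segment classes so the full pipeline
(training, transfer, sliding-window detection, evaluation) can be
exercised without access to clinical recordings:

* **Physiological** — 1/f ("pink") background with low-amplitude
  band-limited (8–30 Hz) oscillations.
* **Pathological** — background plus 1–5 biphasic sharp-wave
  transients (~50–100 ms), each carrying a high-frequency oscillation
  (HFO) burst riding on the spike peak.
* **Line noise** — background plus a dominant 50 or 60 Hz sinusoid
  with weak odd harmonics.
* **Artifact** — non-cerebral contamination: a broadband muscle burst
  (>= 0.5 s), a baseline step (electrode movement / discontinuity), or
  a clipped high-amplitude machine transient.

Amplitudes are in arbitrary units — the feature pipeline z-scores every
row, so only shape and relative power matter.  All randomness flows
from an explicit per-call seed; no global RNG state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .core import ClassLabel, SegmentRecord

__all__ = [
    "SynthConfig",
    "gen_physiological",
    "gen_pathological",
    "gen_line_noise",
    "gen_artifact",
    "gen_dataset",
]

ARTIFACT_VARIANTS = ("muscle", "step", "clip")


@dataclass(frozen=True)
class SynthConfig:
    """Acquisition and amplitude constants for the generator.

    ``sampling_rate_hz`` and ``segment_seconds`` default to the pipeline
    contract of 5 kHz / 3 s (15,000 samples per segment).
    ``artifact_snr`` scales line-noise and artifact amplitudes relative
    to the background standard deviation.
    """

    sampling_rate_hz: float = 5000.0
    segment_seconds: float = 3.0
    line_freq_hz: float = 50.0
    background_amplitude: float = 1.0
    artifact_snr: float = 4.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.segment_seconds <= 0:
            raise ValueError("sampling rate and segment duration must be positive")
        n = self.sampling_rate_hz * self.segment_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "sampling_rate_hz * segment_seconds must be a whole number of samples"
            )
        if self.line_freq_hz not in (50.0, 60.0):
            raise ValueError("line_freq_hz must be 50 or 60")
        if self.background_amplitude <= 0 or self.artifact_snr <= 0:
            raise ValueError("amplitudes must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.segment_seconds))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


def _resolve_rng(cfg: SynthConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.rng_seed)


def _pink_noise(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude background noise, normalized to the configured std.

    Spectral shaping: white Gaussian noise is filtered in the frequency
    domain with amplitude proportional to 1/max(f, 1 Hz) (flat below
    1 Hz to avoid a DC singularity), then rescaled so the time-domain
    standard deviation equals ``background_amplitude``.
    """
    n = cfg.n_samples
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.sampling_rate_hz)
    shaping = 1.0 / np.maximum(freqs, 1.0)
    shaping[0] = 0.0  # zero-mean background
    shaped = np.fft.irfft(spectrum * shaping, n)
    std = shaped.std()
    if std > 0:
        shaped *= cfg.background_amplitude / std
    return shaped


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Pink background plus 1–3 amplitude-modulated 8–30 Hz oscillations."""
    x = _pink_noise(cfg, rng)
    t = cfg.time
    for _ in range(int(rng.integers(1, 4))):
        f = rng.uniform(8.0, 30.0)
        amp = rng.uniform(0.15, 0.5) * cfg.background_amplitude
        mod_f = rng.uniform(0.2, 1.0)
        phase, mod_phase = rng.uniform(0, 2 * np.pi, size=2)
        envelope = 0.5 + 0.5 * np.sin(2 * np.pi * mod_f * t + mod_phase)
        x += amp * envelope * np.sin(2 * np.pi * f * t + phase)
    return x


def gen_physiological(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> SegmentRecord:
    """Generate a physiological iEEG segment (background only)."""
    rng = _resolve_rng(cfg, rng)
    return SegmentRecord(
        _background(cfg, rng), cfg.sampling_rate_hz, ClassLabel.PHYSIOLOGICAL
    )


def _spike_with_hfo(
    cfg: SynthConfig, rng: np.random.Generator, t: np.ndarray
) -> np.ndarray:
    """One biphasic sharp transient with an HFO burst centered on its peak.

    The sharp wave is a difference of two offset Gaussians (total width
    ~50–100 ms); the HFO is a Hann-windowed 100–400 Hz sinusoid.
    """
    sigma_bg = cfg.background_amplitude
    center = rng.uniform(0.25, cfg.segment_seconds - 0.25)
    width = rng.uniform(0.05, 0.10)  # total spike duration, seconds
    polarity = rng.choice((-1.0, 1.0))
    amp = rng.uniform(5.0, 10.0) * sigma_bg
    sharp_sigma = width / 6.0
    slow_sigma = width / 3.0
    offset = width / 4.0
    wave = amp * (
        np.exp(-0.5 * ((t - center) / sharp_sigma) ** 2)
        - 0.55 * np.exp(-0.5 * ((t - center - offset) / slow_sigma) ** 2)
    )
    # HFO burst riding on the spike peak
    f_hfo = rng.uniform(100.0, 400.0)
    dur = rng.uniform(0.04, 0.10)
    n_burst = max(int(dur * cfg.sampling_rate_hz), 8)
    burst = (
        rng.uniform(1.5, 3.0)
        * sigma_bg
        * np.hanning(n_burst)
        * np.sin(2 * np.pi * f_hfo * np.arange(n_burst) / cfg.sampling_rate_hz)
    )
    start = int(center * cfg.sampling_rate_hz) - n_burst // 2
    out = polarity * wave
    sl = slice(max(start, 0), min(start + n_burst, t.shape[0]))
    out[sl] += burst[: sl.stop - sl.start]
    return out


def gen_pathological(
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    n_spikes: int | None = None,
) -> SegmentRecord:
    """Generate a pathological segment: spikes with superimposed HFOs.

    ``n_spikes`` defaults to a random draw in 1–5.  With ``n_spikes=0``
    the signal degenerates to the physiological background contract
    (the label stays ``PATHOLOGICAL``).
    """
    rng = _resolve_rng(cfg, rng)
    if n_spikes is None:
        n_spikes = int(rng.integers(1, 6))
    if n_spikes < 0:
        raise ValueError("n_spikes must be non-negative")
    x = _background(cfg, rng)
    t = cfg.time
    for _ in range(n_spikes):
        x += _spike_with_hfo(cfg, rng, t)
    return SegmentRecord(x, cfg.sampling_rate_hz, ClassLabel.PATHOLOGICAL)


def gen_line_noise(
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    amplitude: float | None = None,
) -> SegmentRecord:
    """Generate a segment dominated by mains interference.

    A sinusoid at ``cfg.line_freq_hz`` plus weak 3rd and 5th harmonics is
    added to the physiological background.  ``amplitude`` defaults to
    ``artifact_snr * background_amplitude``; zero reduces the segment to
    pure background.
    """
    rng = _resolve_rng(cfg, rng)
    x = _background(cfg, rng)
    if amplitude is None:
        amplitude = cfg.artifact_snr * cfg.background_amplitude
    if amplitude < 0:
        raise ValueError("line amplitude must be non-negative")
    t = cfg.time
    phases = rng.uniform(0, 2 * np.pi, size=3)
    for harmonic, frac, phase in zip((1, 3, 5), (1.0, 0.15, 0.05), phases):
        x += amplitude * frac * np.sin(
            2 * np.pi * cfg.line_freq_hz * harmonic * t + phase
        )
    label = (
        ClassLabel.LINE_NOISE_50 if cfg.line_freq_hz == 50.0 else ClassLabel.LINE_NOISE_60
    )
    return SegmentRecord(x, cfg.sampling_rate_hz, label)


def _muscle_burst(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Broadband high-frequency burst (EMG-like), duration >= 0.5 s."""
    n = cfg.n_samples
    fs = cfg.sampling_rate_hz
    dur = rng.uniform(0.5, min(2.0, cfg.segment_seconds - 0.2))
    n_burst = int(dur * fs)
    start = int(rng.uniform(0.1, cfg.segment_seconds - dur - 0.1) * fs)
    high = min(1800.0, 0.45 * fs)
    sos = scipy.signal.butter(4, [100.0, high], btype="bandpass", fs=fs, output="sos")
    noise = scipy.signal.sosfilt(sos, rng.standard_normal(n_burst))
    noise /= max(noise.std(), 1e-12)
    amp = rng.uniform(0.6, 1.2) * cfg.artifact_snr * cfg.background_amplitude
    ramp = min(int(0.05 * fs), n_burst // 4)
    taper = np.ones(n_burst)
    taper[:ramp] = np.linspace(0, 1, ramp)
    taper[-ramp:] = np.linspace(1, 0, ramp)
    out = np.zeros(n)
    out[start : start + n_burst] = amp * taper * noise
    return out


def _baseline_step(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Sustained baseline jump, as from electrode movement."""
    n = cfg.n_samples
    jump_at = int(rng.uniform(0.3, cfg.segment_seconds - 0.3) * cfg.sampling_rate_hz)
    amp = rng.choice((-1.0, 1.0)) * rng.uniform(12.0, 20.0) * cfg.background_amplitude
    out = np.zeros(n)
    out[jump_at:] = amp
    return out


def _clipped_transient(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """High-amplitude saturated (flat-topped) transient, as from amplifier clipping."""
    n = cfg.n_samples
    fs = cfg.sampling_rate_hz
    dur = rng.uniform(0.2, 0.5)
    n_pulse = int(dur * fs)
    start = int(rng.uniform(0.2, cfg.segment_seconds - dur - 0.2) * fs)
    amp = rng.uniform(10.0, 16.0) * cfg.background_amplitude
    f = rng.uniform(2.0, 5.0)
    raw = 3.0 * amp * np.sin(2 * np.pi * f * np.arange(n_pulse) / fs)
    out = np.zeros(n)
    out[start : start + n_pulse] = np.clip(raw, -amp, amp)
    return out


def gen_artifact(
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    variant: str | None = None,
) -> SegmentRecord:
    """Generate a non-cerebral artifact segment.

    ``variant`` selects ``"muscle"`` (broadband burst), ``"step"``
    (baseline jump) or ``"clip"`` (saturated transient); by default the
    variant is drawn at random (muscle most likely, matching how often
    each contaminates clinical recordings).
    """
    rng = _resolve_rng(cfg, rng)
    if variant is None:
        variant = rng.choice(ARTIFACT_VARIANTS, p=(0.6, 0.2, 0.2))
    if variant not in ARTIFACT_VARIANTS:
        raise ValueError(f"unknown artifact variant: {variant!r}")
    x = _background(cfg, rng)
    if variant == "muscle":
        x += _muscle_burst(cfg, rng)
    elif variant == "step":
        x += _baseline_step(cfg, rng)
    else:
        x += _clipped_transient(cfg, rng)
    return SegmentRecord(x, cfg.sampling_rate_hz, ClassLabel.ARTIFACT)


_GENERATORS = {
    ClassLabel.PHYSIOLOGICAL: gen_physiological,
    ClassLabel.PATHOLOGICAL: gen_pathological,
    ClassLabel.ARTIFACT: gen_artifact,
}


def _gen_for_label(
    cfg: SynthConfig, label: ClassLabel, rng: np.random.Generator
) -> SegmentRecord:
    if label in (ClassLabel.LINE_NOISE_50, ClassLabel.LINE_NOISE_60):
        freq = 50.0 if label is ClassLabel.LINE_NOISE_50 else 60.0
        return gen_line_noise(dataclasses.replace(cfg, line_freq_hz=freq), rng)
    return _GENERATORS[label](cfg, rng)


def gen_dataset(
    cfg: SynthConfig, counts: Mapping[ClassLabel, int]
) -> list[SegmentRecord]:
    """Generate a labeled, shuffled dataset with the requested class counts.

    Each segment gets its own child RNG spawned deterministically from
    ``cfg.rng_seed``, so the dataset is reproducible and individual
    segments do not share random streams.
    """
    if not counts:
        raise ValueError("counts must name at least one class")
    for label, n in counts.items():
        if not isinstance(label, ClassLabel):
            raise ValueError(f"counts keys must be ClassLabel, got {label!r}")
        if n < 0:
            raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("counts must request at least one segment")

    seed_seq = np.random.SeedSequence(cfg.rng_seed)
    children = seed_seq.spawn(total + 1)
    segments: list[SegmentRecord] = []
    i = 0
    for label in sorted(counts, key=lambda lb: lb.name):
        for _ in range(counts[label]):
            rng = np.random.default_rng(children[i])
            segments.append(_gen_for_label(cfg, label, rng))
            i += 1
    shuffle_rng = np.random.default_rng(children[-1])
    order = shuffle_rng.permutation(total)
    return [segments[j] for j in order]
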