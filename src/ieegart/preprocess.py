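"""Signal conditioning: downsampling, zero-phase filtering, envelograms,
and assembly of the 5 x 15000 classifier input matrix.

Each 3-s segment at 5 kHz is turned into five rows:

    row 0: raw signal low-passed at 900 Hz
    row 1: envelogram of the 20–100 Hz band (beta / gamma)
    row 2: envelogram of the 80–250 Hz band (ripples)
    row 3: envelogram of the 200–600 Hz band (fast ripples)
    row 4: envelogram of the 500–900 Hz band (very fast ripples, muscle)

An envelogram is the squared magnitude of the analytic signal of the
band-passed trace — an instantaneous band-power time series.  All
filtering is zero-phase (forward–backward 3rd-order Butterworth), and
every row is z-scored independently, so segment amplitude units cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.signal

from .core import SegmentRecord

__all__ = [
    "BandDefinition",
    "FeatureMatrix",
    "DEFAULT_BANDS",
    "LOWPASS_CUTOFF_HZ",
    "PIPELINE_RATE_HZ",
    "SEGMENT_SECONDS",
    "SEGMENT_SAMPLES",
    "antialias_downsample",
    "zero_phase_filter",
    "envelogram",
    "zscore_row",
    "build_feature_matrix",
]

#: Pipeline sampling rate after acquisition-rate downsampling.
PIPELINE_RATE_HZ = 5000.0
#: Segment duration fed to the classifier.
SEGMENT_SECONDS = 3.0
#: Samples per classifier segment.
SEGMENT_SAMPLES = 15000
#: Cutoff of the raw-row low-pass filter.
LOWPASS_CUTOFF_HZ = 900.0
#: Antialiasing low-pass cutoff used before decimation to 5 kHz.
ANTIALIAS_CUTOFF_HZ = 1000.0
#: Butterworth order for the zero-phase band/low-pass filters.
FILTER_ORDER = 3


@dataclass(frozen=True)
class BandDefinition:
    """A band-pass frequency band in Hz."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band: {self.low_hz}-{self.high_hz} Hz")

    def validate_against(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


#: Envelogram bands, in input-row order.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition(20.0, 100.0),
    BandDefinition(80.0, 250.0),
    BandDefinition(200.0, 600.0),
    BandDefinition(500.0, 900.0),
)

#: Human-readable row semantics of the feature matrix.
ROW_SEMANTICS: tuple[str, ...] = (
    "lowpassed-raw",
    "env 20-100",
    "env 80-250",
    "env 200-600",
    "env 500-900",
)


@dataclass
class FeatureMatrix:
    """The z-scored classifier input: one row per signal view.

    ``values`` has shape (5, 15000) at the default configuration; each
    row has mean ~0 and population std ~1 except degenerate constant
    rows, which are all-zero.
    """

    values: np.ndarray
    row_semantics: tuple[str, ...] = ROW_SEMANTICS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[0] != len(self.row_semantics):
            raise ValueError("row count does not match row semantics")


def _antialias_fir(source_rate: float, up: int, cutoff_hz: float) -> np.ndarray:
    """Bartlett–Hann-windowed FIR low-pass at the antialias cutoff.

    Designed at the (possibly up-sampled) working rate.  The tap count
    scales with the working rate so the transition band stays a few
    hundred Hz wide regardless of the acquisition rate.
    """
    work_rate = source_rate * up
    numtaps = int(round(work_rate / 5000.0)) * 257 + 1
    return scipy.signal.firwin(numtaps, cutoff_hz, window="barthann", fs=work_rate)


def antialias_downsample(
    signal: np.ndarray,
    source_rate: float,
    target_rate: float = PIPELINE_RATE_HZ,
    cutoff_hz: float = ANTIALIAS_CUTOFF_HZ,
) -> np.ndarray:
    """Low-pass filter (Bartlett–Hann FIR, 1 kHz cutoff) and resample.

    Handles rational rate ratios through polyphase resampling; for the
    common integer-decimation case (e.g. 32 kHz -> 5 kHz) this reduces
    to filter-and-decimate.  Output length is
    ``round(len(signal) * target_rate / source_rate)``.  ``cutoff_hz``
    can be raised (e.g. to 2 kHz) to emulate acquisition chains that
    band-limited less aggressively before the 5 kHz downsampling.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if target_rate > source_rate:
        raise ValueError("target rate must not exceed source rate")
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate == source_rate:
        return signal.copy()
    if not 0 < cutoff_hz < target_rate / 2:
        raise ValueError("antialias cutoff must lie below the target Nyquist rate")
    ratio = Fraction(target_rate / source_rate).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    fir = _antialias_fir(source_rate, up, cutoff_hz)
    out = scipy.signal.resample_poly(signal, up, down, window=fir)
    n_expected = int(round(signal.shape[0] * target_rate / source_rate))
    return out[:n_expected]


def zero_phase_filter(
    signal: np.ndarray,
    kind: str,
    band: "BandDefinition | float",
    fs: float,
) -> np.ndarray:
    """Forward–backward 3rd-order Butterworth filter (zero net phase).

    ``kind`` is ``"lowpass"`` (``band`` is the cutoff in Hz) or
    ``"bandpass"`` (``band`` is a :class:`BandDefinition`).  The
    forward–backward pass doubles the effective magnitude order and
    cancels the phase response; edges are stabilized with the default
    odd-reflection padding.
    """
    signal = np.asarray(signal, dtype=np.float64)
    nyquist = fs / 2.0
    if kind == "lowpass":
        cutoff = float(band.high_hz) if isinstance(band, BandDefinition) else float(band)
        if not 0 < cutoff < nyquist:
            raise ValueError(f"cutoff {cutoff} Hz outside (0, {nyquist}) Hz")
        sos = scipy.signal.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=fs, output="sos")
    elif kind == "bandpass":
        if not isinstance(band, BandDefinition):
            band = BandDefinition(*band)
        band.validate_against(fs)
        sos = scipy.signal.butter(
            FILTER_ORDER, (band.low_hz, band.high_hz), btype="bandpass", fs=fs, output="sos"
        )
    else:
        raise ValueError(f"unknown filter kind: {kind!r}")
    return scipy.signal.sosfiltfilt(sos, signal)


def envelogram(signal: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Instantaneous band power: squared analytic-signal magnitude.

    The trace is band-passed (zero phase) and the Hilbert transform
    forms the analytic signal; its squared magnitude is a non-negative
    power envelope of the same length as the input.
    """
    filtered = zero_phase_filter(signal, "bandpass", band, fs)
    analytic = scipy.signal.hilbert(filtered)
    return np.abs(analytic) ** 2


def zscore_row(signal: np.ndarray) -> np.ndarray:
    """Z-score with population std; a constant row maps to all zeros."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("cannot z-score an empty signal")
    if np.ptp(signal) == 0:  # constant row: degenerate, defined as all-zero
        return np.zeros_like(signal)
    std = signal.std()
    if std == 0:
        return np.zeros_like(signal)
    return (signal - signal.mean()) / std


def build_feature_matrix(
    segment: SegmentRecord,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    lowpass_cutoff_hz: float = LOWPASS_CUTOFF_HZ,
) -> FeatureMatrix:
    """Assemble the classifier input matrix from one 3-s segment.

    Row 0 is the z-scored 900 Hz-low-passed raw trace; rows 1..4 are the
    z-scored envelograms of the four default bands, in band order.  The
    segment must already be at the 5 kHz pipeline rate with exactly
    15,000 samples.
    """
    if segment.sampling_rate_hz != PIPELINE_RATE_HZ:
        raise ValueError(
            f"segment rate {segment.sampling_rate_hz} Hz != pipeline rate {PIPELINE_RATE_HZ} Hz"
        )
    if segment.n_samples != SEGMENT_SAMPLES:
        raise ValueError(
            f"segment has {segment.n_samples} samples, expected {SEGMENT_SAMPLES}"
        )
    fs = segment.sampling_rate_hz
    rows = [zscore_row(zero_phase_filter(segment.signal, "lowpass", lowpass_cutoff_hz, fs))]
    for band in bands:
        rows.append(zscore_row(envelogram(segment.signal, band, fs)))
    semantics = ("lowpassed-raw",) + tuple(
        f"env {int(b.low_hz)}-{int(b.high_hz)}" for b in bands
    )
    return FeatureMatrix(np.stack(rows), semantics)
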