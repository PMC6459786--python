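"""Shared domain types: class labels and single-channel signal segments.

The classifier distinguishes four kinds of intracranial EEG content:
physiological background activity, pathological activity (interictal
spikes with superimposed high-frequency oscillations), power-line
interference (50 or 60 Hz), and non-cerebral broadband artifact
(muscle, movement, machine).  Line noise is kept out of the
"generalized" 3-class task because mains frequency differs between
acquisition sites; the site-specialized 4-class task includes it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassLabel",
    "SegmentRecord",
    "GENERALIZED_CLASSES",
    "SPECIALIZED_CLASSES",
]


class ClassLabel(str, enum.Enum):
    """Gold-standard segment classes, serialized as their canonical names."""

    PHYSIOLOGICAL = "Physiological iEEG"
    PATHOLOGICAL = "Pathological iEEG"
    ARTIFACT = "Noise and muscle activity"
    LINE_NOISE_50 = "Power line noise (50hz)"
    LINE_NOISE_60 = "Power line noise (60hz)"

    def __str__(self) -> str:  # str(label) -> canonical name
        return self.value

    @classmethod
    def from_string(cls, text: str) -> "ClassLabel":
        """Parse a canonical class name or enum member name; fail fast on unknowns."""
        for member in cls:
            if text == member.value or text == member.name:
                return member
        raise ValueError(f"unknown class label: {text!r}")


#: Class order of the 3-class cross-site ("generalized") task.
GENERALIZED_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.ARTIFACT,
    ClassLabel.PHYSIOLOGICAL,
    ClassLabel.PATHOLOGICAL,
)

#: Class order of the 4-class site-specialized task (US mains frequency).
SPECIALIZED_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.LINE_NOISE_60,
    ClassLabel.ARTIFACT,
    ClassLabel.PHYSIOLOGICAL,
    ClassLabel.PATHOLOGICAL,
)


@dataclass
class SegmentRecord:
    """One channel's worth of signal for one fixed-length segment.

    Attributes
    ----------
    signal:
        1-D float array of samples (arbitrary amplitude units).
    sampling_rate_hz:
        Sampling rate of ``signal``.
    label:
        Optional gold-standard class of the segment.
    channel_name:
        Optional name of the source channel.
    """

    signal: np.ndarray
    sampling_rate_hz: float
    label: ClassLabel | None = None
    channel_name: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1:
            raise ValueError("segment signal must be one-dimensional")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz
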