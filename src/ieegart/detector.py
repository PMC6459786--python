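"""Sliding-window detection over continuous recordings.

The trained classifier is slid along each channel independently: 3-s
windows with 2-s overlap (stride 1 s), with each window's class
probabilities assigned to its *center* 1-s epoch.  The overlap ensures
events straddling window boundaries are still seen centered by some
window.  The result is a channels x seconds x classes probability
matrix; thresholding one class (artifact -> APM, pathological -> PPM)
at a probability higher than 95% gives the binarized matrix, and
connected runs of supra-threshold seconds become detection events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cnn_model import CNNModel, predict_proba_batch
from .core import ClassLabel, SegmentRecord
from .preprocess import PIPELINE_RATE_HZ, SEGMENT_SAMPLES, build_feature_matrix
from .sigio import RecordingBundle

__all__ = [
    "ProbabilityMatrix",
    "DetectionEvent",
    "classify_record",
    "binarize",
    "extract_events",
    "render_matrix",
]

DEFAULT_THRESHOLD = 0.95


@dataclass
class ProbabilityMatrix:
    """Per-channel, per-second class probabilities.

    ``values`` has shape (channels, seconds, classes); each class vector
    sums to 1.  Columns are 0-based 1-s epochs; the seconds dimension is
    ``floor(duration)``.
    """

    values: np.ndarray
    channel_names: list[str]
    class_order: tuple[ClassLabel, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("probability matrix must be channels x seconds x classes")
        if self.values.shape[0] != len(self.channel_names):
            raise ValueError("channel dimension does not match channel_names")
        if self.values.shape[2] != len(self.class_order):
            raise ValueError("class dimension does not match class_order")

    @property
    def n_seconds(self) -> int:
        return self.values.shape[1]

    def class_index(self, label: ClassLabel) -> int:
        try:
            return self.class_order.index(label)
        except ValueError:
            raise ValueError(f"class {label} not in matrix class order") from None

    def class_slice(self, label: ClassLabel) -> np.ndarray:
        """The channels x seconds probability plane of one class."""
        return self.values[:, :, self.class_index(label)]


@dataclass
class DetectionEvent:
    """A contiguous run of supra-threshold seconds on one channel."""

    channel_name: str
    start_second: int
    end_second: int  # half-open
    label: ClassLabel
    peak_probability: float


def classify_record(
    model: CNNModel,
    bundle: RecordingBundle,
    batch_size: int = 64,
) -> ProbabilityMatrix:
    """Slide the classifier over every channel of a continuous recording.

    Windows are 3 s long with 1-s stride (2-s overlap); the window
    starting at second ``t`` contributes the probability column of its
    center second ``t + 1``.  The first and last seconds have no
    centered window and replicate the nearest centered column, so the
    matrix spans all ``floor(duration)`` seconds.  Channels are
    processed independently.
    """
    if bundle.sampling_rate_hz != PIPELINE_RATE_HZ:
        raise ValueError(
            f"recording rate {bundle.sampling_rate_hz} Hz != pipeline rate "
            f"{PIPELINE_RATE_HZ} Hz"
        )
    total_seconds = int(bundle.n_samples // bundle.sampling_rate_hz)
    if total_seconds < 3:
        raise ValueError("recording must be at least 3 s long")
    fs = int(PIPELINE_RATE_HZ)
    n_windows = total_seconds - 2  # stride 1 s, window 3 s
    n_classes = model.config.n_classes
    values = np.empty((bundle.n_channels, total_seconds, n_classes))

    for ch in range(bundle.n_channels):
        feats = np.empty((n_windows, 5, SEGMENT_SAMPLES), dtype=np.float32)
        for w in range(n_windows):
            seg = SegmentRecord(
                bundle.signal[ch, w * fs : w * fs + SEGMENT_SAMPLES],
                PIPELINE_RATE_HZ,
            )
            feats[w] = build_feature_matrix(seg).values
        probs = predict_proba_batch(model, feats, batch_size=batch_size)
        values[ch, 1 : 1 + n_windows] = probs  # window w -> center second w+1
        values[ch, 0] = probs[0]
        values[ch, 1 + n_windows :] = probs[-1]

    return ProbabilityMatrix(values, list(bundle.channel_names), model.class_order)


def binarize(
    matrix: ProbabilityMatrix,
    target_class: ClassLabel,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """Channels x seconds binary matrix: 1 where p(target) > threshold.

    The inequality is strict — a cell at exactly the threshold stays 0,
    matching "probability higher than 95%".
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be inside (0, 1)")
    plane = matrix.class_slice(target_class)
    return (plane > threshold).astype(np.int8)


def extract_events(
    binary_matrix: np.ndarray,
    min_duration_s: int = 1,
    *,
    prob_matrix: ProbabilityMatrix | None = None,
    target_class: ClassLabel | None = None,
    channel_names: list[str] | None = None,
) -> list[DetectionEvent]:
    """Connected-component (run-length) event extraction per channel.

    Maximal horizontal runs of 1s become events; runs shorter than
    ``min_duration_s`` are discarded.  When ``prob_matrix`` and
    ``target_class`` are given, each event records its peak probability
    from the source matrix; otherwise the peak is reported as 1.0.
    """
    binary = np.atleast_2d(np.asarray(binary_matrix))
    if min_duration_s < 1:
        raise ValueError("min_duration_s must be >= 1")
    if channel_names is None:
        if prob_matrix is not None:
            channel_names = prob_matrix.channel_names
        else:
            channel_names = [f"ch{i}" for i in range(binary.shape[0])]
    label = target_class if target_class is not None else ClassLabel.ARTIFACT
    plane = (
        prob_matrix.class_slice(target_class)
        if prob_matrix is not None and target_class is not None
        else None
    )
    events: list[DetectionEvent] = []
    for ch in range(binary.shape[0]):
        row = binary[ch]
        padded = np.concatenate(([0], row.astype(np.int8), [0]))
        diff = np.diff(padded)
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for start, end in zip(starts, ends):
            if end - start < min_duration_s:
                continue
            peak = float(plane[ch, start:end].max()) if plane is not None else 1.0
            events.append(
                DetectionEvent(channel_names[ch], int(start), int(end), label, peak)
            )
    return events


def render_matrix(matrix, path: str | Path, threshold: float | None = None) -> None:
    """Render a matrix as a raster image: one pixel per (channel, second).

    Binary matrices use the two-color map of the probability-matrix
    figures (dark blue background, yellow detections); probability
    planes are rendered on a continuous blue-to-yellow scale.  Pass a
    :class:`ProbabilityMatrix` plus ``threshold`` (with the plane
    pre-selected via :meth:`ProbabilityMatrix.class_slice`) or a plain
    2-D array.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib import colors
    from matplotlib import image as mpimage

    arr = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if arr.size == 0:
        raise ValueError("cannot render an empty matrix")
    if threshold is not None:
        arr = (arr > threshold).astype(np.float64)
    is_binary = np.isin(arr, (0.0, 1.0)).all()
    if is_binary:
        cmap = colors.ListedColormap(["#00007f", "#ffdf00"])
        norm = colors.Normalize(vmin=0.0, vmax=1.0)
        rgba = cmap(norm(arr))
    else:
        cmap = matplotlib.colormaps["cividis"]
        norm = colors.Normalize(vmin=0.0, vmax=1.0)
        rgba = cmap(norm(arr))
    mpimage.imsave(str(path), rgba)
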