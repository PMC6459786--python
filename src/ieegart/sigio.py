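"""Reading and writing signals, annotations, probability matrices, and
model checkpoints in open formats.

Native signal storage is a flat little-endian binary sample array plus a
small YAML header (sampling rate, channel names, dtype, shape) — no
proprietary dependency.  European Data Format (EDF) is supported for
interoperability (read via MNE; a minimal 16-bit EDF writer is provided
because no installed library writes EDF).

All interval coordinates are 0-based, half-open ``[start, end)`` sample
indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ClassLabel, SegmentRecord

__all__ = [
    "RecordingBundle",
    "FormatError",
    "UnsupportedInputError",
    "VersionError",
    "read_recording",
    "write_recording",
    "write_edf",
    "read_annotations",
    "write_annotations",
    "segment_record",
    "write_probability_matrix",
    "read_probability_matrix",
    "save_model",
    "load_model",
]


class FormatError(ValueError):
    """A file does not parse as the expected format."""


class UnsupportedInputError(ValueError):
    """A well-formed file uses a feature this pipeline does not support."""


class VersionError(ValueError):
    """A checkpoint is inconsistent with the architecture that loads it."""


@dataclass
class RecordingBundle:
    """A multichannel recording: channels x samples plus metadata."""

    signal: np.ndarray
    sampling_rate_hz: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must equal number of signal rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


# --------------------------------------------------------------------------
# native array + header format
# --------------------------------------------------------------------------

def _data_path(header_path: Path) -> Path:
    return header_path.with_suffix(".dat")


def write_recording(bundle: RecordingBundle, path: str | Path) -> None:
    """Write the native format: YAML header at ``path`` + sibling ``.dat``."""
    path = Path(path)
    data = np.ascontiguousarray(bundle.signal, dtype="<f8")
    header = {
        "format": "ieegart-array",
        "version": 1,
        "sampling_rate_hz": float(bundle.sampling_rate_hz),
        "channel_names": list(bundle.channel_names),
        "dtype": "<f8",
        "n_channels": bundle.n_channels,
        "n_samples": bundle.n_samples,
        "data_file": _data_path(path).name,
    }
    path.write_text(yaml.safe_dump(header, sort_keys=False))
    data.tofile(_data_path(path))


def _read_array_recording(path: Path) -> RecordingBundle:
    if not path.exists():
        raise FormatError(f"header file not found: {path}")
    try:
        header = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"malformed header {path}: {exc}") from exc
    if not isinstance(header, dict):
        raise FormatError(f"malformed header {path}: not a mapping")
    for key in ("sampling_rate_hz", "channel_names", "dtype", "n_channels", "n_samples"):
        if key not in header:
            raise FormatError(f"header {path} missing field {key!r}")
    data_file = path.parent / header.get("data_file", _data_path(path).name)
    if not data_file.exists():
        raise FormatError(f"data file not found: {data_file}")
    data = np.fromfile(data_file, dtype=header["dtype"])
    n_ch, n_s = int(header["n_channels"]), int(header["n_samples"])
    if data.size != n_ch * n_s:
        raise FormatError(
            f"data file {data_file} has {data.size} samples, "
            f"header promises {n_ch} x {n_s}"
        )
    return RecordingBundle(
        data.reshape(n_ch, n_s).astype(np.float64),
        float(header["sampling_rate_hz"]),
        [str(c) for c in header["channel_names"]],
    )


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def _edf_samples_per_record(path: Path) -> list[int]:
    """Read the per-signal samples-per-record fields from an EDF header."""
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            ns = int(fixed[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: bad signal count field") from exc
        fh.seek(256 + ns * 216)
        raw = fh.read(ns * 8)
    try:
        return [int(raw[i * 8 : (i + 1) * 8].decode("ascii").strip()) for i in range(ns)]
    except ValueError as exc:
        raise FormatError(f"{path}: bad samples-per-record field") from exc


def _read_edf_recording(path: Path) -> RecordingBundle:
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    spr = _edf_samples_per_record(path)
    if len(set(spr)) > 1:
        raise UnsupportedInputError(
            f"{path}: mixed per-channel sampling rates are not supported"
        )
    import mne  # deferred: heavy import

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # MNE returns SI units (volts); scale to microvolt-scale working units.
    return RecordingBundle(raw.get_data() * 1e6, float(raw.info["sfreq"]), raw.ch_names)


def write_edf(bundle: RecordingBundle, path: str | Path) -> None:
    """Write a minimal 16-bit EDF file (equal-rate channels, 1-s records).

    Amplitudes are mapped linearly onto the full digital range per
    channel; the sampling rate must give a whole number of samples per
    1-s data record.
    """
    path = Path(path)
    fs = bundle.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedInputError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = bundle.n_samples // spr
    if n_records * spr != bundle.n_samples:
        raise UnsupportedInputError(
            "EDF writer requires a whole number of 1-s data records"
        )
    ns = bundle.n_channels

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    phys_min = bundle.signal.min(axis=1)
    phys_max = bundle.signal.max(axis=1)
    span = np.where(phys_max - phys_min <= 0, 1.0, phys_max - phys_min)
    phys_max = phys_min + span

    def field(values: Sequence[str], width: int) -> bytes:
        return b"".join(pad(v, width) for v in values)

    header += field(bundle.channel_names, 16)
    header += field([""] * ns, 80)
    header += field(["uV"] * ns, 8)
    header += field([f"{v:.6g}" for v in phys_min], 8)
    header += field([f"{v:.6g}" for v in phys_max], 8)
    header += field(["-32768"] * ns, 8)
    header += field(["32767"] * ns, 8)
    header += field([""] * ns, 80)
    header += field([str(spr)] * ns, 8)
    header += field([""] * ns, 32)

    digital = np.empty((ns, bundle.n_samples), dtype="<i2")
    for ch in range(ns):
        scaled = (bundle.signal[ch] - phys_min[ch]) / span[ch]
        digital[ch] = np.round(scaled * 65535.0 - 32768.0).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for ch in range(ns):
                fh.write(digital[ch, rec * spr : (rec + 1) * spr].tobytes())


def read_recording(path: str | Path, format: str = "auto") -> RecordingBundle:
    """Read a recording from EDF or the native array format.

    ``format`` is ``"edf"``, ``"array"``, or ``"auto"`` (by extension:
    ``.edf`` means EDF, anything else the native header).
    """
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "array"
    if format == "edf":
        return _read_edf_recording(path)
    if format == "array":
        return _read_array_recording(path)
    raise ValueError(f"unknown recording format: {format!r}")


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["channel", "start_sample", "end_sample", "label"]


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    """Write an annotation table as tab-delimited text."""
    df = _validate_annotations(annotations)
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-delimited annotation table."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    return _validate_annotations(df)


def _validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns: {missing}")
    df = df[_ANNOTATION_COLUMNS].copy()
    df["start_sample"] = df["start_sample"].astype(np.int64)
    df["end_sample"] = df["end_sample"].astype(np.int64)
    df["label"] = [str(ClassLabel.from_string(str(lb))) for lb in df["label"]]
    if (df["start_sample"] < 0).any():
        raise ValueError("start_sample must be non-negative")
    if (df["start_sample"] >= df["end_sample"]).any():
        raise ValueError("annotation intervals must satisfy start < end")
    return df


def segment_record(
    bundle: RecordingBundle,
    annotations: pd.DataFrame,
    segment_seconds: float = 3.0,
) -> list[SegmentRecord]:
    """Tile annotated intervals into labeled fixed-length segments.

    Each ``[start, end)`` interval is cut into non-overlapping segments
    of ``segment_seconds``; a trailing remainder shorter than one
    segment is dropped.  Segments inherit the interval's label and
    channel name.
    """
    annotations = _validate_annotations(annotations)
    seg_samples = int(round(segment_seconds * bundle.sampling_rate_hz))
    channel_index = {name: i for i, name in enumerate(bundle.channel_names)}
    segments: list[SegmentRecord] = []
    for row in annotations.itertuples(index=False):
        if row.channel not in channel_index:
            raise ValueError(f"annotation references unknown channel {row.channel!r}")
        if row.end_sample > bundle.n_samples:
            raise ValueError(
                f"annotation [{row.start_sample}, {row.end_sample}) exceeds "
                f"recording length {bundle.n_samples}"
            )
        ch = channel_index[row.channel]
        label = ClassLabel.from_string(row.label)
        n_seg = (row.end_sample - row.start_sample) // seg_samples
        for k in range(n_seg):
            start = row.start_sample + k * seg_samples
            segments.append(
                SegmentRecord(
                    bundle.signal[ch, start : start + seg_samples].copy(),
                    bundle.sampling_rate_hz,
                    label,
                    channel_name=row.channel,
                )
            )
    return segments


# --------------------------------------------------------------------------
# probability matrices
# --------------------------------------------------------------------------

def write_probability_matrix(matrix, path: str | Path) -> None:
    """Write a probability or binary matrix as tab-delimited text.

    A full :class:`~ieegart.detector.ProbabilityMatrix` (channels x
    seconds x classes) is written with one row per (channel, class);
    a plain 2-D channels x seconds array (e.g. a binarized APM) is
    written with one row per channel.  Values round-trip to at least
    six significant digits.
    """
    from .detector import ProbabilityMatrix  # deferred: avoids import cycle

    path = Path(path)
    if isinstance(matrix, ProbabilityMatrix):
        if matrix.values.size == 0:
            raise ValueError("cannot write an empty probability matrix")
        n_ch, n_s, n_cls = matrix.values.shape
        records = []
        for ci, channel in enumerate(matrix.channel_names):
            for ki, label in enumerate(matrix.class_order):
                records.append([channel, str(label)] + list(matrix.values[ci, :, ki]))
        df = pd.DataFrame(records, columns=["channel", "class"] + [str(s) for s in range(n_s)])
    else:
        arr = np.atleast_2d(np.asarray(matrix))
        if arr.size == 0:
            raise ValueError("cannot write an empty matrix")
        df = pd.DataFrame(
            arr, columns=[str(s) for s in range(arr.shape[1])]
        )
        df.insert(0, "channel", [f"ch{i}" for i in range(arr.shape[0])])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_probability_matrix(path: str | Path):
    """Read back a matrix written by :func:`write_probability_matrix`.

    Returns a :class:`~ieegart.detector.ProbabilityMatrix` when the file
    has a ``class`` column, otherwise ``(values, channel_names)``.
    """
    from .detector import ProbabilityMatrix  # deferred: avoids import cycle

    path = Path(path)
    if not path.exists():
        raise FormatError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "channel" not in df.columns:
        raise FormatError(f"{path}: missing channel column")
    if "class" in df.columns:
        channels = list(dict.fromkeys(df["channel"]))
        classes = [ClassLabel.from_string(c) for c in dict.fromkeys(df["class"])]
        sec_cols = [c for c in df.columns if c not in ("channel", "class")]
        values = np.empty((len(channels), len(sec_cols), len(classes)))
        for ci, channel in enumerate(channels):
            sub = df[df["channel"] == channel]
            for ki, label in enumerate(classes):
                row = sub[sub["class"] == str(label)]
                values[ci, :, ki] = row[sec_cols].to_numpy()[0]
        return ProbabilityMatrix(values, channels, tuple(classes))
    sec_cols = [c for c in df.columns if c != "channel"]
    return df[sec_cols].to_numpy(), list(df["channel"])


# --------------------------------------------------------------------------
# model checkpoints
# --------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Save a classifier checkpoint: architecture + weights + class order."""
    import dataclasses

    path = Path(path)
    meta = {
        "format": "ieegart-checkpoint",
        "version": 1,
        "config": dataclasses.asdict(model.config),
        "class_order": [label.name for label in model.class_order],
        "rng_seed": model.rng_seed,
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_model(path: str | Path):
    """Load a checkpoint written by :func:`save_model`.

    Raises :class:`VersionError` when the stored class list is
    inconsistent with the stored architecture.
    """
    from .cnn_model import CNNModel, ModelConfig  # deferred: avoids import cycle

    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    if not path.exists():
        raise FormatError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["__meta__"]).decode())
        except (KeyError, json.JSONDecodeError) as exc:
            raise FormatError(f"{path}: missing or corrupt checkpoint metadata") from exc
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta.get("format") != "ieegart-checkpoint":
        raise FormatError(f"{path}: not an ieegart checkpoint")
    cfg_dict = dict(meta["config"])
    cfg_dict["conv_blocks"] = tuple(tuple(b) for b in cfg_dict["conv_blocks"])
    config = ModelConfig(**cfg_dict)
    class_order = tuple(ClassLabel[name] for name in meta["class_order"])
    if len(class_order) != config.n_classes:
        raise VersionError(
            f"{path}: class list has {len(class_order)} entries but the "
            f"architecture expects {config.n_classes}"
        )
    model = CNNModel(config, class_order, int(meta["rng_seed"]))
    expected = {k: v.shape for k, v in model.state_dict().items()}
    for key, shape in expected.items():
        if key not in state:
            raise VersionError(f"{path}: checkpoint missing tensor {key}")
        if state[key].shape != shape:
            raise VersionError(
                f"{path}: tensor {key} has shape {state[key].shape}, expected {shape}"
            )
    model.load_state_dict(state)
    return model
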