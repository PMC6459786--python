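"""I/O round-trips: native array format, EDF, annotation tables,
probability matrices, and model checkpoints."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ieegart.cnn_model import ModelConfig, build_model
from ieegart.core import ClassLabel, GENERALIZED_CLASSES, SPECIALIZED_CLASSES
from ieegart.detector import ProbabilityMatrix
from ieegart.sigio import (
    FormatError,
    RecordingBundle,
    UnsupportedInputError,
    VersionError,
    load_model,
    read_annotations,
    read_probability_matrix,
    read_recording,
    save_model,
    segment_record,
    write_annotations,
    write_edf,
    write_probability_matrix,
    write_recording,
)


@pytest.fixture
def bundle() -> RecordingBundle:
    rng = np.random.default_rng(0)
    return RecordingBundle(rng.normal(size=(2, 50000)), 5000.0, ["LA1", "LA2"])


class TestArrayFormat:
    def test_round_trip_bit_identical(self, bundle, tmp_path):
        path = tmp_path / "rec.yaml"
        write_recording(bundle, path)
        back = read_recording(path, format="array")
        assert np.array_equal(back.signal, bundle.signal)
        assert back.sampling_rate_hz == 5000.0
        assert back.channel_names == ["LA1", "LA2"]

    def test_missing_header_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="header"):
            read_recording(tmp_path / "absent.yaml", format="array")

    def test_truncated_data_file_is_format_error(self, bundle, tmp_path):
        path = tmp_path / "rec.yaml"
        write_recording(bundle, path)
        data = tmp_path / "rec.dat"
        data.write_bytes(data.read_bytes()[:100])
        with pytest.raises(FormatError, match="samples"):
            read_recording(path, format="array")

    def test_header_missing_field_named(self, bundle, tmp_path):
        import yaml

        path = tmp_path / "rec.yaml"
        write_recording(bundle, path)
        header = yaml.safe_load(path.read_text())
        del header["sampling_rate_hz"]
        path.write_text(yaml.safe_dump(header))
        with pytest.raises(FormatError, match="sampling_rate_hz"):
            read_recording(path, format="array")


class TestEdf:
    def test_write_read_shape_and_rate(self, tmp_path):
        rng = np.random.default_rng(1)
        bundle = RecordingBundle(
            rng.normal(size=(2, 50000)) * 50, 5000.0, ["ch1", "ch2"]
        )
        path = tmp_path / "rec.edf"
        write_edf(bundle, path)
        back = read_recording(path)  # auto-detected by extension
        assert back.signal.shape == (2, 50000)
        assert back.sampling_rate_hz == 5000.0
        assert back.channel_names == ["ch1", "ch2"]
        # 16-bit quantization: values agree to ~span/65536
        assert np.abs(back.signal - bundle.signal).max() < 0.02

    def test_mixed_sampling_rates_rejected(self, tmp_path):
        rng = np.random.default_rng(2)
        bundle = RecordingBundle(rng.normal(size=(2, 1000)), 500.0, ["a", "b"])
        path = tmp_path / "mixed.edf"
        write_edf(bundle, path)
        # corrupt the second channel's samples-per-record header field
        raw = bytearray(path.read_bytes())
        offset = 256 + 2 * 216 + 8  # second signal's samples/record
        raw[offset : offset + 8] = b"250     "
        path.write_bytes(bytes(raw))
        with pytest.raises(UnsupportedInputError, match="mixed"):
            read_recording(path)


class TestAnnotations:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "channel": ["LA1", "LA2"],
                "start_sample": [0, 15000],
                "end_sample": [15000, 60000],
                "label": [str(ClassLabel.PHYSIOLOGICAL), str(ClassLabel.ARTIFACT)],
            }
        )
        path = tmp_path / "ann.tsv"
        write_annotations(df, path)
        back = read_annotations(path)
        pd.testing.assert_frame_equal(back, df)

    def test_unknown_label_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "channel": ["LA1"],
                "start_sample": [0],
                "end_sample": [100],
                "label": ["Eye blink"],
            }
        )
        with pytest.raises(ValueError, match="unknown class label"):
            write_annotations(df, tmp_path / "x.tsv")

    def test_inverted_interval_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "channel": ["LA1"],
                "start_sample": [200],
                "end_sample": [100],
                "label": [str(ClassLabel.ARTIFACT)],
            }
        )
        with pytest.raises(ValueError, match="start < end"):
            write_annotations(df, tmp_path / "x.tsv")


class TestSegmentRecord:
    def _annotations(self, end_sample, channel="LA1"):
        return pd.DataFrame(
            {
                "channel": [channel],
                "start_sample": [0],
                "end_sample": [end_sample],
                "label": [str(ClassLabel.ARTIFACT)],
            }
        )

    @pytest.mark.parametrize(
        "interval_s,expected", [(9, 3), (8, 2), (2, 0)]
    )
    def test_tiling_drops_remainder(self, bundle, interval_s, expected):
        segs = segment_record(bundle, self._annotations(interval_s * 5000))
        assert len(segs) == expected
        for seg in segs:
            assert seg.n_samples == 15000
            assert seg.label is ClassLabel.ARTIFACT
            assert seg.channel_name == "LA1"

    def test_segments_carry_signal_content(self, bundle):
        segs = segment_record(bundle, self._annotations(30000))
        assert np.array_equal(segs[1].signal, bundle.signal[0, 15000:30000])

    def test_unknown_channel_rejected(self, bundle):
        with pytest.raises(ValueError, match="unknown channel"):
            segment_record(bundle, self._annotations(15000, channel="XX9"))

    def test_interval_beyond_recording_rejected(self, bundle):
        with pytest.raises(ValueError, match="exceeds"):
            segment_record(bundle, self._annotations(60000))


class TestProbabilityMatrixIO:
    def test_full_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        raw = rng.random(size=(3, 10, 3))
        raw /= raw.sum(axis=2, keepdims=True)
        pm = ProbabilityMatrix(raw, ["a", "b", "c"], GENERALIZED_CLASSES)
        path = tmp_path / "pm.tsv"
        write_probability_matrix(pm, path)
        back = read_probability_matrix(path)
        assert isinstance(back, ProbabilityMatrix)
        assert back.channel_names == pm.channel_names
        assert back.class_order == pm.class_order
        # >= 6 significant digits survive the text round-trip
        assert np.allclose(back.values, pm.values, rtol=1e-6, atol=1e-9)

    def test_binary_matrix_round_trip(self, tmp_path):
        binary = np.array([[0, 1, 1, 0], [1, 0, 0, 0], [0, 0, 0, 0]])
        path = tmp_path / "apm.tsv"
        write_probability_matrix(binary, path)
        values, channels = read_probability_matrix(path)
        assert np.array_equal(values, binary)
        assert len(channels) == 3

    def test_file_shape(self, tmp_path):
        rng = np.random.default_rng(4)
        raw = rng.random(size=(3, 10, 1))
        pm = ProbabilityMatrix(raw, ["a", "b", "c"], (ClassLabel.ARTIFACT,))
        path = tmp_path / "pm.tsv"
        write_probability_matrix(pm, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + 3  # header + one row per (channel, class)
        assert len(lines[0].split("\t")) == 2 + 10  # channel, class, 10 seconds

    def test_empty_matrix_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_probability_matrix(np.zeros((0, 0)), tmp_path / "x.tsv")


class TestModelCheckpoints:
    def test_round_trip_identical_forward(self, tiny_model_cfg, tmp_path):
        model = build_model(tiny_model_cfg, 0, GENERALIZED_CLASSES)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        x = np.random.default_rng(5).normal(size=(3, 2, 24)).astype(np.float32)
        assert np.array_equal(model.forward(x), back.forward(x))
        assert back.class_order == model.class_order

    def test_tampered_class_list_is_version_error(self, tiny_model_cfg, tmp_path):
        import json

        model = build_model(tiny_model_cfg, 0, GENERALIZED_CLASSES)
        path = tmp_path / "model.npz"
        save_model(model, path)
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        meta["class_order"] = meta["class_order"][:-1]  # drop one class
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **state,
        )
        with pytest.raises(VersionError, match="class list"):
            load_model(path)

    def test_four_class_checkpoint_loads_for_transfer(self, tiny_model_cfg, tmp_path):
        import dataclasses

        from ieegart.trainer import TrainConfig, transfer_retrain

        gm = build_model(tiny_model_cfg, 0, GENERALIZED_CLASSES)
        path = tmp_path / "gm.npz"
        save_model(gm, path)
        loaded = load_model(path)
        cfg4 = dataclasses.replace(tiny_model_cfg, n_classes=4)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 2, 24)).astype(np.float32)
        y = np.array([0, 1, 2, 3] * 2)
        adapted, _ = transfer_retrain(
            loaded,
            (x, y),
            (x, y),
            SPECIALIZED_CLASSES,
            TrainConfig(max_epochs=1, batch_size=4, rng_seed=0),
        )
        assert adapted.config.n_classes == 4

    def test_missing_checkpoint_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_model(tmp_path / "nope.npz")
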