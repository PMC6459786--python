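"""Detector geometry and event extraction: sliding-window layout, edge
replication, strict thresholding, run-length events vs brute force, and
rendering."""

from __future__ import annotations

import numpy as np
import pytest

from ieegart.cnn_model import ModelConfig, build_model
from ieegart.core import ClassLabel, GENERALIZED_CLASSES, SPECIALIZED_CLASSES
from ieegart.detector import (
    DetectionEvent,
    ProbabilityMatrix,
    binarize,
    classify_record,
    extract_events,
    render_matrix,
)
from ieegart.sigio import RecordingBundle
from ieegart.synthgen import SynthConfig, gen_physiological


@pytest.fixture(scope="module")
def probe_model():
    """An untrained (but deterministic) full-size 3-class model: geometry
    tests only need a fixed probability function of the input window."""
    return build_model(ModelConfig(n_classes=3), rng_seed=0)


def _bundle(n_channels: int, seconds: float, seed: int = 0) -> RecordingBundle:
    rng = np.random.default_rng(seed)
    n = int(seconds * 5000)
    return RecordingBundle(
        rng.normal(size=(n_channels, n)),
        5000.0,
        [f"ch{i}" for i in range(n_channels)],
    )


class TestClassifyRecord:
    def test_matrix_geometry_and_edge_replication(self, probe_model):
        """10 s -> 8 centered windows, 10 columns; the first column copies
        the first centered one and the last copies the final one."""
        pm = classify_record(probe_model, _bundle(2, 10))
        assert pm.values.shape == (2, 10, 3)
        assert np.allclose(pm.values.sum(axis=2), 1.0, atol=1e-6)
        assert np.array_equal(pm.values[:, 0], pm.values[:, 1])
        assert np.array_equal(pm.values[:, 9], pm.values[:, 8])
        # interior columns are genuinely window-dependent
        assert not np.array_equal(pm.values[:, 1], pm.values[:, 2])

    def test_exactly_three_seconds_gives_three_identical_columns(self, probe_model):
        pm = classify_record(probe_model, _bundle(1, 3))
        assert pm.values.shape == (1, 3, 3)
        assert np.array_equal(pm.values[:, 0], pm.values[:, 1])
        assert np.array_equal(pm.values[:, 1], pm.values[:, 2])

    def test_fractional_trailing_second_dropped(self, probe_model):
        pm = classify_record(probe_model, _bundle(1, 5.7))
        assert pm.n_seconds == 5

    def test_too_short_rejected(self, probe_model):
        with pytest.raises(ValueError, match="3 s"):
            classify_record(probe_model, _bundle(1, 2))

    def test_rate_mismatch_rejected(self, probe_model):
        bundle = RecordingBundle(np.zeros((1, 10000)), 1000.0, ["a"])
        with pytest.raises(ValueError, match="rate"):
            classify_record(probe_model, bundle)

    def test_channels_are_independent(self, probe_model):
        """Permuting channels permutes matrix rows only."""
        bundle = _bundle(3, 6, seed=3)
        pm = classify_record(probe_model, bundle)
        perm = [2, 0, 1]
        permuted = RecordingBundle(
            bundle.signal[perm], 5000.0, [bundle.channel_names[i] for i in perm]
        )
        pm_perm = classify_record(probe_model, permuted)
        assert np.allclose(pm_perm.values, pm.values[perm], atol=1e-6)

    def test_column_depends_only_on_its_window(self, probe_model):
        """Column t uses only samples in [t-1, t+2) s of that channel."""
        bundle = _bundle(1, 8, seed=4)
        pm = classify_record(probe_model, bundle)
        t = 4
        modified = bundle.signal.copy()
        modified[0, : (t - 1) * 5000] += 7.0  # outside the window
        modified[0, (t + 2) * 5000 :] -= 5.0
        pm2 = classify_record(
            probe_model, RecordingBundle(modified, 5000.0, ["ch0"])
        )
        assert np.allclose(pm2.values[0, t], pm.values[0, t], atol=1e-6)
        assert not np.allclose(pm2.values[0, t - 2], pm.values[0, t - 2], atol=1e-3)


def _matrix_from_plane(plane: np.ndarray, label=ClassLabel.ARTIFACT) -> ProbabilityMatrix:
    """Embed a 2-D probability plane for one class into a 3-class matrix."""
    plane = np.asarray(plane, dtype=np.float64)
    rest = (1.0 - plane) / 2.0
    values = np.stack([plane, rest, rest], axis=2)
    order = (label, ClassLabel.PHYSIOLOGICAL, ClassLabel.PATHOLOGICAL)
    return ProbabilityMatrix(
        values, [f"ch{i}" for i in range(plane.shape[0])], order
    )


class TestBinarize:
    def test_strictly_greater_than_threshold(self):
        pm = _matrix_from_plane([[0.96, 0.95, 0.9501, 0.2]])
        assert binarize(pm, ClassLabel.ARTIFACT, 0.95).tolist() == [[1, 0, 1, 0]]

    def test_all_physiological_gives_zero_matrix(self, probe_model):
        segs = [gen_physiological(SynthConfig(rng_seed=s)) for s in range(4)]
        signal = np.concatenate([s.signal for s in segs])[None, :]
        pm = classify_record(probe_model, RecordingBundle(signal, 5000.0, ["a"]))
        # with threshold ~1 nothing can exceed it regardless of the model
        assert binarize(pm, ClassLabel.PHYSIOLOGICAL, 0.999999).sum() == 0

    def test_majority_class_at_half_threshold(self):
        pm = _matrix_from_plane([[0.6, 0.4]])
        assert binarize(pm, ClassLabel.ARTIFACT, 0.5).tolist() == [[1, 0]]

    def test_threshold_domain(self):
        pm = _matrix_from_plane([[0.5]])
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="threshold"):
                binarize(pm, ClassLabel.ARTIFACT, bad)

    def test_unknown_class_rejected(self):
        pm = _matrix_from_plane([[0.5]])
        with pytest.raises(ValueError, match="not in matrix"):
            binarize(pm, ClassLabel.LINE_NOISE_50)

    def test_apm_and_ppm_disjoint_above_half(self):
        rng = np.random.default_rng(0)
        values = rng.dirichlet(np.ones(3), size=(2, 20))
        pm = ProbabilityMatrix(values, ["a", "b"], GENERALIZED_CLASSES)
        apm = binarize(pm, ClassLabel.ARTIFACT, 0.95)
        ppm = binarize(pm, ClassLabel.PATHOLOGICAL, 0.95)
        assert (apm + ppm <= 1).all()


class TestExtractEvents:
    def test_run_length_example(self):
        row = np.array([[0, 1, 1, 1, 0, 1, 0]])
        events = extract_events(row, min_duration_s=1)
        spans = [(e.start_second, e.end_second) for e in events]
        assert spans == [(1, 4), (5, 6)]

    def test_min_duration_filters_short_runs(self):
        row = np.array([[0, 1, 1, 1, 0, 1, 0]])
        events = extract_events(row, min_duration_s=2)
        assert [(e.start_second, e.end_second) for e in events] == [(1, 4)]

    def test_empty_matrix_gives_no_events(self):
        assert extract_events(np.zeros((3, 10), dtype=int)) == []

    def test_peak_probability_recorded(self):
        plane = np.array([[0.2, 0.97, 0.99, 0.96, 0.1]])
        pm = _matrix_from_plane(plane)
        binary = binarize(pm, ClassLabel.ARTIFACT, 0.95)
        events = extract_events(
            binary, prob_matrix=pm, target_class=ClassLabel.ARTIFACT
        )
        assert len(events) == 1
        assert events[0].peak_probability == pytest.approx(0.99)
        assert events[0].channel_name == "ch0"

    def test_matches_brute_force_on_random_rows(self):
        """Run-length extraction agrees with an index-by-index
        enumeration oracle on random binary matrices."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            binary = (rng.random(size=(3, 30)) < 0.4).astype(int)
            min_dur = int(rng.integers(1, 4))
            events = extract_events(binary, min_duration_s=min_dur)
            expected = []
            for ch in range(3):
                run = 0
                for t in range(31):
                    if t < 30 and binary[ch, t]:
                        run += 1
                    else:
                        if run >= min_dur:
                            expected.append((f"ch{ch}", t - run, t))
                        run = 0
            got = [(e.channel_name, e.start_second, e.end_second) for e in events]
            assert got == expected


class TestEndToEndDetection:
    def test_injected_muscle_burst_detected(self, trained_model):
        """A 3-s muscle artifact injected into physiological background
        yields exactly one artifact event overlapping the injection."""
        from ieegart.synthgen import gen_artifact

        parts = []
        for s in range(8):
            cfg = SynthConfig(rng_seed=100 + s)
            if s == 3:
                parts.append(gen_artifact(cfg, variant="muscle").signal)
            else:
                parts.append(gen_physiological(cfg).signal)
        signal = np.concatenate(parts)[None, :]
        bundle = RecordingBundle(signal, 5000.0, ["probe"])
        pm = classify_record(trained_model, bundle)
        binary = binarize(pm, ClassLabel.ARTIFACT, 0.95)
        events = extract_events(
            binary, prob_matrix=pm, target_class=ClassLabel.ARTIFACT
        )
        # injected interval is seconds [9, 12); windows overlapping the burst
        # may extend the detection by up to a second on each side
        overlapping = [
            e for e in events if e.start_second < 12 and e.end_second > 9
        ]
        assert len(overlapping) == 1
        assert all(e.peak_probability > 0.95 for e in events)


class TestRenderMatrix:
    def test_binary_image_dimensions(self, tmp_path):
        from PIL import Image

        binary = np.zeros((5, 60), dtype=int)
        binary[2, 10:20] = 1
        path = tmp_path / "apm.png"
        render_matrix(binary, path)
        with Image.open(path) as img:
            assert img.size == (60, 5)  # (width, height)

    def test_all_zero_matrix_uniform_background(self, tmp_path):
        from PIL import Image

        path = tmp_path / "zero.png"
        render_matrix(np.zeros((3, 10), dtype=int), path)
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"))
        assert (arr == arr[0, 0]).all()

    def test_binary_and_probability_share_dimensions(self, tmp_path):
        from PIL import Image

        rng = np.random.default_rng(1)
        probs = rng.random(size=(4, 12))
        p1, p2 = tmp_path / "p.png", tmp_path / "b.png"
        render_matrix(probs, p1)
        render_matrix((probs > 0.5).astype(int), p2)
        with Image.open(p1) as a, Image.open(p2) as b:
            assert a.size == b.size == (12, 4)
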