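"""Substrate maps, Dice comparison, fixtures, and text I/O round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fibroegm.errors import DataError, ParameterError
from fibroegm.fixtures import biphasic_train, fixture_signals
from fibroegm.mapping import (
    FibroticPatch,
    MapPoint,
    SubstrateMap,
    dice,
    generate_synthetic_map,
    read_map,
    voltage_labels,
    write_map,
)


class TestDice:
    def test_identical_nonempty_sets_are_one(self):
        assert dice({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_sets_are_zero(self):
        assert dice({1, 2}, {3, 4}) == 0.0

    def test_by_definition(self):
        assert dice({1, 2, 3}, {2, 3, 4}) == pytest.approx(4.0 / 6.0)

    def test_both_empty_convention_one(self):
        assert dice(set(), set()) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30), max_size=20),
        b=st.sets(st.integers(0, 30), max_size=20),
    )
    def test_symmetric_and_bounded(self, a, b):
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        if a == b:
            assert d == 1.0


class TestVoltageLabels:
    def _pt(self, pid, p2p):
        return MapPoint(point_id=pid, x=0, y=0, p2p=p2p)

    def test_threshold_definition(self):
        pts = voltage_labels([self._pt(0, 0.49), self._pt(1, 0.51)])
        assert [p.voltage_label for p in pts] == ["low", "high"]

    def test_boundary_exactly_at_cutoff_is_high(self):
        (pt,) = voltage_labels([self._pt(0, 0.5)])
        assert pt.voltage_label == "high"

    def test_zero_cutoff_all_high(self):
        pts = voltage_labels([self._pt(0, 0.01)], cutoff_mv=0.0)
        assert pts[0].voltage_label == "high"

    def test_missing_p2p_rejected(self):
        with pytest.raises(DataError):
            voltage_labels([MapPoint(point_id=0, x=0, y=0)])


def _toy_factory(condition, rng):
    """Control points get clean wavelet trains, fibrotic points get
    low-amplitude fractionated ones."""
    if condition[0] == "fibrotic":
        x, _ = biphasic_train(n_wavelets=6, amplitude_mv=0.3,
                              baseline_sigma_mv=0.02, rng=rng)
    else:
        x, _ = biphasic_train(n_wavelets=4, amplitude_mv=2.0,
                              baseline_sigma_mv=0.02, rng=rng)
    return x


class TestGenerateSyntheticMap:
    def test_no_patches_all_non_fibrotic(self, rng):
        m = generate_synthetic_map([], _toy_factory, rng, grid_shape=(4, 4))
        assert all(p.true_binary == "non-fibrotic" for p in m.points)

    def test_patch_assigns_truth_and_determinism(self):
        patches = [FibroticPatch(center=(40.0, 40.0), radius=15.0,
                                 density="60", transmurality="2")]
        a = generate_synthetic_map(patches, _toy_factory,
                                   np.random.default_rng(5), grid_shape=(6, 6))
        b = generate_synthetic_map(patches, _toy_factory,
                                   np.random.default_rng(5), grid_shape=(6, 6))
        fib = a.point_set(lambda p: p.true_binary == "fibrotic")
        assert fib  # patch covers some grid points
        assert fib == b.point_set(lambda p: p.true_binary == "fibrotic")
        assert np.allclose(
            [p.p2p for p in a.points], [p.p2p for p in b.points]
        )

    def test_overlapping_patches_rejected(self, rng):
        patches = [
            FibroticPatch(center=(40, 40), radius=15, density="60",
                          transmurality="2"),
            FibroticPatch(center=(50, 40), radius=15, density="20",
                          transmurality="1"),
        ]
        with pytest.raises(ParameterError):
            generate_synthetic_map(patches, _toy_factory, rng)

    def test_empty_map_rejected(self):
        with pytest.raises(DataError):
            SubstrateMap(points=[])

    def test_map_write_read_roundtrip(self, rng, tmp_path):
        patches = [FibroticPatch(center=(40.0, 40.0), radius=15.0,
                                 density="60", transmurality="2")]
        m = generate_synthetic_map(patches, _toy_factory, rng,
                                   grid_shape=(5, 5))
        path = tmp_path / "map.json"
        write_map(m, path)
        back = read_map(path)
        assert back.map_id == m.map_id
        assert len(back.points) == len(m.points)
        for p, q in zip(m.points, back.points):
            assert p.point_id == q.point_id
            assert p.voltage_label == q.voltage_label
            assert p.true_binary == q.true_binary
            assert p.p2p == pytest.approx(q.p2p)


class TestFixtureSignals:
    def test_sinusoid_exact_values(self):
        x = fixture_signals("sinusoid",
                            {"freq_hz": 100.0, "duration_s": 2.5})
        assert len(x) == 5000
        t = np.arange(5000) / 2000.0
        assert np.allclose(x, np.sin(2 * np.pi * 100 * t))

    def test_biphasic_train_ground_truth_detectable(self, rng):
        from fibroegm.processing import detect_activity

        x, truth = fixture_signals("biphasic-train", {"n_wavelets": 4}, rng)
        assert len(truth) == 4
        assert len(detect_activity(x)) == 4

    def test_deterministic_under_seed(self):
        a = fixture_signals("white-noise", {"n": 1000},
                            np.random.default_rng(3))
        b = fixture_signals("white-noise", {"n": 1000},
                            np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ParameterError):
            fixture_signals("square-wave", {}, rng)


class TestTraceIO:
    def test_trace_roundtrip(self, rng, tmp_path):
        from fibroegm.io import read_traces, write_traces

        x = rng.normal(size=(3, 500))
        path = tmp_path / "traces.tsv"
        write_traces(path, x, fs=2000.0, ids=["e0", "e1", "e2"])
        back, fs, ids = read_traces(path)
        assert fs == 2000.0
        assert ids == ["e0", "e1", "e2"]
        assert np.allclose(back, x, atol=1e-4)

    def test_ar_model_roundtrip(self, tmp_path):
        from fibroegm.io import read_ar_model, write_ar_model
        from fibroegm.noise import DEFAULT_CLINICAL_AR

        path = tmp_path / "model.json"
        write_ar_model(path, DEFAULT_CLINICAL_AR)
        back = read_ar_model(path)
        assert back.order == DEFAULT_CLINICAL_AR.order
        assert np.allclose(back.coefficients, DEFAULT_CLINICAL_AR.coefficients)


class TestFieldContainer:
    def test_field_write_read_roundtrip(self, rng, tmp_path):
        from fibroegm.io import read_field, write_field
        from fibroegm.propagation import VmField

        data = rng.normal(-60, 20, size=(40, 8, 8, 2)).astype(np.float32)
        field = VmField(data=data, fs=2000.0, spacing=0.25)
        path = tmp_path / "field.npz"
        write_field(path, field)
        back = read_field(path)
        assert back.fs == field.fs
        assert back.spacing == field.spacing
        assert np.array_equal(back.data, field.data)


class TestEndToEndMapDemo:
    def test_predicted_map_recovers_ground_truth_patches(self):
        """A binary tree trained on the simulated library recovers the map's
        fibrotic patches (truth-vs-prediction Dice well above chance)."""
        from fibroegm.sweep import synthetic_map_demo

        substrate_map, report = synthetic_map_demo(seed=7, grid_shape=(6, 6))
        assert report["n_usable"] > 0
        assert report["dice_truth_prediction"] >= 0.5
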