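import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mislabel import (
    RenderConfig,
    TraceParams,
    inject_mislabels,
    make_nanopore_dataset,
    make_stand_in_dataset,
    render_segment,
    segment_trace,
    simulate_trace,
)


class TestSimulateTrace:
    def test_one_second_at_default_rate_has_250k_points(self):
        trace = simulate_trace(TraceParams(), duration_s=1.0, seed=0)
        assert len(trace.samples) == 250_000

    def test_no_events_no_noise_is_constant_baseline(self):
        p = TraceParams(event_rate=0.0, noise_sd=0.0, baseline=42.0)
        trace = simulate_trace(p, 0.5, sample_rate=1000.0, seed=0)
        np.testing.assert_array_equal(trace.samples, 42.0)

    def test_seed_determinism(self):
        p = TraceParams()
        a = simulate_trace(p, 2.0, 1000.0, seed=3).samples
        b = simulate_trace(p, 2.0, 1000.0, seed=3).samples
        c = simulate_trace(p, 2.0, 1000.0, seed=4).samples
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_event_free_mean_approaches_baseline(self):
        # law of large numbers on a pure-noise trace
        p = TraceParams(event_rate=0.0, noise_sd=2.0, baseline=100.0)
        trace = simulate_trace(p, 10.0, 10_000.0, seed=0)
        n = len(trace.samples)
        assert abs(trace.samples.mean() - 100.0) < 3 * 2.0 / np.sqrt(n)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(TraceParams(), duration_s=-1.0)
        with pytest.raises(ValueError):
            TraceParams(event_rate=-1.0)
        with pytest.raises(ValueError):
            TraceParams(dwell_mean=0.0)


class TestSegmentTrace:
    def test_120s_trace_gives_120_one_second_windows(self):
        trace = simulate_trace(TraceParams(), 120.0, 500.0, seed=0)
        assert len(segment_trace(trace, 1.0)) == 120

    def test_trailing_partial_window_dropped(self):
        trace = simulate_trace(TraceParams(), 10.7, 1000.0, seed=0)
        windows = segment_trace(trace, 1.0)
        assert len(windows) == 10
        assert all(len(w) == 1000 for w in windows)

    def test_concatenation_is_prefix_of_trace(self):
        trace = simulate_trace(TraceParams(), 5.3, 1000.0, seed=1)
        windows = segment_trace(trace, 1.0)
        np.testing.assert_array_equal(
            np.concatenate(windows), trace.samples[: 5 * 1000]
        )

    def test_segment_longer_than_trace_gives_empty_list(self):
        trace = simulate_trace(TraceParams(), 0.5, 1000.0, seed=0)
        assert segment_trace(trace, 1.0) == []


class TestRenderSegment:
    def test_output_shape_matches_config(self):
        window = np.full(500, 100.0)
        img = render_segment(window, RenderConfig(width=40, height=24))
        assert img.shape == (24, 40, 3)

    def test_identical_inputs_byte_identical_output(self):
        rng = np.random.default_rng(0)
        window = 100 + rng.normal(0, 2, 1000)
        cfg = RenderConfig()
        a, b = render_segment(window, cfg), render_segment(window, cfg)
        assert a.tobytes() == b.tobytes()

    def test_large_deflection_changes_pixels(self):
        flat = np.full(1000, 100.0)
        dipped = flat.copy()
        dipped[400:600] = 30.0
        cfg = RenderConfig()
        assert (render_segment(flat, cfg) != render_segment(dipped, cfg)).any()

    def test_out_of_limits_values_clip_with_warning(self):
        window = np.full(100, 500.0)
        with pytest.warns(UserWarning, match="clipped"):
            img = render_segment(window, RenderConfig(y_limits=(0, 120)))
        assert img.shape == (32, 32, 3)


class TestMakeNanoporeDataset:
    def test_per_class_counts_follow_durations(self):
        specs = {
            "single": (TraceParams(amplitude_mean=45), 9.0),
            "double": (TraceParams(amplitude_mean=80), 5.0),
            "empty": (TraceParams(amplitude_mean=15), 3.0),
        }
        ds = make_nanopore_dataset(specs, sample_rate=500.0, seed=0)
        assert len(ds) == 17
        counts = np.bincount(ds.assigned, minlength=3)
        by_name = dict(zip(ds.vocabulary.names, counts))
        assert by_name == {"single": 9, "double": 5, "empty": 3}

    def test_equal_durations_are_balanced(self):
        specs = {
            "a": (TraceParams(amplitude_mean=15), 4.0),
            "b": (TraceParams(amplitude_mean=80), 4.0),
        }
        ds = make_nanopore_dataset(specs, sample_rate=500.0, seed=0)
        assert len(ds) == 8
        assert (np.bincount(ds.assigned) == 4).all()

    def test_seed_reproducibility(self):
        specs = {
            "a": (TraceParams(), 3.0),
            "b": (TraceParams(amplitude_mean=80), 3.0),
        }
        d1 = make_nanopore_dataset(specs, 500.0, seed=5)
        d2 = make_nanopore_dataset(specs, 500.0, seed=5)
        assert d1.images.tobytes() == d2.images.tobytes()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            make_nanopore_dataset({"only": (TraceParams(), 3.0)}, 500.0)


class TestMakeStandInDataset:
    def test_counts(self):
        ds = make_stand_in_dataset(n_classes=10, per_class=20, seed=0)
        assert len(ds) == 200
        assert (np.bincount(ds.assigned) == 20).all()

    def test_zero_jitter_zero_noise_gives_identical_images(self):
        ds = make_stand_in_dataset(n_classes=3, per_class=4, jitter_sd=0, noise_sd=0, seed=0)
        for c in range(3):
            imgs = ds.images[ds.assigned == c]
            assert all(np.array_equal(imgs[0], im) for im in imgs[1:])

    def test_low_noise_classes_are_1nn_separable(self):
        from mislabel import extract_features, knn_evaluate

        ds = make_stand_in_dataset(n_classes=4, per_class=25, jitter_sd=0.5, noise_sd=0.02, seed=2)
        feats = extract_features(ds, "pixels")
        _, acc = knn_evaluate(feats, ds.assigned, k=1, test_fraction=0.25, seed=0)
        assert acc == 1.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            make_stand_in_dataset(n_classes=1)
        with pytest.raises(ValueError):
            make_stand_in_dataset(per_class=0)


class TestInjectMislabels:
    def test_changes_exactly_count_labels_never_to_self(self, small_dataset):
        noisy, rec = inject_mislabels(small_dataset, count=10, seed=3)
        changed = np.flatnonzero(noisy.assigned != small_dataset.assigned)
        assert len(changed) == 10 == rec.count
        assert set(changed) == rec.indices
        for i, orig, new in rec.flipped:
            assert orig != new
            assert noisy.assigned[i] == new
            assert noisy.true[i] == orig

    def test_count_zero_is_identity(self, small_dataset):
        noisy, rec = inject_mislabels(small_dataset, count=0, seed=0)
        np.testing.assert_array_equal(noisy.assigned, small_dataset.assigned)
        assert rec.count == 0

    def test_same_seed_same_flips_and_json_round_trip(self, small_dataset, tmp_path):
        _, r1 = inject_mislabels(small_dataset, 5, seed=9)
        _, r2 = inject_mislabels(small_dataset, 5, seed=9)
        assert r1.flipped == r2.flipped
        r1.to_json(tmp_path / "r.json")
        from mislabel import NoiseInjectionRecord

        assert NoiseInjectionRecord.from_json(tmp_path / "r.json").flipped == r1.flipped

    def test_count_exceeding_n_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            inject_mislabels(small_dataset, count=len(small_dataset) + 1)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(count=st.integers(0, 30), seed=st.integers(0, 2**31 - 1))
    def test_flip_invariants_hold_for_any_seed(self, count, seed):
        ds = make_stand_in_dataset(n_classes=3, per_class=10, seed=0)
        noisy, rec = inject_mislabels(ds, count, seed=seed)
        assert int((noisy.assigned != ds.assigned).sum()) == count
        assert all(a != b for _, a, b in rec.flipped)
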