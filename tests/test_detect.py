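import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazescreen import (
    DetectorConfig,
    binocular_signals,
    classify_directions,
    detect_events,
    rms_noise,
    segment_events,
    simulate_recording,
)
from gazescreen.simulate import HR_DEFAULT_PARAMS, LR_DEFAULT_PARAMS, noiseless
from .conftest import make_recording


class TestBinocularSignals:
    def test_hand_arithmetic(self):
        rec = make_recording([0.0, 0.0])
        rec.pos[0] = [1.0, 2.0, 3.0, 4.0]  # lx, ly, rx, ry
        sig = binocular_signals(rec)
        assert sig.hor_version[0] == 2.0
        assert sig.vert_version[0] == 3.0
        assert sig.hor_vergence[0] == -2.0
        assert sig.vert_vergence[0] == -2.0

    def test_equal_eyes_give_zero_vergence(self):
        rec = make_recording(np.linspace(0, 3, 20), np.linspace(0, 1, 20))
        sig = binocular_signals(rec)
        assert np.all(sig.hor_vergence == 0)
        assert np.all(sig.vert_vergence == 0)
        assert np.allclose(sig.hor_version, rec.pos[:, 0])

    def test_one_invalid_eye_poisons_all_series(self):
        valid = np.ones((10, 2), dtype=bool)
        valid[4, 0] = False
        rec = make_recording(np.zeros(10), valid=valid)
        sig = binocular_signals(rec)
        assert not sig.usable[4]
        for series in sig.series().values():
            assert np.isnan(series[4])


class TestRmsNoise:
    def test_constant_series_is_zero(self):
        assert rms_noise(np.full(50, 3.3), idx=49) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_plus_minus_a(self):
        # balanced +/-a window: mean 0, so RMS deviation equals a exactly
        a = 0.7
        series = a * np.resize([1.0, -1.0], 26)
        assert rms_noise(series, idx=25, window=26) == pytest.approx(a)

    def test_first_sample_bootstraps_to_zero(self):
        assert rms_noise(np.array([5.0, 1.0]), idx=0) == 0.0

    def test_window_restricts_history(self):
        # large outlier outside the window is ignored
        series = np.concatenate([[100.0], np.zeros(30)])
        assert rms_noise(series, idx=30, window=25) == 0.0


class TestSegmentation:
    def test_constant_signal_is_one_fixation(self):
        rec = make_recording(np.zeros(100))
        events = segment_events(rec)
        assert [e.kind for e in events] == ["fixation"]
        assert (events[0].start_idx, events[0].end_idx) == (0, 99)

    def test_all_invalid_is_one_distortion(self):
        rec = make_recording(np.zeros(50), valid=np.zeros((50, 2), dtype=bool))
        events = segment_events(rec)
        assert [e.kind for e in events] == ["distortion"]
        assert events[0].n_samples == 50

    def test_too_short_recording_warns_and_is_empty(self):
        rec = make_recording(np.zeros(4))
        with pytest.warns(UserWarning, match="shorter than min_fixation"):
            assert segment_events(rec) == []

    def test_short_stable_run_is_transient(self):
        # 5 stable samples (40 ms span) then a jump: below the 50 ms rule
        x = np.concatenate([np.zeros(5), [1.5], np.full(20, 2.5)])
        events = segment_events(make_recording(x))
        assert [e.kind for e in events] == ["transient", "saccade", "fixation"]
        # 6 stable samples span exactly 50 ms: promoted to fixation
        x = np.concatenate([np.zeros(6), [1.5], np.full(20, 2.5)])
        events = segment_events(make_recording(x))
        assert [e.kind for e in events][0] == "fixation"

    def test_distortion_interrupts_run_without_merging(self):
        valid = np.ones((30, 2), dtype=bool)
        valid[12:15] = False
        events = segment_events(make_recording(np.zeros(30), valid=valid))
        assert [e.kind for e in events] == ["fixation", "distortion", "fixation"]

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("group", [HR_DEFAULT_PARAMS, LR_DEFAULT_PARAMS])
    def test_noiseless_oracle_matches_ground_truth(self, group, seed, small_layout):
        rec = simulate_recording(noiseless(group), small_layout, seed=seed)
        detected = detect_events(rec)
        truth = rec.ground_truth
        assert [
            (e.kind, e.direction, e.start_idx, e.end_idx) for e in detected
        ] == [(e.kind, e.direction, e.start_idx, e.end_idx) for e in truth]

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_events_tile_and_are_exclusive(self, seed, small_layout):
        rec = simulate_recording(HR_DEFAULT_PARAMS, small_layout, seed=seed)
        events = detect_events(rec)
        idx = 0
        for e in events:
            assert e.start_idx == idx, "gap or overlap between events"
            assert e.kind in {"fixation", "saccade", "sweep", "transient", "distortion"}
            idx = e.end_idx + 1
        assert idx == len(rec)

    def test_threshold_monotonicity(self, small_layout):
        rec = simulate_recording(LR_DEFAULT_PARAMS, small_layout, seed=2)
        counts = []
        for base in (0.3, 0.5, 0.8, 1.2):
            cfg = DetectorConfig(dispersion_base=base)
            counts.append(
                sum(e.kind == "saccade" for e in segment_events(rec, cfg))
            )
        assert counts == sorted(counts, reverse=True)


class TestDirections:
    @staticmethod
    def _rec(*segments):
        return make_recording(np.concatenate(segments))

    def test_rightward_saccade_is_progressive(self):
        rec = self._rec(np.zeros(10), [1.5], np.full(10, 2.5))
        events = detect_events(rec)
        assert [(e.kind, e.direction) for e in events] == [
            ("fixation", "none"),
            ("saccade", "progressive"),
            ("fixation", "progressive"),
        ]

    def test_small_leftward_is_regressive(self):
        rec = self._rec(np.full(10, 2.5), [1.0], np.zeros(10))
        events = detect_events(rec)
        assert events[1].kind == "saccade"
        assert events[1].direction == "regressive"
        assert events[2].direction == "regressive"

    def test_large_leftward_is_sweep_and_next_fixation_progressive(self):
        rec = self._rec(np.full(10, 12.0), [8.0, 3.0], np.zeros(10))
        events = detect_events(rec)
        assert [(e.kind, e.direction) for e in events] == [
            ("fixation", "none"),
            ("sweep", "none"),
            ("fixation", "progressive"),
        ]

    def test_alternating_progressive_saccades(self):
        parts = [np.zeros(10)]
        x = 0.0
        for _ in range(4):
            parts += [[x + 1.2], np.full(10, x + 2.0)]
            x += 2.0
        events = detect_events(self._rec(*parts))
        fixations = [e for e in events if e.kind == "fixation"]
        assert fixations[0].direction == "none"
        assert all(f.direction == "progressive" for f in fixations[1:])


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=40))
def test_rms_noise_nonnegative_and_shift_invariant(values):
    series = np.array(values)
    r = rms_noise(series, idx=len(series) - 1)
    assert r >= 0
    assert rms_noise(series + 5.0, idx=len(series) - 1) == pytest.approx(r, abs=1e-9)
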