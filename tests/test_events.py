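"""Unit and property tests for the four event detectors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazekit.events import (
    DegenerateVelocityError,
    DetectionConfig,
    GazeTrace,
    PupilTrace,
    compute_dispersion,
    compute_ms_threshold,
    compute_ms_velocity,
    detect_blinks,
    detect_fixations_idt,
    detect_microsaccades,
    detect_saccades_ivt,
    smooth_pupil,
)
from gazekit.fixtures import generate_trial
from gazekit.parameters import detect_all_events

from conftest import fix_sacc_blink_plan, ms_plan


def make_gaze(x, y=None, sfreq=1000.0):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return GazeTrace(x, y, np.arange(len(x)) * 1000.0 / sfreq, sfreq)


# ---------------------------------------------------------------------------
# blinks
# ---------------------------------------------------------------------------


class TestBlinks:
    def test_refinement_extends_into_descending_flank(self, cfg):
        # hand-traced: smoothed means are [4.25,4.25,4.25,4.0,4.0,4.14...],
        # so the onset walks back from the last valid sample (index 3)
        # to index 2, before the first '3'
        v = [5, 5, 4, 3, np.nan, np.nan, np.nan, 3, 4, 5, 5]
        p = PupilTrace(v, np.arange(11.0), 1000.0)
        blinks = detect_blinks(p, cfg)
        assert len(blinks) == 1
        assert blinks[0].onset_index == 2
        assert blinks[0].offset_index == 7

    def test_no_gaps_yields_no_blinks(self, cfg):
        p = PupilTrace(np.full(100, 7.0), np.arange(100.0), 1000.0)
        assert detect_blinks(p, cfg) == []

    def test_two_gaps_yield_two_disjoint_blinks(self, cfg):
        v = np.full(200, 50.0)
        v[40:50] = np.nan
        v[140:160] = np.nan
        p = PupilTrace(v, np.arange(200.0), 1000.0)
        blinks = detect_blinks(p, cfg)
        assert len(blinks) == 2
        assert blinks[0].offset_index < blinks[1].onset_index

    def test_refinement_never_shrinks_initial_window(self, cfg):
        rng = np.random.default_rng(5)
        v = 100 + rng.normal(0, 2, 500)
        v[100:140] = np.nan
        v[300:310] = np.nan
        p = PupilTrace(v, np.arange(500.0), 1000.0)
        for b, (a0, b0) in zip(detect_blinks(p, cfg), [(99, 140), (299, 310)]):
            assert b.onset_index <= a0
            assert b.offset_index >= b0

    def test_all_missing_is_one_spanning_blink(self, cfg):
        p = PupilTrace(np.full(50, np.nan), np.arange(50.0), 1000.0)
        with pytest.warns(UserWarning):
            blinks = detect_blinks(p, cfg)
        assert len(blinks) == 1
        assert (blinks[0].onset_index, blinks[0].offset_index) == (0, 49)

    def test_smoothing_impulse_support_is_10_samples_at_1khz(self):
        impulse = np.zeros(100)
        impulse[50] = 1.0
        out = smooth_pupil(impulse, 1000.0, 10.0)
        assert int(np.count_nonzero(out)) == 10


# ---------------------------------------------------------------------------
# dispersion / I-DT
# ---------------------------------------------------------------------------


def idt_oracle(x, y, w, d_thresh):
    """Straightforward re-execution of the windowing loop with plain
    Python loops and explicit range arithmetic."""

    def disp(lo, hi):  # [lo, hi)
        xs, ys = x[lo:hi], y[lo:hi]
        return math.hypot(max(xs) - min(xs), max(ys) - min(ys))

    n = len(x)
    segs = []
    i = 0
    while i + w <= n:
        if disp(i, i + w) > d_thresh:
            i += 1
            continue
        j = i + w
        while j < n and disp(i, j + 1) <= d_thresh:
            j += 1
        if j < n:
            segs.append((i, j - 1))  # breaking sample j excluded
            i = j
        else:
            segs.append((i, n - 1))
            i = n
    return segs


class TestDispersion:
    def test_three_four_five(self):
        assert compute_dispersion([0, 3, 0], [0, 0, 4]) == pytest.approx(5.0)

    def test_single_point_is_zero(self):
        assert compute_dispersion([2.0], [3.0]) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_dispersion([], [])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_ranges(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 100, 20), rng.uniform(0, 100, 20)
        brute = math.sqrt(
            (max(x) - min(x)) ** 2 + (max(y) - min(y)) ** 2
        )
        assert compute_dispersion(x, y) == pytest.approx(brute)


class TestIDT:
    def test_single_station_then_jump(self, cfg):
        x = np.concatenate([np.full(60, 100.0), np.full(10, 600.0)])
        y = np.concatenate([np.full(60, 100.0), np.full(10, 600.0)])
        fixations = detect_fixations_idt(make_gaze(x, y), cfg)
        assert len(fixations) == 1
        f = fixations[0]
        assert f.offset_index - f.onset_index + 1 >= 59
        assert (f.centroid_x, f.centroid_y) == (100.0, 100.0)

    def test_pure_noise_gives_no_fixations(self, cfg):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1000, 300)
        y = rng.uniform(0, 1000, 300)
        assert detect_fixations_idt(make_gaze(x, y), cfg) == []

    def test_trace_shorter_than_window_is_empty(self, cfg):
        assert detect_fixations_idt(make_gaze(np.zeros(10)), cfg) == []

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_segmentation_matches_bruteforce_loop(self, seed):
        cfg = DetectionConfig()
        rng = np.random.default_rng(seed)
        # random walk with occasional jumps: realistic mix of stations
        steps = rng.normal(0, 2, (400, 2))
        jumps = rng.random(400) < 0.02
        steps[jumps] += rng.uniform(-200, 200, (jumps.sum(), 2))
        x, y = np.cumsum(steps, axis=0).T
        got = [
            (f.onset_index, f.offset_index)
            for f in detect_fixations_idt(make_gaze(x, y), cfg)
        ]
        assert got == idt_oracle(list(x), list(y), 50, cfg.d_thresh_px)

    def test_every_fixation_at_least_w_thresh_samples(self, cfg):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0, 3, 1000))
        y = np.cumsum(rng.normal(0, 3, 1000))
        for f in detect_fixations_idt(make_gaze(x, y), cfg):
            assert f.offset_index - f.onset_index + 1 >= 50


# ---------------------------------------------------------------------------
# I-VT saccades
# ---------------------------------------------------------------------------


class TestIVT:
    def test_constant_gaze_has_no_saccades(self, cfg):
        assert detect_saccades_ivt(make_gaze(np.full(100, 5.0)), cfg) == []

    def test_single_jump_is_one_sample_saccade(self, cfg):
        x = np.concatenate([np.zeros(10), np.full(10, 100.0)])
        saccades = detect_saccades_ivt(make_gaze(x), cfg)
        assert len(saccades) == 1
        s = saccades[0]
        assert (s.onset_index, s.offset_index) == (9, 10)
        assert s.peak_velocity == pytest.approx(100_000.0)
        assert s.amplitude == pytest.approx(100.0)

    def test_detection_invariant_to_joint_velocity_threshold_rescale(self):
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.normal(0, 1, 500))
        base = detect_saccades_ivt(make_gaze(x), DetectionConfig())
        scaled = detect_saccades_ivt(
            make_gaze(7.0 * x), DetectionConfig(ivt_vel_thresh=7.0 * 40.0)
        )
        assert [(s.onset_index, s.offset_index) for s in base] == [
            (s.onset_index, s.offset_index) for s in scaled
        ]


# ---------------------------------------------------------------------------
# microsaccades
# ---------------------------------------------------------------------------


class TestMsVelocity:
    def test_constant_gaze_is_zero(self):
        assert compute_ms_velocity(np.full(20, 3.0), 1000.0) == pytest.approx(0.0)

    def test_unit_ramp_interior_value(self):
        v = compute_ms_velocity(np.arange(20.0), 1000.0)
        assert v[2:-2] == pytest.approx(6.0 / 6000.0)
        assert v[:2] == pytest.approx(0.0) and v[-2:] == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_stencil(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, 5, 40)
        v = compute_ms_velocity(g, 500.0)
        for t in range(2, 38):
            expect = (g[t + 2] + g[t + 1] - g[t - 1] - g[t - 2]) / (6 * 500.0)
            assert v[t] == pytest.approx(expect)

    def test_engbert_units_rescale(self):
        g = np.random.default_rng(1).normal(0, 5, 30)
        a = compute_ms_velocity(g, 1000.0)
        b = compute_ms_velocity(g, 1000.0, engbert_units=True)
        assert b == pytest.approx(a * 1000.0**2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_ms_velocity(np.zeros(4), 1000.0)


class TestMsThreshold:
    def test_alternating_unit_vector_gives_v_fac(self):
        v = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert compute_ms_threshold(v, 5.0) == pytest.approx(5.0)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateVelocityError):
            compute_ms_threshold(np.full(10, 2.0), 5.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_medians(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 1, 31)
        med = sorted(v)[15]
        dev2 = sorted((u - med) ** 2 for u in v)[15]
        assert compute_ms_threshold(v, 5.0) == pytest.approx(5.0 * math.sqrt(dev2))


class TestMicrosaccades:
    @staticmethod
    def _fixation_segment(seed=2, n=400, excursion=None):
        rng = np.random.default_rng(seed)
        x = 640 + rng.normal(0, 0.4, n)
        y = 512 + rng.normal(0, 0.4, n)
        if excursion is not None:
            a, length, amp = excursion
            prof = amp * (1 - np.cos(np.pi * np.linspace(0, 1, length))) / 2
            x[a : a + length] += prof
            x[a + length :] += amp
        return make_gaze(x, y)

    def test_minimum_run_length_boundary(self):
        # sweeping excursion lengths: a detection appears exactly when the
        # supra-threshold run (recomputed brute force) reaches 6 samples
        import itertools

        cfg = DetectionConfig(ms_min_samples=6)
        seen_below = seen_at_or_above = False
        for length in range(3, 14):
            gaze = self._fixation_segment(excursion=(200, length, 25.0))
            vx = compute_ms_velocity(gaze.x, 1000.0)
            vy = compute_ms_velocity(gaze.y, 1000.0)
            k = (vx / compute_ms_threshold(vx, 5.0)) ** 2 + (
                vy / compute_ms_threshold(vy, 5.0)
            ) ** 2
            longest = max(
                (len(list(g)) for v, g in itertools.groupby(k > 1) if v), default=0
            )
            detected = detect_microsaccades(gaze, cfg)
            if longest < 6:
                assert detected == []
                seen_below = True
            else:
                assert len(detected) >= 1
                seen_at_or_above = True
        assert seen_below and seen_at_or_above

    def test_elliptic_criterion_boundary(self):
        # equal per-axis velocity at threshold gives k = 2 > 1
        assert (1.0 / 1.0) ** 2 + (1.0 / 1.0) ** 2 > 1

    def test_planted_excursion_detected_once(self):
        cfg = DetectionConfig()
        gaze = self._fixation_segment(excursion=(200, 14, 18.0))
        ms = detect_microsaccades(gaze, cfg)
        assert len(ms) == 1
        assert abs(ms[0].onset_index - 200) <= 2

    def test_degenerate_threshold_warns_empty(self):
        cfg = DetectionConfig()
        gaze = make_gaze(np.full(100, 640.0), np.full(100, 512.0))
        with pytest.warns(UserWarning):
            assert detect_microsaccades(gaze, cfg) == []

    def test_scale_free_detection(self):
        cfg = DetectionConfig()
        gaze = self._fixation_segment(excursion=(150, 14, 18.0))
        scaled = make_gaze(gaze.x * 3.0, gaze.y * 3.0)
        a = detect_microsaccades(gaze, cfg)
        b = detect_microsaccades(scaled, cfg)
        assert [(m.onset_index, m.offset_index) for m in a] == [
            (m.onset_index, m.offset_index) for m in b
        ]


# ---------------------------------------------------------------------------
# planted-event recovery
# ---------------------------------------------------------------------------


class TestRecovery:
    def test_zero_noise_counts_exact(self, clean_trial, cfg):
        trial, truth = clean_trial
        detected = detect_all_events(trial, cfg)
        assert len(detected["fixation"]) == len(truth.of_kind("fixation")) == 3
        assert len(detected["saccade"]) == len(truth.of_kind("saccade")) == 1
        assert len(detected["blink"]) == len(truth.of_kind("blink")) == 1

    def test_zero_noise_saccade_amplitude_within_10pct(self, clean_trial, cfg):
        trial, truth = clean_trial
        planted = truth.of_kind("saccade")[0]["plan"]
        expected = math.hypot(
            planted.end[0] - planted.start[0], planted.end[1] - planted.start[1]
        )
        s = detect_all_events(trial, cfg)["saccade"][0]
        assert s.amplitude == pytest.approx(expected, rel=0.10)

    def test_noisy_fixation_and_blink_boundaries_within_10ms(self, noisy_trial, cfg):
        trial, truth = noisy_trial
        detected = detect_all_events(trial, cfg)
        for planted in truth.of_kind("fixation"):
            hit = min(
                detected["fixation"],
                key=lambda f: abs(f.onset_index - planted["onset_index"]),
            )
            assert abs(hit.onset_index - planted["onset_index"]) <= 10
        for planted in truth.of_kind("blink"):
            hit = detected["blink"][0]
            assert abs(hit.onset_index - planted["onset_index"]) <= 10
            assert abs(hit.offset_index - planted["offset_index"]) <= 10

    def test_noisy_microsaccade_onset_within_2_samples(self, cfg):
        trial, truth = generate_trial(ms_plan(), 1000, seed=21)
        detected = detect_all_events(trial, cfg)
        planted = truth.of_kind("microsaccade")[0]
        hits = [
            m
            for m in detected["microsaccade"]
            if abs(m.onset_index - planted["onset_index"]) <= 2
        ]
        assert len(hits) == 1

    def test_events_sorted_and_nonoverlapping(self, noisy_trial, cfg):
        detected = detect_all_events(noisy_trial[0], cfg)
        for kind in ("blink", "fixation", "saccade", "microsaccade"):
            evs = detected[kind]
            for a, b in zip(evs, evs[1:]):
                assert a.offset_index < b.onset_index
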