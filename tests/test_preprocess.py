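"""Preprocessing: gap filling, binocular merge, fixation detection, AOIs,
trial validity."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from traitgaze.geometry import AOISet, Rect
from traitgaze.preprocess import (Fixation, PreprocessParams,
                                  detect_fixations, detect_fixations_idt,
                                  interpolate_gaps, merge_binocular,
                                  validate_trial)

from _oracles import idt_oracle
from conftest import make_fixations

DT = 1000.0 / 300.0


def _frame(t, lx, ly, lv, rx=None, ry=None, rv=None):
    lx = np.asarray(lx, dtype=float)
    ly = np.asarray(ly, dtype=float)
    return pd.DataFrame({
        "t_ms": np.asarray(t, dtype=float),
        "lx_px": lx, "ly_px": ly, "l_valid": np.asarray(lv, dtype=bool),
        "rx_px": lx if rx is None else np.asarray(rx, dtype=float),
        "ry_px": ly if ry is None else np.asarray(ry, dtype=float),
        "r_valid": (np.asarray(lv, dtype=bool) if rv is None
                    else np.asarray(rv, dtype=bool)),
    })


class TestInterpolation:
    def test_midpoint_fill(self):
        t = [0.0, 30.0, 60.0]
        df = _frame(t, [100, np.nan, 160], [200, np.nan, 260],
                    [True, False, True])
        out = interpolate_gaps(df, max_gap=75.0)
        assert out.loc[1, "lx_px"] == pytest.approx(130.0)
        assert out.loc[1, "ly_px"] == pytest.approx(230.0)
        assert bool(out.loc[1, "l_valid"])

    def test_gap_longer_than_max_left_unfilled(self):
        t = [0.0, 25.0, 50.0, 75.0, 100.0]
        lv = [True, False, False, False, True]
        df = _frame(t, [0, np.nan, np.nan, np.nan, 10],
                    [0, np.nan, np.nan, np.nan, 10], lv)
        out = interpolate_gaps(df, max_gap=75.0)
        assert not out["l_valid"][1:4].any()

    def test_edge_runs_untouched(self):
        df = _frame([0.0, 10.0, 20.0], [np.nan, 5, 6], [np.nan, 5, 6],
                    [False, True, True])
        out = interpolate_gaps(df)
        assert not bool(out.loc[0, "l_valid"])

    def test_fully_valid_identity(self):
        df = _frame([0.0, 10.0], [1, 2], [3, 4], [True, True])
        out = interpolate_gaps(df)
        pd.testing.assert_frame_equal(out, df)

    def test_unordered_timestamps_rejected(self):
        df = _frame([0.0, 0.0], [1, 2], [3, 4], [True, True])
        with pytest.raises(ValueError):
            interpolate_gaps(df)

    @given(hst.lists(hst.booleans(), min_size=3, max_size=60),
           hst.integers(0, 2 ** 31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_interpolation_properties(self, validity, seed):
        """Valid samples never change; only bridgeable short gaps fill."""
        rng = np.random.default_rng(seed)
        n = len(validity)
        t = np.arange(n) * DT
        x = rng.uniform(0, 1920, n)
        y = rng.uniform(0, 1080, n)
        v = np.array(validity)
        x[~v] = np.nan
        y[~v] = np.nan
        df = _frame(t, x, y, v)
        out = interpolate_gaps(df, max_gap=75.0)
        ov = out["l_valid"].to_numpy()
        # valid count non-decreasing; original valid samples untouched
        assert ov.sum() >= v.sum()
        assert (ov | ~v).all()
        np.testing.assert_array_equal(out.loc[v, "lx_px"], df.loc[v, "lx_px"])
        # every filled run is bounded by originally-valid samples <= 75 ms apart
        i = 0
        while i < n:
            if v[i] or not ov[i]:
                i += 1
                continue
            j = i
            while j < n and not v[j] and ov[j]:
                j += 1
            assert i > 0 and j < n
            assert t[j] - t[i - 1] <= 75.0
            i = j

    def test_interpolation_eyes_independent(self):
        df = _frame([0.0, 30.0, 60.0], [100, np.nan, 160], [0, np.nan, 0],
                    [True, False, True],
                    rx=[0, 50, 100], ry=[0, 0, 0], rv=[True, True, True])
        out = interpolate_gaps(df)
        assert out.loc[1, "rx_px"] == 50  # untouched valid right eye


class TestBinocularMerge:
    def test_both_eyes_mean(self):
        df = _frame([0.0], [100], [200], [True], rx=[110], ry=[210],
                    rv=[True])
        out = merge_binocular(df)
        assert out.loc[0, "x_px"] == 105 and out.loc[0, "y_px"] == 205
        assert bool(out.loc[0, "valid"])

    def test_single_eye_fallback(self):
        df = _frame([0.0], [np.nan], [np.nan], [False], rx=[300], ry=[400],
                    rv=[True])
        out = merge_binocular(df)
        assert out.loc[0, "x_px"] == 300 and out.loc[0, "y_px"] == 400
        assert bool(out.loc[0, "valid"])

    def test_both_invalid(self):
        df = _frame([0.0], [np.nan], [np.nan], [False], rx=[np.nan],
                    ry=[np.nan], rv=[False])
        out = merge_binocular(df)
        assert not bool(out.loc[0, "valid"])
        assert np.isnan(out.loc[0, "x_px"])


def _cyclo(t, x, y, valid=None):
    n = len(t)
    return pd.DataFrame({
        "t_ms": np.asarray(t, dtype=float),
        "x_px": np.asarray(x, dtype=float),
        "y_px": np.asarray(y, dtype=float),
        "valid": np.ones(n, bool) if valid is None else np.asarray(valid, bool),
    })


class TestFixationDetection:
    def test_constant_gaze_single_fixation(self):
        n = 60  # 200 ms at 300 Hz
        df = _cyclo(np.arange(n) * DT, np.full(n, 500.0), np.full(n, 500.0))
        fx = detect_fixations(df)
        assert len(fx) == 1
        assert fx[0].duration == pytest.approx(200.0)
        assert (fx[0].cx, fx[0].cy) == (500.0, 500.0)

    def test_two_clusters_two_fixations(self):
        t = np.arange(96) * DT  # 150 ms + 3-sample transit + 150 ms
        x = np.concatenate([np.full(45, 400.0),
                            [470.0, 530.0, 590.0],
                            np.full(48, 600.0)])
        y = np.full(96, 500.0)
        fx = detect_fixations(_cyclo(t, x, y))
        assert len(fx) == 2
        assert fx[0].cx == pytest.approx(400.0)
        assert fx[1].cx == pytest.approx(600.0, abs=1.0)
        oracle = idt_oracle(t, x, y, np.ones(96, bool),
                            PreprocessParams().dispersion_px, 60.0)
        assert [(f.onset, f.offset) for f in fx] == [
            (o[0], o[1]) for o in oracle]

    def test_short_burst_below_minimum(self):
        n = 12  # 40 ms
        df = _cyclo(np.arange(n) * DT, np.full(n, 500.0), np.full(n, 500.0))
        assert detect_fixations(df) == []

    def test_empty_input(self):
        assert detect_fixations(_cyclo([], [], [])) == []

    def test_invalid_samples_break_windows(self):
        n = 90
        valid = np.ones(n, bool)
        valid[40:45] = False
        df = _cyclo(np.arange(n) * DT, np.full(n, 500.0), np.full(n, 500.0),
                    valid)
        fx = detect_fixations(df)
        assert len(fx) == 2
        assert fx[0].offset <= fx[1].onset

    @given(hst.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        t = np.arange(n) * DT
        # piecewise-stationary walk with jumps and dropouts
        x = np.cumsum(rng.choice([0.0, 0.0, 0.0, 80.0], n) - 20 * 0)
        x = x + rng.normal(0, 8, n) + 500
        y = 500 + rng.normal(0, 8, n)
        valid = rng.random(n) > 0.1
        params = PreprocessParams()
        fast = detect_fixations_idt(t, x, y, valid, params.dispersion_px,
                                    params.min_fix_ms)
        slow = idt_oracle(t, x, y, valid, params.dispersion_px,
                          params.min_fix_ms)
        assert [(f.onset, f.offset, f.cx, f.cy) for f in fast] == slow

    def test_fixation_invariants_on_random_trace(self):
        rng = np.random.default_rng(3)
        n = 900
        x = 500 + np.repeat(rng.uniform(-300, 300, 30), 30) + rng.normal(0, 5, n)
        y = 400 + np.repeat(rng.uniform(-200, 200, 30), 30) + rng.normal(0, 5, n)
        fx = detect_fixations(_cyclo(np.arange(n) * DT, x, y))
        assert fx, "expected fixations on a piecewise-stationary trace"
        for f in fx:
            assert f.duration >= 60.0
        for a, b in zip(fx, fx[1:]):
            assert a.offset <= b.onset + 1e-6  # disjoint and ordered

    def test_ivt_mode_detects_stationary_run(self):
        n = 120
        x = np.concatenate([np.full(60, 400.0), np.full(60, 900.0)])
        df = _cyclo(np.arange(n) * DT, x, np.full(n, 500.0))
        fx = detect_fixations(df, PreprocessParams(algorithm="ivt"))
        assert len(fx) == 2

    def test_unknown_algorithm_rejected(self):
        df = _cyclo([0.0, DT], [0, 0], [0, 0])
        with pytest.raises(ValueError):
            detect_fixations(df, PreprocessParams(algorithm="idk"))


class TestAOI:
    def test_nested_labels_and_half_open_edges(self):
        aois = AOISet.default()
        e = aois.eyes_rect
        cx, cy = (e.x0 + e.x1) / 2, (e.y0 + e.y1) / 2
        assert aois.label(cx, cy) == "eyes"
        assert aois.label(cx, aois.face_rect.y1 - 1.0) == "face"
        assert aois.label(5.0, 5.0) == "off"
        # exactly on the eyes-band bottom edge -> face (half-open intervals)
        assert aois.label(cx, e.y1) == "face"
        # the band spans the face width, so its right edge is also the
        # face's right edge: half-open on both -> off
        assert aois.label(e.x1, cy) == "off"

    def test_eyes_must_nest_in_face(self):
        face = Rect(100, 100, 200, 200)
        with pytest.raises(ValueError):
            AOISet(eyes_rect=Rect(50, 120, 150, 140), face_rect=face)


class TestTrialValidity:
    def _samples(self, n_invalid, n=300):
        v = np.ones(n, bool)
        v[:n_invalid] = False
        return _cyclo(np.arange(n) * DT, np.full(n, 500.0),
                      np.full(n, 500.0), v)

    def test_missing_over_threshold_excludes(self):
        samples = self._samples(105)  # 35% missing
        fx = make_fixations([("eyes", 0.0, 900.0)])
        res = validate_trial(samples, fx, correct=True, duration_ms=1000.0)
        assert not res.valid
        assert res.reasons == ("missing_gt_30pct",)
        assert res.missing_fraction == pytest.approx(0.35)

    def test_low_face_time_excludes(self):
        samples = self._samples(0)
        fx = make_fixations([("eyes", 0.0, 400.0), ("off", 400.0, 1000.0)])
        res = validate_trial(samples, fx, correct=True, duration_ms=1000.0)
        assert res.reasons == ("face_lt_50pct",)
        assert res.face_fraction == pytest.approx(0.40)

    def test_exact_boundaries_keep_trial(self):
        samples = self._samples(90)  # exactly 30% missing
        fx = make_fixations([("face", 0.0, 500.0)])  # exactly 50% face
        res = validate_trial(samples, fx, correct=True, duration_ms=1000.0)
        assert res.valid and res.reasons == ()

    def test_incorrect_response_is_a_reason(self):
        samples = self._samples(0)
        fx = make_fixations([("face", 0.0, 900.0)])
        res = validate_trial(samples, fx, correct=False, duration_ms=1000.0)
        assert res.reasons == ("incorrect_response",)
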