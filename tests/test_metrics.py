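"""Questionnaire scoring, trait grouping, and gaze dependent variables."""
import math

import numpy as np
import pandas as pd
import pytest

from traitgaze.metrics import (AQ_AGREE_ITEMS, aq_levels_from_moments,
                               epoch_timecourse, exclusion_summary,
                               participant_first_fix_proportion, score_scales,
                               standardize_and_group, trial_gaze_metrics)
from traitgaze.simulate import (SimulationParams, TrialSpec, aq4_to_binary,
                                Participant, simulate_aoi_sequence)

from _oracles import epoch_recount_oracle
from conftest import make_fixations

DT = 1000.0 / 300.0


def _aq_frame(fill):
    """All items answered ``fill`` (1..4)."""
    return pd.DataFrame({f"aq_{i}": [fill] for i in range(1, 51)})


def _spin_frame(fill):
    return pd.DataFrame({f"spin_{i}": [fill] for i in range(1, 18)})


class TestScoring:
    def test_spin_extremes(self):
        assert score_scales(_spin_frame(4))["spin"].iloc[0] == 68
        assert score_scales(_spin_frame(0))["spin"].iloc[0] == 0

    def test_aq_maximum_under_key(self):
        """Every item at its agree-keyed extreme: 4 on agree-scored items,
        1 on reverse-keyed ones."""
        row = {f"aq_{i}": [4 if i in AQ_AGREE_ITEMS else 1]
               for i in range(1, 51)}
        out = score_scales(pd.DataFrame(row))
        assert out["aq4"].iloc[0] == 200
        assert out["aq_binary"].iloc[0] == 50

    def test_aq_uniform_answers_split_by_key(self):
        # answering 4 everywhere scores 4 on 24 agree items, 1 on 26 others
        out = score_scales(_aq_frame(4))
        assert out["aq4"].iloc[0] == 24 * 4 + 26 * 1
        assert out["aq_binary"].iloc[0] == 24

    def test_missing_items_error(self):
        bad = _spin_frame(2).drop(columns=["spin_9"])
        with pytest.raises(ValueError):
            score_scales(bad)
        nan = _spin_frame(2)
        nan.loc[0, "spin_3"] = np.nan
        with pytest.raises(ValueError):
            score_scales(nan)

    def test_totals_pass_through(self):
        df = pd.DataFrame({"aq4": [120], "aq_binary": [23], "spin": [30]})
        out = score_scales(df)
        assert out.iloc[0].tolist() == [120, 23, 30]


class TestStandardizeAndGroup:
    def _participants(self, aq_binary, spin):
        n = len(aq_binary)
        return pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(n)],
            "aq4": np.linspace(100, 140, n).round(),
            "aq_binary": aq_binary, "spin": spin,
        })

    def test_group_cutoffs_inclusive(self):
        df = self._participants([26, 25, 30], [19, 18, 40])
        out = standardize_and_group(df)
        assert out["aq_group"].tolist() == ["high", "low", "high"]
        assert out["spin_group"].tolist() == ["high", "low", "high"]

    def test_z_scores_standardized(self):
        df = self._participants([20, 25, 30, 22], [10, 19, 30, 25])
        out = standardize_and_group(df)
        for col in ("z_aq4", "z_spin"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0)

    def test_z_of_z_round_trip(self):
        df = self._participants([20, 25, 30, 22], [10, 19, 30, 25])
        once = standardize_and_group(df)
        again = standardize_and_group(
            once.assign(aq4=once["z_aq4"], spin=once["z_spin"]))
        np.testing.assert_allclose(again["z_aq4"], once["z_aq4"], atol=1e-12)

    def test_zero_variance_rejected(self):
        df = self._participants([25, 25], [10, 20]).assign(aq4=[120, 120])
        with pytest.raises(ValueError):
            standardize_and_group(df)

    def test_mean_participant_scores_z_zero(self):
        df = self._participants([20, 25, 30], [10, 20, 30])
        out = standardize_and_group(df)
        assert out["z_spin"].iloc[1] == pytest.approx(0.0, abs=1e-12)


def test_moderator_levels_on_original_scale():
    levels = aq_levels_from_moments(120.35, 14.28)
    assert levels == {"low": 106, "medium": 120, "high": 135}


class TestTrialMetrics:
    def test_proportional_eye_looking(self):
        fx = make_fixations([("eyes", 0, 2000), ("face", 2000, 5000)])
        m = trial_gaze_metrics(fx)
        assert m.prop_eyes_overall == pytest.approx(0.4)

    def test_first_fixation_on_eyes_defines_latency_and_duration(self):
        fx = make_fixations([("off", 0, 300), ("eyes", 300, 450),
                             ("face", 450, 9000)])
        m = trial_gaze_metrics(fx)
        assert m.first_face_fix_on_eyes is True
        assert m.latency_to_eyes == 300
        assert m.first_fix_duration == 150
        assert m.log_latency == pytest.approx(math.log(300))
        assert m.log_duration == pytest.approx(math.log(150))

    def test_face_first_leaves_metrics_undefined(self):
        fx = make_fixations([("off", 0, 300), ("face", 300, 600),
                             ("eyes", 600, 900)])
        m = trial_gaze_metrics(fx)
        assert m.first_face_fix_on_eyes is False
        assert math.isnan(m.first_fix_duration)
        assert math.isnan(m.latency_to_eyes)

    def test_no_face_time_undefined(self):
        m = trial_gaze_metrics(make_fixations([("off", 0, 1000)]))
        assert math.isnan(m.prop_eyes_overall)
        assert m.first_face_fix_on_eyes is None


class TestFirstFixProportion:
    def test_simple_counts(self):
        flags = [True] * 12 + [False] * 48
        assert participant_first_fix_proportion(flags) == pytest.approx(0.2)
        assert participant_first_fix_proportion([True] * 5) == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        flags = [bool(b) for b in rng.random(50) < 0.3]
        shuffled = list(flags)
        rng.shuffle(shuffled)
        assert (participant_first_fix_proportion(flags)
                == participant_first_fix_proportion(shuffled))

    def test_no_trials_error(self):
        with pytest.raises(ValueError):
            participant_first_fix_proportion([])

    def test_generator_proportion_tracks_bernoulli_rate(self):
        """With a flat 50% eyes-first probability, the recovered proportion
        over 10^4 simulated trials is binomial around 0.5."""
        params = SimulationParams(
            first_eye_prob_base=0.5, first_eye_slope_aq=0.0,
            first_eye_slope_spin=0.0, first_eye_slope_spin_by_aq=0.0, seed=0)
        part = Participant("p1", 22.0, "female", aq4=120,
                           aq_binary=aq4_to_binary(120), spin=24)
        spec = TrialSpec(participant_id="p1", block=1, trial_index=1,
                         emotion="neutral", fixation_side="left")
        rng = np.random.default_rng(77)
        flags = []
        for _ in range(10_000):
            seq = simulate_aoi_sequence(spec, part, params, rng)
            first = next(a for a, s, e in seq if a in ("eyes", "face"))
            flags.append(first == "eyes")
        assert participant_first_fix_proportion(flags) == pytest.approx(
            0.5, abs=0.02)


class TestEpochCurve:
    def test_constant_eyes_gives_ones(self):
        fx = make_fixations([("eyes", 0, 10_000)])
        curve = epoch_timecourse(fx)
        assert np.allclose(curve["prop_eyes"], 1.0)
        assert curve["t_ms"].iloc[0] == 125.0
        assert curve["t_ms"].iloc[-1] == 9875.0

    def test_step_function(self):
        fx = make_fixations([("eyes", 0, 5000), ("face", 5000, 10_000)])
        curve = epoch_timecourse(fx)
        before = curve[curve["t_ms"] <= 5000 - 125]
        after = curve[curve["t_ms"] >= 5000 + 125]
        assert np.allclose(before["prop_eyes"], 1.0)
        assert np.allclose(after["prop_eyes"], 0.0)

    def test_no_face_time_is_nan(self):
        fx = make_fixations([("off", 0, 10_000)])
        assert epoch_timecourse(fx)["prop_eyes"].isna().all()

    def test_matches_per_sample_recount(self):
        """Grid-aligned random fixation tilings: interval-overlap arithmetic
        equals a brute-force 300 Hz per-sample recount."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            edges = np.sort(rng.choice(np.arange(1, 3000), size=25,
                                       replace=False)) * DT
            edges = np.concatenate([[0.0], edges, [10_000.0]])
            aois = rng.choice(["eyes", "face", "off"], size=len(edges) - 1)
            fx = make_fixations([(a, s, e) for a, s, e
                                 in zip(aois, edges[:-1], edges[1:])])
            curve = epoch_timecourse(fx)
            _, oracle_vals = epoch_recount_oracle(fx, 10_000.0, 250.0, 50.0)
            np.testing.assert_allclose(curve["prop_eyes"], oracle_vals,
                                       atol=1e-9, equal_nan=True)

    def test_whole_trial_window_equals_overall_proportion(self):
        rng = np.random.default_rng(5)
        edges = np.concatenate([[0.0], np.sort(rng.uniform(0, 10_000, 20)),
                                [10_000.0]])
        aois = rng.choice(["eyes", "face", "off"], size=len(edges) - 1)
        fx = make_fixations([(a, s, e) for a, s, e
                             in zip(aois, edges[:-1], edges[1:])])
        curve = epoch_timecourse(fx, window_ms=10_000.0, step_ms=10_000.0)
        overall = trial_gaze_metrics(fx).prop_eyes_overall
        assert curve["prop_eyes"].iloc[0] == pytest.approx(overall)


class TestExclusionSummary:
    def _validity(self, n_invalid, n):
        valid = [True] * (n - n_invalid) + [False] * n_invalid
        return pd.DataFrame({
            "valid": valid,
            "reasons": ["" if v else "missing_gt_30pct" for v in valid],
        })

    def test_study_scale_arithmetic(self):
        out = exclusion_summary(self._validity(874, 4800))
        assert out["invalid_pct"] == 18.2
        assert out["n_invalid"] == 874
        assert out["reason_counts"]["missing_gt_30pct"] == 874

    def test_extremes(self):
        assert exclusion_summary(self._validity(0, 100))["invalid_pct"] == 0.0
        assert exclusion_summary(self._validity(50, 50))["invalid_pct"] == 100.0
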