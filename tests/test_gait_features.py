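"""Gait events, leg-length normalization, step metrics and the full
229-feature vector."""

import warnings

import numpy as np
import pandas as pd
import pytest

from emogait import features, gait_features, preprocess, registry, synthcap
from emogait.gait_features import (
    StepMetrics,
    detect_gait_events,
    leg_length_estimate,
    normalize,
    pick_extrema,
)
from emogait.mocap_io import MarkerTrajectorySet, TrialRecording
from tests.conftest import CLEAN_CONFIG


class TestEventDetection:
    def test_stationary_standing_yields_zero_events(self, standing_segment):
        m, _, _ = standing_segment
        for side in ("left", "right"):
            ev = detect_gait_events(m, side)
            assert ev.heel_strike_frames.size == 0
            assert ev.toe_off_frames.size == 0

    def test_events_match_ground_truth_within_one_frame(self, clean_trial_and_truth):
        """Steady-walking contacts detected within +-1 frame (8.3 ms) of the
        generator's scheduled events (compared on the frame grid)."""
        trial, gt = clean_trial_and_truth
        m = preprocess.filter_trial(trial).markers
        lo, hi = gt.turn_time + 0.4, gt.arrival_time - 0.6
        n_checked = 0
        for side in ("left", "right"):
            ev = detect_gait_events(m, side)
            for det_frames, truth in (
                (ev.heel_strike_frames, gt.heel_strike_times[side]),
                (ev.toe_off_frames, gt.toe_off_times[side]),
            ):
                truth_frames = np.round(np.asarray(truth) * m.rate)
                for f in det_frames:
                    if lo * m.rate < f < hi * m.rate:
                        n_checked += 1
                        assert np.abs(truth_frames - f).min() <= 1
        assert n_checked >= 8

    def test_peak_picker_matches_brute_force_extrema_scan(self, rng):
        """Exhaustive scan of a 500-frame window reproduces the gated peaks."""
        rate = 120.0
        t = np.arange(500) / rate
        x = 0.3 * np.sin(2 * np.pi * 1.1 * t) + 0.05 * np.sin(2 * np.pi * 3.7 * t)
        x += 0.001 * rng.normal(size=t.size)
        min_sep, prom = 0.4, 0.02
        got = pick_extrema(x, rate, min_sep, prom)

        # oracle: all strict local maxima, brute-force prominence, then
        # greedy min-separation selection by descending height
        cand = [i for i in range(1, len(x) - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]

        def prominence(i):
            left = x[: i + 1]
            right = x[i:]
            lh = left[np.argmax(left[::-1] > x[i]) :] if (left > x[i]).any() else left
            lo_l = (
                left[len(left) - 1 - np.argmax(left[::-1] > x[i]) :].min()
                if (left > x[i]).any()
                else left.min()
            )
            lo_r = (
                right[: np.argmax(right > x[i]) + 1].min()
                if (right > x[i]).any()
                else right.min()
            )
            return x[i] - max(lo_l, lo_r)

        cand = [i for i in cand if prominence(i) >= prom]
        keep: list[int] = []
        for i in sorted(cand, key=lambda i: -x[i]):
            if all(abs(i - j) >= round(min_sep * rate) for j in keep):
                keep.append(i)
        assert sorted(keep) == sorted(got.tolist())


class TestLegLengthAndNormalization:
    def test_fixed_trochanter_height(self):
        data = {
            "L_TROCH": np.tile([0.0, 0.09, 0.90], (120, 1)),
            "R_TROCH": np.tile([0.0, -0.09, 0.90], (120, 1)),
        }
        m = MarkerTrajectorySet(120.0, data)
        assert leg_length_estimate(m, (0.0, 1.0)) == pytest.approx(0.90)

    def test_sway_noise_averages_out(self, rng):
        z = 0.90 + rng.normal(0, 0.01, 3600)
        data = {
            "L_TROCH": np.column_stack([np.zeros(3600), np.zeros(3600), z]),
            "R_TROCH": np.column_stack([np.zeros(3600), np.zeros(3600), z]),
        }
        m = MarkerTrajectorySet(120.0, data)
        assert leg_length_estimate(m, (0.0, 30.0)) == pytest.approx(0.90, abs=0.005)

    def test_profile_leg_length_round_trips(self, clean_trial_and_truth, subject):
        trial, _ = clean_trial_and_truth
        est = leg_length_estimate(trial.markers, (0.0, 30.0))
        assert abs(est - subject.leg_length) < 0.02

    @pytest.mark.parametrize(
        "value,kind,L,expected",
        [
            (0.72, "length", 0.9, 0.8),
            (0.6058, "time", 0.9, 2.000),     # sqrt(0.9 / 9.81) = 0.30288 s
            (1.4857, "speed", 0.9, 0.500),    # sqrt(9.81 * 0.9) = 2.9714 m/s
        ],
    )
    def test_hand_computed_normalizations(self, value, kind, L, expected):
        assert normalize(value, kind, L) == pytest.approx(expected, abs=5e-4)

    def test_non_positive_leg_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            normalize(1.0, "length", 0.0)


class TestStepMetrics:
    def test_speed_is_length_over_duration(self):
        s = StepMetrics(side="left", length=0.7, duration=0.5, height=0.05, width=0.1)
        assert s.speed == pytest.approx(0.7 / 0.5, rel=1e-12)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            StepMetrics(side="left", length=0.7, duration=0.0, height=0.05, width=0.1)


class TestWalkingRecovery:
    def test_configured_gait_parameters_recovered_noise_free(
        self, clean_trial_and_truth, trial_features
    ):
        trial, gt = clean_trial_and_truth
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vec = features.extract_trial_features(trial)
        g = gt.generative["gait"]
        for side in ("left", "right"):
            assert vec[f"walking.{side}.raw.mean.step_length"] == pytest.approx(
                g.step_length, rel=0.03
            )
            assert vec[f"walking.{side}.raw.mean.step_duration"] == pytest.approx(
                g.step_duration, rel=0.03
            )
            # constant-parameter gait: cycle-to-cycle SDs below 5% of means
            sd = vec[f"walking.{side}.raw.sd.step_duration"]
            if np.isfinite(sd):
                assert sd < 0.05 * vec[f"walking.{side}.raw.mean.step_duration"]

    def test_stance_plus_swing_equals_stride(self, trial_features):
        one_frame = 1.0 / 120.0
        for side in ("left", "right"):
            total = (
                trial_features[f"walking.{side}.raw.mean.stance_duration"]
                + trial_features[f"walking.{side}.raw.mean.swing_duration"]
            )
            stride = trial_features[f"walking.{side}.raw.mean.stride_duration"]
            assert abs(total - stride) <= one_frame

    def test_event_count_parity(self, clean_trial_and_truth):
        trial, gt = clean_trial_and_truth
        m = preprocess.filter_trial(trial).markers
        counts = {}
        for side in ("left", "right"):
            ev = detect_gait_events(m, side)
            hs = ev.heel_strike_times
            counts[side] = ((hs > gt.turn_time) & (hs < gt.arrival_time)).sum()
        assert abs(counts["left"] - counts["right"]) <= 1

    def test_first_step_length_matches_generator(self, clean_trial_and_truth):
        trial, gt = clean_trial_and_truth
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vec = features.extract_trial_features(trial)
        expected = 0.6 * gt.generative["gait"].step_length  # first-step scale
        assert vec["gait_initiation.step1.raw.length"] == pytest.approx(expected, rel=0.08)
        assert np.isfinite(vec["gait_initiation.step1.raw.swing_speed"])
        assert np.isfinite(vec["gait_initiation.step1.raw.swing_width"])


class TestScaleInvariance:
    def test_normalized_features_invariant_to_body_scale(self, null_effects):
        """Regenerating a subject at 1.1x stature with identical dimensionless
        gait parameters changes normalized step length/duration/speed < 2%."""
        import copy

        base = synthcap.generate_subject(5, "S05", "male")
        scaled = copy.deepcopy(base)
        s = 1.1
        scaled.leg_length = base.leg_length * s
        scaled.stature_scale = base.stature_scale * s
        g = base.base_gait
        scaled.base_gait = synthcap.GaitParams(
            step_length=g.step_length * s,
            step_duration=g.step_duration * np.sqrt(s),
            step_width=g.step_width * s,
            step_height=g.step_height * s,
            double_support_fraction=g.double_support_fraction,
            arm_swing_amplitude=g.arm_swing_amplitude * s,
        )
        vals = {}
        for name, prof in (("base", base), ("scaled", scaled)):
            trial, _ = synthcap.generate_trial(
                prof, "neutral", null_effects, seed=5, config=CLEAN_CONFIG
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals[name] = features.extract_trial_features(trial)
        for key in (
            "walking.left.normalized.mean.step_length",
            "walking.left.normalized.mean.step_duration",
            "walking.left.normalized.mean.step_speed",
            "walking.right.normalized.mean.step_length",
        ):
            assert vals["scaled"][key] == pytest.approx(vals["base"][key], rel=0.02)


class TestFeatureVector:
    def test_registry_enumerates_exactly_229_features(self):
        built = registry.build_registry()
        assert len(built) == 229
        assert built["name"].is_unique
        shipped = registry.load_registry()
        pd.testing.assert_frame_equal(shipped, built)
        cats = built["category"].value_counts()
        assert set(cats.index) == {
            "balance", "standing_posture", "gait_initiation", "walking"
        }

    def test_complete_trial_yields_229_named_values(self, trial_features):
        assert len(trial_features) == 229
        assert list(trial_features.index) == registry.feature_names()
        # the core catalog is populated; entries may be flagged missing only
        # when their data genuinely does not exist on this trial: transition
        # variants (no transitions occurred) and cycle-level SDs on a side
        # with a single full cycle
        missing = trial_features[trial_features.isna()].index
        assert len(trial_features.dropna()) >= 185
        for name in missing:
            assert ".transition." in name or ".sd." in name

    def test_extraction_is_deterministic(self, trial_and_truth, trial_features):
        trial, _ = trial_and_truth
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = features.extract_trial_features(trial)
        pd.testing.assert_series_equal(again, trial_features)

    def test_trial_without_walking_flags_walking_features(self, standing_segment):
        m, fp, _ = standing_segment
        trial = TrialRecording("S01", "female", "neutral", m, fp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vec = features.extract_trial_features(trial)
        assert len(vec) == 229
        walking = vec[[n for n in vec.index if n.startswith("walking.")]]
        assert walking.isna().all()
        assert np.isfinite(vec["balance.standing.full.sd.ml"])
        assert np.isfinite(vec["posture.standing.full.mean.back_sagittal"])
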