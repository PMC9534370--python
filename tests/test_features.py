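import numpy as np
import pandas as pd
import pytest

from painquant.features import (
    DegenerateWindowError,
    assign_pain_labels,
    compute_pulse_params,
    compute_window_features,
    extract_recording_features,
    feature_columns,
    fit_apply_zscore,
)
from painquant.preprocess import PulseSegment, SampleWindow

from conftest import make_recording


def _pulses(triples):
    return [PulseSegment(*t) for t in triples]


class TestPulseParams:
    def test_widths_and_intervals_from_hand_built_pulses(self):
        fs = 100.0
        params = compute_pulse_params(
            _pulses([(0, 30, 100), (100, 130, 200), (200, 240, 300)]), fs
        )
        np.testing.assert_allclose(params["LR"], [0.3, 0.3, 0.4])
        np.testing.assert_allclose(params["LF"], [0.7, 0.7, 0.6])
        np.testing.assert_allclose(params["PPIH"][:2], [1.0, 1.1])
        np.testing.assert_allclose(params["PPIL"][:2], [1.0, 1.0])
        assert np.isnan(params["PPIH"].iloc[-1]) and np.isnan(params["PPIL"].iloc[-1])

    def test_rise_plus_fall_equals_valley_to_valley(self):
        fs = 66.67
        params = compute_pulse_params(_pulses([(5, 21, 58), (58, 74, 111)]), fs)
        np.testing.assert_allclose(params["LR"] + params["LF"], [53 / fs, 53 / fs])

    def test_single_pulse_is_degenerate(self):
        with pytest.raises(DegenerateWindowError):
            compute_pulse_params(_pulses([(0, 30, 100)]), 100.0)


class TestWindowFeatures:
    @staticmethod
    def _temps(values):
        return {site: np.full(100, v, dtype=float) for site, v in values.items()}

    def test_temperature_ratio_and_difference_arithmetic(self):
        temps = self._temps({"forehead": 31.0, "temple": 33.0, "wrist_top": 31.0,
                             "wrist_bottom": 31.0, "finger": 30.0})
        params = {"temple": compute_pulse_params(
            _pulses([(0, 20, 60), (60, 80, 120)]), 66.67)}
        row = compute_window_features(SampleWindow(0, 100), params, temps)
        assert row["temp_ratio_temple_finger"] == pytest.approx(1.1)
        assert row["temp_diff_temple_finger"] == pytest.approx(3.0)
        assert row["temp_ratio_forehead_finger"] == pytest.approx(31.0 / 30.0)
        assert row["temp_diff_forehead_finger"] == pytest.approx(1.0)

    def test_equal_temperatures_give_unit_ratio_zero_difference(self):
        temps = self._temps({s: 32.0 for s in
                             ("forehead", "temple", "wrist_top", "wrist_bottom", "finger")})
        params = {"temple": compute_pulse_params(
            _pulses([(0, 20, 60), (60, 80, 120)]), 66.67)}
        row = compute_window_features(SampleWindow(0, 100), params, temps)
        assert row["temp_ratio_temple_finger"] == 1.0
        assert row["temp_diff_temple_finger"] == 0.0

    def test_zero_finger_temperature_is_flagged(self):
        temps = self._temps({"forehead": 31.0, "temple": 33.0, "wrist_top": 31.0,
                             "wrist_bottom": 31.0, "finger": 0.0})
        params = {"temple": compute_pulse_params(
            _pulses([(0, 20, 60), (60, 80, 120)]), 66.67)}
        with pytest.raises(DegenerateWindowError, match="finger"):
            compute_window_features(SampleWindow(0, 100), params, temps)


class TestPainLabels:
    def test_halves_get_their_scores(self):
        rec = make_recording(n=800, fs=66.67, pain_start=3, pain_end=5)
        rec.duration_s = 600.0          # label logic only uses fs/duration/scores
        w1 = SampleWindow(start=int(115 * rec.fs), end=int(125 * rec.fs))
        w2 = SampleWindow(start=int(475 * rec.fs), end=int(485 * rec.fs))
        assign_pain_labels([w1, w2], rec)
        assert (w1.half, w1.label) == ("first", 3)
        assert (w2.half, w2.label) == ("second", 5)

    def test_equal_scores_label_everything(self):
        rec = make_recording(pain_start=4, pain_end=4)
        rec.duration_s = 600.0
        ws = [SampleWindow(start=0, end=667), SampleWindow(start=30000, end=30667)]
        assign_pain_labels(ws, rec)
        assert all(w.label == 4 for w in ws)

    def test_midpoint_tie_goes_to_second_half(self):
        rec = make_recording(pain_start=1, pain_end=9)
        rec.duration_s = 600.0
        half_len = int(round(5 * rec.fs))
        w = SampleWindow(start=int(round(300 * rec.fs)) - half_len,
                         end=int(round(300 * rec.fs)) + half_len)
        assign_pain_labels([w], rec)
        assert (w.half, w.label) == ("second", 9)


class TestZScore:
    def test_train_columns_standardized_and_test_uses_train_stats(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(5, 2, size=(50, 3)), columns=list("abc"))
        test = pd.DataFrame([train.mean().to_dict()])
        ztr, zte, params = fit_apply_zscore(train, test, feature_cols=list("abc"))
        np.testing.assert_allclose(ztr[list("abc")].mean(), 0, atol=1e-12)
        np.testing.assert_allclose(
            ztr[list("abc")].to_numpy().std(axis=0), 1, atol=1e-12)
        np.testing.assert_allclose(zte[list("abc")].iloc[0], 0, atol=1e-12)

    def test_constant_train_column_is_dropped_everywhere(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        test = pd.DataFrame({"a": [2.0], "b": [9.0]})
        ztr, zte, params = fit_apply_zscore(train, test, feature_cols=["a", "b"])
        assert params.dropped == ["b"]
        assert "b" not in ztr.columns and "b" not in zte.columns

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_apply_zscore(pd.DataFrame({"a": []}), feature_cols=["a"])


class TestRecordingExtraction:
    def test_amplitude_affine_transform_leaves_pulse_features_bitwise_equal(
            self, noise_free_recording):
        rec, _ = noise_free_recording
        base = extract_recording_features(rec, ["temple", "finger"])
        import copy
        rec2 = copy.deepcopy(rec)
        rec2.pulse["temple"] = rec2.pulse["temple"] * 3.7 + 10.0
        rec2.pulse["finger"] = rec2.pulse["finger"] * 0.2 + 1.0
        scaled = extract_recording_features(rec2, ["temple", "finger"])
        pulse_cols = [c for c in base.columns
                      if c.startswith(("temple_", "finger_"))]
        assert len(base) > 0
        np.testing.assert_array_equal(base[pulse_cols].to_numpy(),
                                      scaled[pulse_cols].to_numpy())

    def test_labels_come_from_the_recording_scores(self, small_cohort):
        for rec, _ in small_cohort[:3]:
            table = extract_recording_features(rec, ["temple"])
            assert set(table["label"]) <= {rec.pain_start, rec.pain_end}
            assert (table.loc[table.half == "first", "label"] == rec.pain_start).all()
            assert (table.loc[table.half == "second", "label"] == rec.pain_end).all()

    def test_feature_columns_are_complete_and_ordered(self, small_cohort):
        rec, _ = small_cohort[0]
        table = extract_recording_features(rec, ["temple", "carotid"])
        expected = feature_columns(["temple", "carotid"])
        assert list(table.columns)[6:] == expected[:]
        assert list(table.columns)[:6] == ["recording_id", "subject_id", "half",
                                           "label", "start", "end"]
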