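"""Segmentation, segment/differential features, matrices and z-scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppgaffect as pa
from ppgaffect import featurization as fz


def _beats_df(onsets, st=200.0, dt=650.0, bva=10.0):
    onsets = np.asarray(onsets, dtype=float)
    return pd.DataFrame(
        {
            "onset_s": onsets,
            "peak_s": onsets + st / 1000.0,
            "end_s": onsets + (st + dt) / 1000.0,
            "bva_mV": np.full(len(onsets), bva),
            "st_ms": np.full(len(onsets), st),
            "dt_ms": np.full(len(onsets), dt),
            "ppi_ms": np.full(len(onsets), st + dt),
            "vvi_ms": np.full(len(onsets), st + dt),
        }
    )


class TestSegmentRecord:
    def test_six_segments_per_three_minutes(self):
        beats = _beats_df(np.arange(0, 179, 0.85))
        groups = pa.segment_record(beats, 180.0, 30.0)
        assert len(groups) == 6

    def test_half_open_windows(self):
        beats = _beats_df([29.999, 30.0, 59.999, 60.0])
        groups = pa.segment_record(beats, 180.0, 30.0)
        assert len(groups[0]) == 1
        assert len(groups[1]) == 2  # onset exactly at 30.0 s goes to segment 2
        assert len(groups[2]) == 1

    def test_groups_partition_all_beats(self):
        rng = np.random.default_rng(4)
        beats = _beats_df(np.sort(rng.uniform(0, 180, 200)))
        groups = pa.segment_record(beats, 180.0, 30.0)
        combined = pd.concat(groups)
        assert len(combined) == len(beats)
        assert combined.index.is_unique

    def test_partial_trailing_window_warns(self):
        beats = _beats_df(np.arange(0, 40, 0.85))
        with pytest.warns(UserWarning):
            groups = pa.segment_record(beats, 45.0, 30.0)
        assert len(groups) == 1


class TestSegmentFeatures:
    def test_identical_beats_have_zero_spread(self):
        feats = pa.segment_features(_beats_df(np.arange(0, 10, 0.85)))
        assert len(feats) == 10
        for idx in fz.INDEX_NAMES:
            assert feats[f"{idx}_std"] == 0.0
        assert feats["st_mean"] == 200.0
        assert feats["vvi_mean"] == 850.0

    def test_hand_computed_mean_and_population_sd(self):
        beats = _beats_df([0.0, 0.9, 1.8])
        beats["st_ms"] = [190.0, 200.0, 210.0]
        feats = pa.segment_features(beats)
        assert feats["st_mean"] == pytest.approx(200.0)
        # population SD, divisor n: sqrt(((-10)^2 + 0 + 10^2)/3)
        assert feats["st_std"] == pytest.approx(np.sqrt(200.0 / 3.0))

    def test_nan_ppi_excluded_pairwise(self):
        beats = _beats_df([0.0, 0.9, 1.8, 2.7])
        beats.loc[3, "ppi_ms"] = np.nan
        feats = pa.segment_features(beats)
        assert feats["ppi_mean"] == pytest.approx(850.0)

    def test_too_few_beats_rejected(self):
        with pytest.raises(fz.InvalidSegmentError):
            pa.segment_features(_beats_df([0.0, 0.9]))

    def test_long_synthetic_segment_matches_stage_mean(self, stage_params):
        beats = pa.draw_beat_params(stage_params["baseline"], 5000, np.random.default_rng(2))
        beats = beats.rename(columns={"st_ms": "st_ms"})
        df = _beats_df(np.arange(5000) * 0.85)
        df["st_ms"] = beats["st_ms"].to_numpy()
        feats = pa.segment_features(df)
        se = beats["st_ms"].std(ddof=1) / np.sqrt(len(beats))
        assert abs(feats["st_mean"] - 196.01) < 3 * se


class TestDifferentialFeatures:
    def test_published_anger_deltas(self):
        baseline = pd.Series({f: 0.0 for f in fz.WAVEFORM_FEATURES})
        state = baseline.copy()
        baseline["st_mean"], state["st_mean"] = 196.01, 226.18
        baseline["bva_mean"], state["bva_mean"] = 11.82, 8.23
        delta = pa.differential_features(state, baseline)
        assert delta["d_st_mean"] == pytest.approx(30.17)
        assert delta["d_bva_mean"] == pytest.approx(-3.59)

    def test_state_equal_reference_is_zero(self):
        v = pd.Series({f: float(i) for i, f in enumerate(fz.WAVEFORM_FEATURES)})
        assert (pa.differential_features(v, v) == 0).all()

    def test_name_mismatch_rejected(self):
        v = pd.Series({f: 1.0 for f in fz.WAVEFORM_FEATURES})
        with pytest.raises(KeyError):
            pa.differential_features(v.drop("st_mean"), v)

    def test_baseline_reference_is_elementwise_average(self):
        rows = pd.DataFrame([{f: 1.0 for f in fz.WAVEFORM_FEATURES},
                             {f: 3.0 for f in fz.WAVEFORM_FEATURES}])
        ref = pa.baseline_reference(rows)
        assert (ref == 2.0).all()
        # idempotent: reference of the reference row is itself
        again = pa.baseline_reference(pd.DataFrame([ref]))
        assert (again == ref).all()

    def test_subject_mean_baseline_delta_is_zero(self, small_features):
        base = small_features[small_features["stage"] == "baseline"]
        per_subject = base.groupby("subject_id")[fz.DIFFERENTIAL_FEATURES].mean()
        assert np.allclose(per_subject.to_numpy(), 0.0, atol=1e-9)


class TestAssembleMatrix:
    def test_feature_vector_lengths(self, small_features):
        m10 = pa.assemble_matrix(small_features, "waveform10", "4C")
        m20 = pa.assemble_matrix(small_features, "combined20", "4C")
        assert len(fz.WAVEFORM_FEATURES) == 10
        assert len(fz.COMBINED_FEATURES) == 20
        assert m10[fz.WAVEFORM_FEATURES].shape[1] == 10
        assert m20[fz.COMBINED_FEATURES].shape[1] == 20

    def test_4c_row_count(self, small_features):
        m = pa.assemble_matrix(small_features, "waveform10", "4C")
        assert len(m) == 8 * 4 * 6
        assert set(m["stage"]) == set(fz.EMOTION_STAGES)

    def test_2c_and_3c_label_maps(self, small_features):
        m2 = pa.assemble_matrix(small_features, "waveform10", "2C")
        neg = m2[m2["stage"].isin(["anger", "sadness"])]["label"]
        pos = m2[m2["stage"].isin(["neutral", "happiness"])]["label"]
        assert set(neg) == {0} and set(pos) == {1}
        m3 = pa.assemble_matrix(small_features, "waveform10", "3C")
        assert set(m3[m3["stage"] == "happiness"]["label"]) == {2}
        assert set(m3[m3["stage"] == "neutral"]["label"]) == {1}

    def test_baseline_task_includes_baseline_rows(self, small_features):
        m = pa.assemble_matrix(small_features, "combined20", "baseline_vs_anger")
        assert set(m["stage"]) == {"baseline", "anger"}
        assert set(m["label"]) == {0, 1}

    def test_unknown_task_rejected(self, small_features):
        with pytest.raises(ValueError):
            pa.assemble_matrix(small_features, "waveform10", "5C")

    def test_assembly_is_deterministic(self, small_features):
        a = pa.assemble_matrix(small_features, "combined20", "3C")
        b = pa.assemble_matrix(small_features, "combined20", "3C")
        pd.testing.assert_frame_equal(a, b)


class TestZScore:
    def test_hand_computed_matrix(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [10.0, 10.0, 40.0]})
        model = pa.zscore_fit(df)
        out = pa.zscore_apply(model, df)
        sd_a = np.sqrt(2.0 / 3.0)
        assert np.allclose(out["a"], [-1 / sd_a, 0.0, 1 / sd_a])
        assert out["b"].iloc[2] == pytest.approx((40 - 20) / np.sqrt(200.0))

    def test_training_rows_standardized(self, small_features):
        cols = [c for c in fz.WAVEFORM_FEATURES]
        model = pa.zscore_fit(small_features, cols)
        out = pa.zscore_apply(model, small_features)
        assert np.allclose(out[cols].mean(), 0.0, atol=1e-12)
        assert np.allclose(out[cols].std(ddof=0), 1.0, atol=1e-12)

    def test_constant_column_maps_to_zero_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        model = pa.zscore_fit(df)
        with pytest.warns(UserWarning):
            out = pa.zscore_apply(model, df)
        assert (out["a"] == 0.0).all()

    def test_fit_never_sees_test_rows(self):
        train = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        test1 = pd.DataFrame({"a": [100.0]})
        test2 = pd.DataFrame({"a": [-100.0]})
        model = pa.zscore_fit(train)
        before = (model.mean.copy(), model.std.copy())
        pa.zscore_apply(model, test1)
        pa.zscore_apply(model, test2)
        assert model.mean.equals(before[0]) and model.std.equals(before[1])
        # swapping the test data never changes the transform of the train rows
        a = pa.zscore_apply(model, train)
        b = pa.zscore_apply(model, train)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            pa.zscore_fit(pd.DataFrame({"a": [1.0]}))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=12))
    def test_zscore_is_affine_invariant_roundtrip(self, values):
        df = pd.DataFrame({"a": values})
        model = pa.zscore_fit(df)
        out = pa.zscore_apply(model, df)["a"]
        if model.std["a"] > 1e-9:
            back = out * model.std["a"] + model.mean["a"]
            assert np.allclose(back, df["a"], rtol=1e-9, atol=1e-9)
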