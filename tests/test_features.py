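import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nervedecode import features
from nervedecode.features import (
    FEATURE_IDS,
    FeatureMatrix,
    FeatureWindow,
    apply_normalizer,
    compute_feature,
    feature_block,
    feature_matrix,
    fit_norm_constants,
    fit_normalizer,
    normalize,
    row_index,
)
from nervedecode.preprocessing import Trial, cut_trials
from nervedecode.synth import NerveRecording, TrajectorySet

from .oracles import brute_force_features

# frozen oracle values for x = [1, -2, 3, -4] (hand/brute-force evaluation)
X4 = [1.0, -2.0, 3.0, -4.0]
X4_EXPECTED = {
    "ZC": 3.0,
    "SSC": 2.0,
    "WL": 15.0,
    "WA": 2.0,
    "MAB": 2.5,
    "MSQ": 7.5,
    "RMS": 2.7386127875,
    "V3": -2.2239800906,
    "LD": 2.2133638394,
    # note: DABS = sqrt(83/3) and MFL = ln(83)/2, computed by the oracle;
    # MFL also equals ln(DABS) + ln(3)/2
    "DABS": 5.2599112794,
    "MFL": 2.2094203039,
    "MPR": 1.0,
    "MAVS": -2.0,
    "WMA": 2.0,
}


class TestSingleFeatures:
    @pytest.mark.parametrize("fid,expected", sorted(X4_EXPECTED.items()))
    def test_hand_evaluated_window(self, fid, expected):
        assert compute_feature(fid, FeatureWindow(X4)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_oracle_agrees_on_hand_window(self):
        oracle = brute_force_features(X4)
        for fid, expected in X4_EXPECTED.items():
            assert oracle[fid] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("fid", FEATURE_IDS)
    def test_numeric_feature_ids(self, fid):
        fnum = f"F{FEATURE_IDS.index(fid) + 1}"
        w = FeatureWindow([0.5, -1.0, 2.0, 0.1, -0.7])
        assert compute_feature(fnum, w) == compute_feature(fid, w)

    def test_constant_window_counting_features_zero(self):
        w = FeatureWindow(np.full(50, 3.7))
        for fid in ("ZC", "SSC", "WL", "WA"):
            assert compute_feature(fid, w) == 0.0

    def test_all_zero_window_finite(self):
        vals = feature_block(np.zeros(100))
        assert np.all(np.isfinite(vals))
        out = dict(zip(FEATURE_IDS, vals))
        for fid, v in out.items():
            if fid == "LD":
                assert v == pytest.approx(1e-12)
            else:
                assert v == 0.0

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            compute_feature("SSC", np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            FeatureWindow([1.0])

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            compute_feature("F15", FeatureWindow(X4))
        with pytest.raises(ValueError):
            compute_feature("XYZ", FeatureWindow(X4))


class TestOracleEquivalence:
    def test_brute_force_on_random_windows(self, rng):
        # 1,000 random windows of mixed lengths, all 14 features to 1e-9
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            scale = 10.0 ** rng.uniform(-2, 2)
            x = rng.standard_normal(n) * scale
            got = dict(zip(FEATURE_IDS, feature_block(x)))
            want = brute_force_features(x)
            for fid in FEATURE_IDS:
                assert got[fid] == pytest.approx(want[fid], abs=1e-9), fid

    def test_mfl_dabs_identity(self, rng):
        # MFL = ln(DABS) + 0.5*ln(N-1) for any window with variation
        for _ in range(200):
            n = int(rng.integers(3, 200))
            x = rng.standard_normal(n)
            vals = dict(zip(FEATURE_IDS, feature_block(x)))
            assert vals["MFL"] == pytest.approx(
                np.log(vals["DABS"]) + 0.5 * np.log(n - 1), abs=1e-9
            )


@settings(max_examples=50, deadline=None)
@given(
    gain=st.floats(min_value=0.1, max_value=100.0),
    seed=st.integers(min_value=0, max_value=2 ** 16),
)
def test_scale_behavior(gain, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(64)
    base = dict(zip(FEATURE_IDS, feature_block(x)))
    scaled = dict(zip(FEATURE_IDS, feature_block(gain * x)))
    for fid in ("MAB", "RMS", "WL", "DABS", "V3"):
        assert scaled[fid] == pytest.approx(gain * base[fid], rel=1e-9)
    for fid in ("ZC", "SSC", "MPR", "WA"):
        assert scaled[fid] == base[fid]


class TestFeatureMatrix:
    def _trial(self, rng, n_ch=16, fs=5000.0, seconds=4.0):
        n = int(seconds * fs)
        sig = rng.standard_normal((n_ch, n))
        return Trial(
            signal=sig,
            trajectory=np.zeros((10, int(seconds / 0.02))),
            finger_state=np.zeros(5, dtype=np.int8),
            t_end=seconds,
            start_index=0,
            end_index=n,
            sample_rate=fs,
        )

    def test_shape_224_by_200(self, rng):
        fm = feature_matrix(self._trial(rng))
        assert fm.values.shape == (224, 200)
        assert fm.n_rows == 16 * 14 == 224
        assert fm.n_steps == int(4.0 / 0.02) == 200

    def test_row_ordering_channel_major(self, rng):
        fm = feature_matrix(self._trial(rng))
        assert fm.row_index == row_index(16)
        assert fm.row_index[0] == (0, "ZC")
        assert fm.row_index[14] == (1, "ZC")
        assert fm.row_index[-1] == (15, "WMA")

    def test_all_zero_trial(self):
        t = self._trial(np.random.default_rng(0))
        t.signal[:] = 0.0
        fm = feature_matrix(t)
        ld_rows = [i for i, (_, fid) in enumerate(fm.row_index) if fid == "LD"]
        other = np.delete(fm.values, ld_rows, axis=0)
        assert np.all(other == 0.0)
        assert np.allclose(fm.values[ld_rows], 1e-12)

    def test_columns_match_single_feature_calls(self, rng):
        # 20 random (t, channel, feature) probes against direct slices
        trial = self._trial(rng)
        fm = feature_matrix(trial)
        n_win, n_step = 500, 100
        padded = np.concatenate(
            [np.zeros((16, n_win - n_step)), trial.signal], axis=1
        )
        for _ in range(20):
            t = int(rng.integers(0, 200))
            ch = int(rng.integers(0, 16))
            k = int(rng.integers(0, 14))
            end = (n_win - n_step) + (t + 1) * n_step
            window = padded[ch, end - n_win : end]
            row = ch * 14 + k
            assert fm.values[row, t] == pytest.approx(
                compute_feature(FEATURE_IDS[k], window), abs=1e-9
            )

    def test_parent_context_used_for_left_columns(self, small_session, small_trials):
        _, recording, _ = small_session
        trial = small_trials[5]  # has 0.5 s of preceding context
        fm = feature_matrix(trial)
        # oracle: first column from real preceding samples
        end = trial.start_index + 100
        window = recording.samples[3, end - 500 : end]
        assert fm.values[3 * 14 + 4, 0] == pytest.approx(
            compute_feature("MAB", window), abs=1e-9
        )

    def test_grid_equals_per_trial_matrices(self, small_session, small_trials, small_grid):
        _, recording, _ = small_session
        for trial in (small_trials[0], small_trials[7], small_trials[-1]):
            c0 = trial.start_index // 100
            sl = small_grid[:, c0 : c0 + trial.n_steps]
            fm = feature_matrix(trial)
            assert np.allclose(sl, fm.values, atol=1e-9)

    def test_wrong_overlap_rejected(self, rng):
        with pytest.raises(ValueError):
            feature_matrix(self._trial(rng), window_ms=100.0, step_ms=50.0)


class TestNormalizer:
    def test_constants_positive_and_percentile(self, rng):
        vals = rng.standard_normal((224, 400)) * 3.0
        consts = fit_norm_constants(vals)
        assert consts.shape == (14,)
        assert np.all(consts > 0)
        normed = apply_normalizer(vals, consts)
        frac_in = (np.abs(normed) <= 1.0).mean()
        assert frac_in >= 0.99 - 1e-9

    def test_degenerate_all_zero_floored(self):
        consts = fit_norm_constants(np.zeros((28, 100)))
        assert np.all(consts == 1e-12)

    def test_no_leakage_constants_unchanged(self, rng):
        train = rng.standard_normal((224, 300))
        consts = fit_norm_constants(train)
        digest = consts.tobytes()
        new_session = rng.standard_normal((224, 500)) * 100.0
        apply_normalizer(new_session, consts)
        assert consts.tobytes() == digest

    def test_fit_normalizer_matrix_surface(self, rng):
        mats = [
            FeatureMatrix(
                values=rng.standard_normal((224, 50)), row_index=row_index()
            )
            for _ in range(3)
        ]
        consts = fit_normalizer(mats)
        stacked = np.concatenate([m.values for m in mats], axis=1)
        assert np.allclose(consts, fit_norm_constants(stacked))
        normed = normalize(mats[0], consts)
        assert normed.norm_constants is not None
        assert np.allclose(
            normed.values, apply_normalizer(mats[0].values, consts)
        )

    def test_invalid_constants_rejected(self, rng):
        vals = rng.standard_normal((224, 10))
        with pytest.raises(ValueError):
            apply_normalizer(vals, np.zeros(14))
        with pytest.raises(ValueError):
            apply_normalizer(vals, np.ones(10))
        with pytest.raises(ValueError):
            fit_normalizer([])


def test_compression_ratio_consistent():
    from nervedecode.preprocessing import bitrate

    feature_kbps = bitrate(16, len(FEATURE_IDS) / 0.02, 16)
    raw_kbps = 480.0 * 16
    assert raw_kbps / feature_kbps > 40.0
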