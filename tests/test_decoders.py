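import numpy as np
import pytest

from nervedecode import decoders, evaluation, features, preprocessing, synth
from nervedecode.decoders import (
    ClassifierModel,
    ModelSpec,
    TrainConfig,
    baseline_inputs,
    build_baseline,
    build_network,
    classification_input,
    default_spec,
    fit_pca,
    neural_spec,
    regression_input,
    train_classifier,
    train_regressor,
)
from nervedecode.gestures import lookup
from nervedecode.pipeline import _columns_mask, trial_grid_slices

TABLE_CLS_PARAMS = 1_465_749
TABLE_REG_PARAMS_TOTAL = 767_200


@pytest.fixture(scope="module")
def training_setup():
    """Separable two-gesture session prepared for decoder training."""
    cfg = synth.SessionConfig(n_repetitions=6, snr_db=30.0, rng_seed=21)
    gestures = [lookup("thumb"), lookup("little")]
    rec, traj = synth.generate_session(cfg, gestures)
    trials = preprocessing.cut_trials(rec, traj)
    # drop windows straddling the thumb->little block boundary: their
    # threshold-derived labels flag activity that barely enters the window
    boundary = rec.n_samples // 2
    trials = [
        t for t in trials
        if not (t.start_index < boundary < t.end_index)
    ]
    grid = features.extract_grid(rec.samples, rec.sample_rate)
    train_idx, valid_idx = evaluation.split_regression(
        trials, frac=0.8, rng=21, n_blocks=2
    )
    mask = _columns_mask(grid.shape[1], trials, train_idx, 20.0)
    norm = features.fit_norm_constants(grid[:, mask])
    grid_n = features.apply_normalizer(grid, norm)
    mats = trial_grid_slices(grid_n, trials, 20.0)
    return trials, mats, train_idx, valid_idx, norm


class TestSpecs:
    def test_cnn_classification_layer_counts(self):
        spec = neural_spec("classification", "cnn")
        assert spec.layer_counts() == (1, 0, 3)

    def test_regression_layer_counts(self):
        for fam in ("cnn", "rnn"):
            assert neural_spec("regression", fam).layer_counts() == (3, 2, 0)

    def test_built_network_matches_plan_counts(self):
        rng = np.random.default_rng(0)
        net = build_network(neural_spec("classification", "cnn"), rng)
        assert net.layer_counts() == (1, 0, 3)
        net_r = build_network(neural_spec("regression", "rnn"), rng)
        assert net_r.layer_counts() == (3, 2, 0)

    def test_classification_capacity_near_table(self):
        rng = np.random.default_rng(0)
        net = build_network(neural_spec("classification", "cnn"), rng)
        assert 0.5 * TABLE_CLS_PARAMS <= net.param_count() <= 2 * TABLE_CLS_PARAMS

    def test_regression_capacity_near_table(self):
        rng = np.random.default_rng(0)
        net = build_network(neural_spec("regression", "rnn"), rng)
        total = 10 * net.param_count()
        assert 0.5 * TABLE_REG_PARAMS_TOTAL <= total <= 2 * TABLE_REG_PARAMS_TOTAL

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(task="clustering", family="cnn")
        with pytest.raises(ValueError):
            ModelSpec(task="regression", family="gbm")


class TestBaselineSpecs:
    def test_rf_classification(self):
        spec = build_baseline("rf", "classification")
        assert spec.hyperparams == {"n_estimators": 5, "max_depth": 3}

    def test_rf_regression(self):
        spec = build_baseline("rf", "regression")
        assert spec.hyperparams == {"n_estimators": 10, "max_depth": 3}

    def test_svm_kernels(self):
        assert build_baseline("svm", "classification").hyperparams == {
            "kernel": "rbf", "C": 1.0,
        }
        assert build_baseline("svm", "regression").hyperparams == {
            "kernel": "poly", "degree": 3, "C": 1.0,
        }

    def test_mlp_regression_widths(self):
        spec = build_baseline("mlp", "regression")
        assert spec.hyperparams["hidden"] == [300, 300, 300, 50]

    def test_mlp_classification_replaces_conv_with_fc200(self):
        spec = build_baseline("mlp", "classification")
        assert spec.layer_plan[0] == {"kind": "dense", "units": 200}
        assert spec.layer_counts()[0] == 0  # no conv layer left
        cnn = neural_spec("classification", "cnn")
        # rest of the FC stack identical to the CNN plan
        assert spec.layer_plan[2:] == cnn.layer_plan[2:]


class TestBaselineInputs:
    def test_constant_matrix_mean(self):
        m = np.full((224, 200), 2.5)
        m[5] = -1.0
        vec = classification_input(m)
        assert vec.shape == (224,)
        assert vec[0] == 2.5 and vec[5] == -1.0

    def test_mean_equals_matvec(self, rng):
        m = rng.standard_normal((224, 200))
        assert np.allclose(
            classification_input(m), m @ (np.ones(200) / 200.0)
        )

    def test_pca_rank_bound(self, rng):
        # matrices whose per-step columns live in a rank-5 subspace
        basis = rng.standard_normal((224, 5))
        mats = [
            basis @ rng.standard_normal((5, 200)) for _ in range(40)
        ]
        pca = fit_pca(mats, seed=0)
        assert pca.n_components_ == 30
        assert np.all(pca.explained_variance_ratio_[5:] < 1e-6)

    def test_regression_input_requires_pca(self, rng):
        with pytest.raises(ValueError):
            baseline_inputs(rng.standard_normal((224, 200)), "regression")

    def test_regression_input_is_last_step_scores(self, rng):
        mats = [rng.standard_normal((224, 200)) for _ in range(40)]
        pca = fit_pca(mats, seed=0)
        got = baseline_inputs(mats[0], "regression", pca)
        want = pca.transform(mats[0][:, -1][None, :])[0]
        assert np.allclose(got, want)
        assert got.shape == (30,)


class TestTrainClassifier:
    def test_separable_data_high_accuracy(self, training_setup):
        trials, mats, train_idx, valid_idx, norm = training_setup
        data = [(mats[i], trials[i].finger_state) for i in train_idx]
        model = train_classifier(
            build_baseline("rf", "classification"), data,
            TrainConfig(seed=0), norm_constants=norm,
        )
        pred = model.predict_state([mats[i] for i in valid_idx])
        truth = np.stack([trials[i].finger_state for i in valid_idx])
        for f in (0, 4):  # thumb and little are exercised by the gestures
            counts = evaluation.ConfusionCounts.from_labels(
                truth[:, f], pred[:, f]
            )
            acc = evaluation.classification_metrics(counts)["accuracy"]
            assert acc >= 0.95

    def test_all_rest_degenerate(self, rng):
        data = [
            (rng.standard_normal((224, 200)), np.zeros(5, dtype=int))
            for _ in range(10)
        ]
        with pytest.warns(UserWarning, match="single-class"):
            model = train_classifier(
                build_baseline("rf", "classification"), data, TrainConfig()
            )
        pred = model.predict_state([data[0][0]])
        assert np.array_equal(pred[0], np.zeros(5))

    def test_seed_determinism(self, training_setup):
        trials, mats, train_idx, valid_idx, _ = training_setup
        data = [(mats[i], trials[i].finger_state) for i in train_idx[:80]]
        probe = [mats[i] for i in valid_idx[:10]]

        def run():
            m = train_classifier(
                build_baseline("rf", "classification"), data,
                TrainConfig(seed=5),
            )
            return m.predict_state(probe)

        assert np.array_equal(run(), run())

    def test_neural_classifier_smoke(self, training_setup):
        trials, mats, train_idx, valid_idx, norm = training_setup
        data = [(mats[i], trials[i].finger_state) for i in train_idx[:120]]
        cfg = TrainConfig(seed=0, max_epochs=3, lr_init=0.001)
        model = train_classifier(
            neural_spec("classification", "cnn"), data, cfg,
            norm_constants=norm,
        )
        scores = model.predict_scores([mats[i] for i in valid_idx[:5]])
        assert scores.shape == (5, 5)
        assert np.all((scores >= 0) & (scores <= 1))
        assert model.built_layer_counts() == (1, 0, 3)
        assert len(model.history) == 3

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(build_baseline("rf", "classification"), [])


class TestTrainRegressor:
    def test_noiseless_single_finger_vaf(self, training_setup):
        trials, mats, train_idx, valid_idx, norm = training_setup
        pca = fit_pca([mats[i] for i in train_idx], seed=0)
        dof = 1  # thumb MCP
        data = [(mats[i], trials[i].trajectory[dof - 1]) for i in train_idx]
        model = train_regressor(
            build_baseline("svm", "regression"), data, TrainConfig(seed=0),
            subset="active_only", dof_id=dof, norm_constants=norm,
            pca_state=pca,
        )
        act = [
            i for i in valid_idx
            if trials[i].trajectory[dof - 1].max() > 0.1
        ]
        pred = model.predict_end([mats[i] for i in act])
        truth = np.array([trials[i].trajectory[dof - 1, -1] for i in act])
        v = evaluation.vaf(evaluation.TrajectoryPair(y=truth, y_hat=pred))
        assert v >= 0.7

    def test_zero_target_gives_zero_output(self, rng):
        mats = [rng.standard_normal((224, 200)) for _ in range(30)]
        # DOF never active -> subset=full trains on all-zero targets
        data = [(m, np.zeros(200)) for m in mats]
        model = train_regressor(
            build_baseline("rf", "regression"), data, TrainConfig(seed=0),
            subset="full", dof_id=3,
        )
        pred = model.predict_end(mats[:5])
        assert np.allclose(pred, 0.0, atol=1e-6)

    def test_active_only_empty_subset_raises(self, rng):
        data = [(rng.standard_normal((224, 200)), np.zeros(200))
                for _ in range(5)]
        with pytest.raises(ValueError, match="empty"):
            train_regressor(
                build_baseline("rf", "regression"), data,
                subset="active_only", dof_id=1,
            )

    def test_one_step_imbalance_ratio_matches_protocol(self):
        # equal-repetition 9-gesture schedule: for the ring and little
        # fingers the idle:active sample ratio lands in the 5:1-10:1 band
        cfg = synth.SessionConfig(n_repetitions=2, snr_db=20.0, rng_seed=0)
        _, traj = synth.generate_session(cfg)
        for dof_row in (6, 8):  # ring MCP, little MCP
            active = (traj.values[dof_row] > 0.1).mean()
            ratio = (1 - active) / active
            assert 5.0 <= ratio <= 10.0

    def test_neural_regressor_smoke(self, training_setup):
        trials, mats, train_idx, valid_idx, norm = training_setup
        data = [(mats[i], trials[i].trajectory[0]) for i in train_idx[:100]]
        cfg = TrainConfig(seed=0, max_epochs=3, lr_init=0.001)
        model = train_regressor(
            neural_spec("regression", "rnn"), data, cfg, subset="full",
            dof_id=1, norm_constants=norm,
        )
        series = model.predict_series([mats[i] for i in valid_idx[:3]])
        assert series.shape == (3, 200)
        assert np.all((series >= 0) & (series <= 1))
        end = model.predict_end([mats[i] for i in valid_idx[:3]])
        assert np.allclose(end, series[:, -1])
        assert model.built_layer_counts() == (3, 2, 0)

    def test_invalid_args(self, rng):
        data = [(rng.standard_normal((224, 200)), np.ones(200))]
        with pytest.raises(ValueError):
            train_regressor(build_baseline("rf", "regression"), data,
                            subset="half")
        with pytest.raises(ValueError):
            train_regressor(build_baseline("rf", "regression"), data,
                            dof_id=11)


class TestTrainConfig:
    def test_defaults_match_schedule(self):
        cfg = TrainConfig()
        assert cfg.beta1 == 0.99
        assert cfg.beta2 == 0.999
        assert cfg.weight_decay == 1e-5
        assert cfg.minibatch == 38
        assert cfg.minibatches_per_epoch == 10
        assert cfg.lr_init == 0.005
        assert cfg.lr_drop_factor == 10.0
        assert cfg.plateau_epochs == 2

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_init=0.0)
        with pytest.raises(ValueError):
            TrainConfig(minibatch=-1)


def test_default_spec_dispatch():
    assert default_spec("classification", "cnn").layer_counts() == (1, 0, 3)
    assert default_spec("regression", "rf").hyperparams["n_estimators"] == 10
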