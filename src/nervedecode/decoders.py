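"""Decoding models behind a uniform train/predict contract.

Two neural families (cnn, rnn) built on the in-package NumPy framework, and
three classic baselines (svm, rf, mlp) built on scikit-learn with the
printed hyperparameters. Classification is multi-label: five independent
binary finger outputs. Regression is one model per DOF (10 total).

Baseline inputs: classification uses the 224-row means across time;
regression uses the 30 leading PCA components of the flattened matrix
(PCA fitted on the training split only).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC, SVR

from . import nets
from .features import FeatureMatrix
from .gestures import N_FINGERS
from .preprocessing import DEFAULT_ACTIVITY_THRESHOLD

N_DOF = 10
NEURAL_FAMILIES = ("cnn", "rnn")
BASELINE_FAMILIES = ("svm", "rf", "mlp")
PCA_COMPONENTS = 30


@dataclass
class TrainConfig:
    """Optimization schedule shared by the neural decoders.

    beta1 = 0.99 is implemented as printed even though 0.9 is the
    conventional Adam default.
    """

    beta1: float = 0.99
    beta2: float = 0.999
    weight_decay: float = 1e-5
    minibatch: int = 38
    minibatches_per_epoch: int = 10
    lr_init: float = 0.005
    lr_drop_factor: float = 10.0
    plateau_epochs: int = 2
    max_epochs: int = 200
    min_lr: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.beta1, self.beta2, self.weight_decay, self.minibatch,
            self.minibatches_per_epoch, self.lr_init, self.lr_drop_factor,
            self.plateau_epochs, self.max_epochs,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("all TrainConfig schedule fields must be positive")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


@dataclass
class ModelSpec:
    """Architecture/hyperparameter description of one decoder."""

    task: str  # "classification" | "regression"
    family: str  # "cnn" | "rnn" | "svm" | "rf" | "mlp"
    layer_plan: tuple[dict, ...] = ()
    input_shape: tuple[int, int] = (224, 200)
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task: {self.task!r}")
        if self.family not in NEURAL_FAMILIES + BASELINE_FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")

    def layer_counts(self) -> tuple[int, int, int]:
        """(conv, lstm, fully-connected) counts from the layer plan."""
        conv = sum(l["kind"] == "conv" for l in self.layer_plan)
        lstm = sum(l["kind"] == "lstm" for l in self.layer_plan)
        fc = sum(l["kind"] == "dense" for l in self.layer_plan)
        return conv, lstm, fc


def classification_plan(family: str = "cnn") -> tuple[dict, ...]:
    """Classification architecture: 1 conv + 3 fully-connected layers
    (cnn), or the recurrent variant (rnn). Widths are configurable
    defaults chosen so the parameter count lands near the published
    order of magnitude."""
    if family == "cnn":
        return (
            {"kind": "conv", "filters": 32, "kernel": 5, "stride": 4},
            {"kind": "relu"},
            {"kind": "flatten"},
            {"kind": "dense", "units": 512},
            {"kind": "relu"},
            {"kind": "dropout", "p": 0.3},
            {"kind": "dense", "units": 128},
            {"kind": "relu"},
            {"kind": "dense", "units": N_FINGERS},
        )
    if family == "rnn":
        return (
            {"kind": "transpose"},
            {"kind": "lstm", "units": 64, "return_sequences": True},
            {"kind": "lstm", "units": 64, "return_sequences": False},
            {"kind": "dense", "units": 128},
            {"kind": "relu"},
            {"kind": "dense", "units": N_FINGERS},
        )
    raise ValueError(f"no neural classification plan for family {family!r}")


def regression_plan(family: str = "rnn") -> tuple[dict, ...]:
    """Regression architecture: 3 conv + 2 LSTM layers with a per-time-step
    linear head. Both neural families share this plan (a single published
    regression layout exists and both strategies use the same regression
    model)."""
    if family not in NEURAL_FAMILIES:
        raise ValueError(f"no neural regression plan for family {family!r}")
    return (
        {"kind": "conv", "filters": 32, "kernel": 5, "stride": 2},
        {"kind": "relu"},
        {"kind": "conv", "filters": 32, "kernel": 5, "stride": 2},
        {"kind": "relu"},
        {"kind": "conv", "filters": 16, "kernel": 5, "stride": 2},
        {"kind": "relu"},
        {"kind": "transpose"},
        {"kind": "lstm", "units": 64, "return_sequences": True},
        {"kind": "lstm", "units": 64, "return_sequences": True},
        {"kind": "head", "units": 1},
    )


def neural_spec(task: str, family: str,
                input_shape: tuple[int, int] = (224, 200)) -> ModelSpec:
    plan = (classification_plan(family) if task == "classification"
            else regression_plan(family))
    return ModelSpec(task=task, family=family, layer_plan=plan,
                     input_shape=input_shape)


def build_baseline(family: str, task: str) -> ModelSpec:
    """Baseline specs with the printed hyperparameters: SVM rbf (cls) /
    poly-3 (reg) with C=1; RF 5 trees (cls) / 10 trees (reg), depth 3;
    MLP regression widths 300/300/300/50; MLP classification = the CNN
    classification plan with the conv layer replaced by a 200-unit
    fully-connected layer."""
    if family not in BASELINE_FAMILIES:
        raise ValueError(f"unknown baseline family: {family!r}")
    if family == "svm":
        hp = ({"kernel": "rbf", "C": 1.0} if task == "classification"
              else {"kernel": "poly", "degree": 3, "C": 1.0})
        return ModelSpec(task=task, family="svm", hyperparams=hp)
    if family == "rf":
        n_trees = 5 if task == "classification" else 10
        return ModelSpec(task=task, family="rf",
                         hyperparams={"n_estimators": n_trees, "max_depth": 3})
    # mlp
    if task == "classification":
        plan = ({"kind": "dense", "units": 200}, {"kind": "relu"}) + \
            classification_plan("cnn")[2:]
        return ModelSpec(task=task, family="mlp", layer_plan=plan,
                         input_shape=(224, 200),
                         hyperparams={"hidden": [200, 512, 128]})
    return ModelSpec(task=task, family="mlp",
                     hyperparams={"hidden": [300, 300, 300, 50]})


def default_spec(task: str, family: str) -> ModelSpec:
    if family in NEURAL_FAMILIES:
        return neural_spec(task, family)
    return build_baseline(family, task)


def build_network(spec: ModelSpec, rng: np.random.Generator) -> nets.Sequential:
    """Instantiate a Sequential network from a layer plan."""
    c, t = spec.input_shape
    layers: list[nets.Layer] = []
    flat_dim = None  # set after flatten
    seq_dim = None  # feature dim once in (B, T, F) layout
    for item in spec.layer_plan:
        kind = item["kind"]
        if kind == "conv":
            layers.append(nets.Conv1d(c, item["filters"], item["kernel"],
                                      item["stride"], rng))
            t = (t - item["kernel"]) // item["stride"] + 1
            c = item["filters"]
        elif kind == "relu":
            layers.append(nets.ReLU())
        elif kind == "dropout":
            layers.append(nets.Dropout(item["p"]))
        elif kind == "flatten":
            layers.append(nets.Flatten())
            flat_dim = c * t
        elif kind == "transpose":
            layers.append(nets.Transpose())
            seq_dim = c
        elif kind == "lstm":
            layers.append(nets.LSTM(seq_dim, item["units"], rng,
                                    return_sequences=item.get(
                                        "return_sequences", True)))
            seq_dim = item["units"]
        elif kind == "dense":
            n_in = flat_dim if flat_dim is not None else seq_dim
            layers.append(nets.Dense(n_in, item["units"], rng))
            flat_dim = item["units"] if flat_dim is not None else flat_dim
            seq_dim = item["units"] if flat_dim is None else seq_dim
        elif kind == "head":
            layers.append(nets.TimeDense(seq_dim, item["units"], rng))
        else:
            raise ValueError(f"unknown layer kind: {kind!r}")
    return nets.Sequential(layers)


def conv_output_steps(spec: ModelSpec) -> int:
    """Time steps remaining after the plan's strided convolutions."""
    t = spec.input_shape[1]
    for item in spec.layer_plan:
        if item["kind"] == "conv":
            t = (t - item["kernel"]) // item["stride"] + 1
    return t


# ---------------------------------------------------------------------------
# input adapters


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, FeatureMatrix) else np.asarray(m, float)


def classification_input(matrix) -> np.ndarray:
    """Baseline classification input: per-row mean across time steps."""
    return _values(matrix).mean(axis=1)


def regression_input(matrix, pca_state: PCA) -> np.ndarray:
    """Baseline regression input: the 30 leading principal-component scores
    of the trial's current (last) per-step feature vector.

    The PCA basis is fitted over 224-dim per-step feature vectors of the
    training split only (time steps are the samples); at decode time the
    causal "now" is the window's final step.
    """
    if pca_state is None:
        raise ValueError("pca_state is required for regression inputs")
    return pca_state.transform(_values(matrix)[:, -1][None, :])[0]


def baseline_inputs(matrix, task: str, pca_state: PCA | None = None
                    ) -> np.ndarray:
    if task == "classification":
        return classification_input(matrix)
    if task == "regression":
        return regression_input(matrix, pca_state)
    raise ValueError(f"unknown task: {task!r}")


def fit_pca(matrices, n_components: int = PCA_COMPONENTS,
            seed: int = 0) -> PCA:
    """Fit the regression-input PCA basis on per-step feature vectors (the
    final column of each training matrix; the trials' sliding windows cover
    every movement phase)."""
    cols = np.stack([_values(m)[:, -1] for m in matrices]).astype(np.float32)
    k = min(n_components, *cols.shape)
    pca = PCA(n_components=k, svd_solver="randomized", random_state=seed)
    pca.fit(cols)
    return pca


def _config_hash(norm_constants) -> str:
    if norm_constants is None:
        return "unnormalized"
    arr = np.asarray(norm_constants, float)
    return hashlib.sha256(arr.tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# classifier


class _ConstantBinary:
    """Stand-in for a degenerate single-class finger output."""

    def __init__(self, value: int):
        self.value = int(value)

    def predict(self, x):
        return np.full(len(x), self.value)


def _make_binary_classifier(spec: ModelSpec, seed: int):
    hp = spec.hyperparams
    if spec.family == "svm":
        return SVC(kernel=hp["kernel"], C=hp["C"], random_state=seed)
    if spec.family == "rf":
        return RandomForestClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            random_state=seed,
        )
    raise ValueError(spec.family)


@dataclass
class ClassifierModel:
    """Multi-label finger-state classifier: 5 independent binary outputs."""

    spec: ModelSpec
    threshold: float = 0.5
    norm_constants: np.ndarray | None = None
    history: list = field(default_factory=list, repr=False)
    _net: nets.Sequential | None = field(default=None, repr=False)
    _per_finger: list | None = field(default=None, repr=False)
    _input_mode: str = "matrix"  # "matrix" | "rowmean"

    @property
    def config_hash(self) -> str:
        return _config_hash(self.norm_constants)

    def predict_scores(self, matrices) -> np.ndarray:
        """(B, 5) per-finger activity scores in [0, 1]."""
        if self._net is not None:
            if self._input_mode == "rowmean":
                x = np.stack([classification_input(m) for m in matrices])
            else:
                x = np.stack([_values(m) for m in matrices])
            logits = self._net.forward(x, train=False)
            return 1.0 / (1.0 + np.exp(-np.clip(logits, -50, 50)))
        feats = np.stack([classification_input(m) for m in matrices])
        cols = [np.asarray(clf.predict(feats), float)
                for clf in self._per_finger]
        return np.stack(cols, axis=1)

    def predict_state(self, matrices) -> np.ndarray:
        """(B, 5) binary finger states."""
        return (self.predict_scores(matrices) > self.threshold).astype(np.int8)

    def param_count(self) -> int | None:
        return self._net.param_count() if self._net is not None else None

    def built_layer_counts(self) -> tuple[int, int, int] | None:
        return self._net.layer_counts() if self._net is not None else None


def train_classifier(spec: ModelSpec, data, cfg: TrainConfig | None = None,
                     norm_constants=None) -> ClassifierModel:
    """Fit a multi-label finger-state classifier.

    ``data`` is a list of (FeatureMatrix-or-array, finger_state) pairs with
    5-bit labels. Deterministic given ``cfg.seed``. A degenerate label
    column (single class) fixes that output to the constant class with a
    warning.
    """
    cfg = cfg or TrainConfig()
    if not data:
        raise ValueError("training data must be non-empty")
    labels = np.stack([np.asarray(y, float) for _, y in data])
    if labels.shape[1] != N_FINGERS:
        raise ValueError("labels must be 5-bit finger-state vectors")

    model = ClassifierModel(spec=spec, norm_constants=norm_constants)
    if spec.family in NEURAL_FAMILIES or (
        spec.family == "mlp" and spec.task == "classification"
    ):
        rng = np.random.default_rng(cfg.seed)
        if spec.family == "mlp":
            # Baseline input (per-row means) through the CNN plan's FC
            # stack, with the conv layer swapped for a 200-unit dense layer.
            x = np.stack([classification_input(m) for m, _ in data])
            layers = [nets.Dense(x.shape[1], 200, rng), nets.ReLU(),
                      nets.Dense(200, 512, rng), nets.ReLU(),
                      nets.Dropout(0.3), nets.Dense(512, 128, rng),
                      nets.ReLU(), nets.Dense(128, N_FINGERS, rng)]
            net = nets.Sequential(layers)
        else:
            x = np.stack([_values(m) for m, _ in data])
            net = build_network(spec, rng)
        model.history = nets.train_network(
            net, x, labels, loss="bce",
            lr_init=cfg.lr_init, beta1=cfg.beta1, beta2=cfg.beta2,
            weight_decay=cfg.weight_decay, minibatch=cfg.minibatch,
            minibatches_per_epoch=cfg.minibatches_per_epoch,
            lr_drop_factor=cfg.lr_drop_factor,
            plateau_epochs=cfg.plateau_epochs, max_epochs=cfg.max_epochs,
            min_lr=cfg.min_lr, seed=cfg.seed,
        )
        model._net = net
        model._input_mode = "rowmean" if spec.family == "mlp" else "matrix"
        return model

    feats = np.stack([classification_input(m) for m, _ in data])
    per_finger = []
    for f in range(N_FINGERS):
        y = labels[:, f].astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"finger {f}: single-class labels; output fixed to {y[0]}"
            )
            per_finger.append(_ConstantBinary(y[0]))
            continue
        clf = _make_binary_classifier(spec, cfg.seed + f)
        clf.fit(feats, y)
        per_finger.append(clf)
    model._per_finger = per_finger
    return model


# ---------------------------------------------------------------------------
# regressor


@dataclass
class RegressorModel:
    """Trajectory regressor for a single DOF.

    ``predict_end`` gives the trial-end value (the pseudo-online decoder
    output for the window); ``predict_series`` gives one value per 20-ms
    step — natively for neural models, tiled from the end value for the
    scalar baselines.
    """

    spec: ModelSpec
    dof_id: int  # 1..10
    norm_constants: np.ndarray | None = None
    history: list = field(default_factory=list, repr=False)
    _net: nets.Sequential | None = field(default=None, repr=False)
    _est: object | None = field(default=None, repr=False)
    _pca: PCA | None = field(default=None, repr=False)
    _head_steps: int = 0

    @property
    def config_hash(self) -> str:
        return _config_hash(self.norm_constants)

    def _series_neural(self, matrices) -> np.ndarray:
        x = np.stack([_values(m) for m in matrices])
        out = self._net.forward(x, train=False)[..., 0]  # (B, head_steps)
        n_steps = x.shape[2]
        pos_coarse = (np.arange(1, out.shape[1] + 1)
                      * (n_steps / out.shape[1]))
        pos_fine = np.arange(1, n_steps + 1)
        series = np.stack(
            [np.interp(pos_fine, pos_coarse, row) for row in out]
        )
        return np.clip(series, 0.0, 1.0)

    def predict_series(self, matrices) -> np.ndarray:
        """(B, n_steps) trajectory values in [0, 1]."""
        if self._net is not None:
            return self._series_neural(matrices)
        end = self.predict_end(matrices)
        n_steps = _values(matrices[0]).shape[1]
        return np.tile(end[:, None], (1, n_steps))

    def predict_end(self, matrices) -> np.ndarray:
        """(B,) predicted DOF value at each trial's end, clipped to [0, 1]."""
        if self._net is not None:
            return self._series_neural(matrices)[:, -1]
        feats = np.stack(
            [regression_input(m, self._pca) for m in matrices]
        )
        return np.clip(np.asarray(self._est.predict(feats), float), 0.0, 1.0)

    def param_count(self) -> int | None:
        return self._net.param_count() if self._net is not None else None

    def built_layer_counts(self) -> tuple[int, int, int] | None:
        return self._net.layer_counts() if self._net is not None else None


def _make_baseline_regressor(spec: ModelSpec, seed: int):
    hp = spec.hyperparams
    if spec.family == "svm":
        return SVR(kernel=hp["kernel"], degree=hp["degree"], C=hp["C"])
    if spec.family == "rf":
        return RandomForestRegressor(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            random_state=seed,
        )
    if spec.family == "mlp":
        return MLPRegressor(
            hidden_layer_sizes=tuple(hp["hidden"]), random_state=seed,
            max_iter=800, tol=1e-6, early_stopping=False,
        )
    raise ValueError(spec.family)


def train_regressor(
    spec: ModelSpec,
    data,
    cfg: TrainConfig | None = None,
    subset: str = "active_only",
    dof_id: int = 1,
    norm_constants=None,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    pca_state: PCA | None = None,
) -> RegressorModel:
    """Fit one DOF's trajectory regressor.

    ``data`` is a list of (FeatureMatrix-or-array, dof_trajectory) pairs; a
    trial counts as *active* when its trajectory exceeds
    ``activity_threshold``. ``subset="active_only"`` (two-step strategy)
    trains on active trials only; ``subset="full"`` (one-step) keeps every
    trial and balances the active/idle classes by inverse-frequency
    weighting (sample weights where the estimator supports them, seeded
    oversampling otherwise).
    """
    if subset not in ("active_only", "full"):
        raise ValueError(f"unknown subset: {subset!r}")
    if not 1 <= dof_id <= N_DOF:
        raise ValueError("dof_id must be in 1..10")
    cfg = cfg or TrainConfig()
    if not data:
        raise ValueError("training data must be non-empty")

    targets = [np.asarray(t, float).ravel() for _, t in data]
    active = np.array([t.max() > activity_threshold for t in targets])
    if subset == "active_only":
        keep = np.flatnonzero(active)
        if keep.size == 0:
            raise ValueError(
                f"active_only subset is empty for DOF {dof_id}"
            )
        data = [data[i] for i in keep]
        targets = [targets[i] for i in keep]
        weights = None
    else:
        # inverse class frequency over the active/idle split
        n_act = int(active.sum())
        n_idle = len(active) - n_act
        if n_act and n_idle:
            w_act = len(active) / (2.0 * n_act)
            w_idle = len(active) / (2.0 * n_idle)
            weights = np.where(active, w_act, w_idle)
        else:
            weights = None

    model = RegressorModel(spec=spec, dof_id=dof_id,
                           norm_constants=norm_constants)

    if spec.family in NEURAL_FAMILIES:
        x = np.stack([_values(m) for m, _ in data])
        head_steps = conv_output_steps(spec)
        n_steps = x.shape[2]
        # end-aligned downsample of the per-step trajectory to the head grid
        step = n_steps // head_steps
        y = np.stack([t[step - 1 :: step][:head_steps] for t in targets])
        y = y[..., None]
        rng = np.random.default_rng(cfg.seed + dof_id)
        net = build_network(spec, rng)
        prob = None
        if weights is not None:
            prob = weights / weights.sum()
        model.history = nets.train_network(
            net, x, y, loss="mse",
            lr_init=cfg.lr_init, beta1=cfg.beta1, beta2=cfg.beta2,
            weight_decay=cfg.weight_decay, minibatch=cfg.minibatch,
            minibatches_per_epoch=cfg.minibatches_per_epoch,
            lr_drop_factor=cfg.lr_drop_factor,
            plateau_epochs=cfg.plateau_epochs, max_epochs=cfg.max_epochs,
            min_lr=cfg.min_lr, seed=cfg.seed + dof_id, sample_prob=prob,
        )
        model._net = net
        model._head_steps = head_steps
        return model

    # sklearn baselines: PCA-30 input, trial-end target
    if pca_state is None:
        pca_state = fit_pca([m for m, _ in data], seed=cfg.seed)
    feats = np.stack([regression_input(m, pca_state) for m, _ in data])
    y_end = np.array([t[-1] for t in targets])
    est = _make_baseline_regressor(spec, cfg.seed + dof_id)
    if weights is not None:
        if isinstance(est, MLPRegressor):
            rng = np.random.default_rng(cfg.seed + dof_id)
            prob = weights / weights.sum()
            idx = rng.choice(len(feats), size=2 * len(feats), replace=True,
                             p=prob)
            est.fit(feats[idx], y_end[idx])
        else:
            est.fit(feats, y_end, sample_weight=weights)
    else:
        est.fit(feats, y_end)
    model._est = est
    model._pca = pca_state
    return model
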