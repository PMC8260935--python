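"""One-step (1S) and two-step (2S) decoding orchestration.

2S runs the finger-state classifier first and invokes only the regressors
of fingers predicted active; inactive fingers' trajectory rows are set to
exactly zero. 1S invokes all 10 regressors on every trial, regardless of
state, so idle DOF typically show small nonzero output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .decoders import N_DOF, ClassifierModel, RegressorModel
from .features import FeatureMatrix
from .gestures import N_FINGERS


@dataclass
class DecodeResult:
    """Per-trial decoder output.

    ``trajectories`` is (10, n_steps) in [0, 1]; ``models_invoked`` lists
    the 1-based DOF ids whose regressors actually ran. For 1S the
    finger_state is recorded as all-active (no gating occurs).
    """

    finger_state: np.ndarray
    trajectories: np.ndarray
    strategy: str  # "1S" | "2S"
    models_invoked: tuple[int, ...]
    t_end: float | None = None

    def __post_init__(self) -> None:
        self.finger_state = np.asarray(self.finger_state, dtype=np.int8)
        self.trajectories = np.asarray(self.trajectories, dtype=float)
        if self.finger_state.shape != (N_FINGERS,):
            raise ValueError("finger_state must have 5 entries")
        if self.trajectories.shape[0] != N_DOF:
            raise ValueError("trajectories must have 10 rows")


def _check_compatible(classifier: ClassifierModel | None,
                      regressors: Sequence[RegressorModel]) -> None:
    hashes = {r.config_hash for r in regressors}
    if classifier is not None:
        hashes.add(classifier.config_hash)
    if len(hashes) > 1:
        raise ValueError(
            "model/feature configuration mismatch: models were fitted with "
            "different normalization constants"
        )


def _check_regressors(regressors: Sequence[RegressorModel]) -> None:
    if len(regressors) != N_DOF:
        raise ValueError(f"need {N_DOF} regressors, got {len(regressors)}")
    ids = sorted(r.dof_id for r in regressors)
    if ids != list(range(1, N_DOF + 1)):
        raise ValueError("regressors must cover DOF ids 1..10 exactly once")


def decode_2s(
    matrix: FeatureMatrix | np.ndarray,
    classifier: ClassifierModel,
    regressors: Sequence[RegressorModel],
    t_end: float | None = None,
) -> DecodeResult:
    """Two-step decode of one trial's feature matrix.

    The classifier's 5-bit prediction gates the regression stage: only DOF
    belonging to predicted-active fingers are regressed; the rest are
    exactly zero.
    """
    _check_regressors(regressors)
    _check_compatible(classifier, regressors)
    state = classifier.predict_state([matrix])[0]
    by_id = {r.dof_id: r for r in regressors}
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    n_steps = values.shape[1]
    traj = np.zeros((N_DOF, n_steps))
    invoked = []
    for finger in range(N_FINGERS):
        if not state[finger]:
            continue
        for dof in (2 * finger + 1, 2 * finger + 2):
            traj[dof - 1] = by_id[dof].predict_series([matrix])[0]
            invoked.append(dof)
    return DecodeResult(
        finger_state=state,
        trajectories=np.clip(traj, 0.0, 1.0),
        strategy="2S",
        models_invoked=tuple(invoked),
        t_end=t_end,
    )


def decode_1s(
    matrix: FeatureMatrix | np.ndarray,
    regressors: Sequence[RegressorModel],
    t_end: float | None = None,
) -> DecodeResult:
    """One-step decode: every DOF regressed directly, no gating."""
    _check_regressors(regressors)
    _check_compatible(None, regressors)
    by_id = {r.dof_id: r for r in regressors}
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    n_steps = values.shape[1]
    traj = np.zeros((N_DOF, n_steps))
    for dof in range(1, N_DOF + 1):
        traj[dof - 1] = by_id[dof].predict_series([matrix])[0]
    return DecodeResult(
        finger_state=np.ones(N_FINGERS, dtype=np.int8),
        trajectories=np.clip(traj, 0.0, 1.0),
        strategy="1S",
        models_invoked=tuple(range(1, N_DOF + 1)),
        t_end=t_end,
    )


@dataclass
class SessionDecode:
    """Vectorized decode of many trials (same models), with per-trial
    end-of-window outputs — the pseudo-online result stream."""

    strategy: str
    t_end: np.ndarray  # (B,)
    finger_state: np.ndarray  # (B, 5)
    end_values: np.ndarray  # (B, 10) DOF values at each trial end
    models_invoked: list = field(default_factory=list)


def decode_session(
    matrices: Sequence,
    strategy: str,
    regressors: Sequence[RegressorModel],
    classifier: ClassifierModel | None = None,
    t_end: Sequence[float] | None = None,
) -> SessionDecode:
    """Decode a batch of trials efficiently (models run batched).

    For 2S, each regressor runs once on the subset of trials whose finger
    is predicted active; gated-off DOF are exactly zero.
    """
    strategy = strategy.upper()
    if strategy not in ("1S", "2S"):
        raise ValueError(f"unknown strategy: {strategy!r}")
    _check_regressors(regressors)
    b = len(matrices)
    t_end_arr = (np.asarray(t_end, float) if t_end is not None
                 else np.full(b, np.nan))
    by_id = {r.dof_id: r for r in regressors}

    if strategy == "1S":
        _check_compatible(None, regressors)
        end_vals = np.stack(
            [by_id[d].predict_end(matrices) for d in range(1, N_DOF + 1)],
            axis=1,
        )
        return SessionDecode(
            strategy="1S",
            t_end=t_end_arr,
            finger_state=np.ones((b, N_FINGERS), dtype=np.int8),
            end_values=np.clip(end_vals, 0.0, 1.0),
            models_invoked=[tuple(range(1, N_DOF + 1))] * b,
        )

    if classifier is None:
        raise ValueError("2S decoding requires a classifier")
    _check_compatible(classifier, regressors)
    states = classifier.predict_state(matrices)  # (B, 5)
    end_vals = np.zeros((b, N_DOF))
    invoked: list[list[int]] = [[] for _ in range(b)]
    for finger in range(N_FINGERS):
        rows = np.flatnonzero(states[:, finger])
        if rows.size == 0:
            continue
        sub = [matrices[i] for i in rows]
        for dof in (2 * finger + 1, 2 * finger + 2):
            end_vals[rows, dof - 1] = np.clip(
                by_id[dof].predict_end(sub), 0.0, 1.0
            )
            for i in rows:
                invoked[int(i)].append(dof)
    return SessionDecode(
        strategy="2S",
        t_end=t_end_arr,
        finger_state=states,
        end_values=end_vals,
        models_invoked=[tuple(sorted(v)) for v in invoked],
    )
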