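"""Decoding metrics, split protocols, and model comparison statistics.

Classification metrics are the balanced-accuracy family (sensitivity,
specificity, precision, balanced accuracy, F1) computed per finger
one-vs-rest; regression metrics are MSE and variance-accounted-for (VAF).
Splits are leakage-free with respect to the raw samples shared by
overlapping sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

from .preprocessing import Trial


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(
        cls, truth: np.ndarray, pred: np.ndarray
    ) -> "ConfusionCounts":
        truth = np.asarray(truth).astype(bool)
        pred = np.asarray(pred).astype(bool)
        if truth.shape != pred.shape:
            raise ValueError("truth/pred shape mismatch")
        return cls(
            tp=int((truth & pred).sum()),
            tn=int((~truth & ~pred).sum()),
            fp=int((~truth & pred).sum()),
            fn=int((truth & ~pred).sum()),
        )


def _ratio(num: int, den: int) -> float:
    """Degenerate-denominator rule: when the class is absent and no errors
    were made, the metric is defined as 1."""
    return num / den if den else 1.0


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision, balanced accuracy, F1.

    Accuracy weighs sensitivity and specificity equally because inactive
    samples vastly outnumber active ones in continuous decoding.
    """
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    acc = (sens + spec) / 2.0
    f1 = 2.0 * sens * prec / (sens + prec) if (sens + prec) > 0 else 0.0
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "accuracy": acc,
        "f1": f1,
    }


@dataclass
class TrajectoryPair:
    """A ground-truth / prediction pair for one DOF."""

    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.y_hat = np.asarray(self.y_hat, dtype=float).ravel()
        if self.y.shape != self.y_hat.shape:
            raise ValueError("y and y_hat must have equal length")

    @property
    def y_bar(self) -> float:
        return float(self.y.mean())


def mse(p: TrajectoryPair) -> float:
    """Mean squared error between prediction and ground truth."""
    return float(np.mean((p.y_hat - p.y) ** 2))


def vaf(p: TrajectoryPair) -> float:
    """Variance accounted for: 1 - SS_res / SS_tot, range (-inf, 1].

    Returns NaN (undefined) when the ground truth has zero variance.
    """
    if p.y.size < 2:
        raise ValueError("VAF needs at least 2 samples")
    ss_tot = float(np.sum((p.y - p.y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((p.y_hat - p.y) ** 2))
    return 1.0 - ss_res / ss_tot


def summarize_vaf(values: Sequence[float]) -> dict:
    """Aggregate VAF scores, excluding (but counting) negative/undefined
    ones, which are retained in the raw output upstream."""
    arr = np.asarray(list(values), dtype=float)
    undefined = int(np.isnan(arr).sum())
    finite = arr[~np.isnan(arr)]
    negative = int((finite < 0).sum())
    kept = finite[finite >= 0]
    return {
        "mean_vaf": float(kept.mean()) if kept.size else float("nan"),
        "n_total": int(arr.size),
        "n_excluded_negative": negative,
        "n_undefined": undefined,
    }


def _trial_spans(trials: Sequence[Trial]) -> np.ndarray:
    """(n, 2) array of [start_index, end_index) raw-sample spans."""
    return np.array([[t.start_index, t.end_index] for t in trials])


def split_regression(
    trials: Sequence[Trial],
    frac: float = 0.8,
    rng: np.random.Generator | int | None = None,
    n_blocks: int = 1,
) -> tuple[list[int], list[int]]:
    """Block-wise train/validation split with zero raw-sample overlap.

    The validation set is ``n_blocks`` contiguous runs of trials (in time
    order), one placed randomly inside each of ``n_blocks`` equal segments
    of the session, totalling roughly ``1 - frac`` of the trials. Training
    trials whose raw-sample span intersects any validation span are dropped
    (guard gaps sized from the trials' actual windows, not a fixed
    constant). Returns (train_indices, valid_indices).

    ``n_blocks > 1`` spreads validation coverage across the session, at the
    cost of one guard gap per extra block.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    n = len(trials)
    if n < 2:
        raise ValueError("need at least 2 trials to split")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng)
    order = np.argsort([t.t_end for t in trials])
    spans = _trial_spans(trials)

    n_valid_total = max(n_blocks, int(round((1 - frac) * n)))
    per_block = n_valid_total // n_blocks
    seg = n // n_blocks
    valid_pos: list[int] = []
    for b in range(n_blocks):
        lo = b * seg
        hi = min((b + 1) * seg, n)
        start = int(rng.integers(lo, max(lo + 1, hi - per_block + 1)))
        valid_pos.extend(range(start, min(start + per_block, hi)))
    valid_idx = sorted({int(order[i]) for i in valid_pos})

    v_spans = spans[valid_idx]
    train_idx = []
    valid_set = set(valid_idx)
    for i in order:
        if int(i) in valid_set:
            continue
        lo, hi = spans[i]
        if not ((v_spans[:, 0] < hi) & (v_spans[:, 1] > lo)).any():
            train_idx.append(int(i))
    if not train_idx:
        raise ValueError("too few trials to honor the guard gaps")
    return train_idx, valid_idx


def audit_split_leakage(
    trials: Sequence[Trial], train_idx: Sequence[int], valid_idx: Sequence[int]
) -> int:
    """Number of raw-sample indices shared between train and validation
    trials (must be 0 for a sound split)."""
    spans = _trial_spans(trials)
    shared = 0
    for i in train_idx:
        for j in valid_idx:
            lo = max(spans[i, 0], spans[j, 0])
            hi = min(spans[i, 1], spans[j, 1])
            shared += max(0, hi - lo)
    return int(shared)


def split_cv(
    trials: Sequence[Trial],
    k: int = 5,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[list[int], list[int]]]:
    """Gesture-stratified k-fold CV over trials (classification protocol).

    Stratification key is the finger-state tuple; every trial appears in
    exactly one validation fold.
    """
    n = len(trials)
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n_trials]")
    rng = np.random.default_rng(rng)
    keys = [tuple(int(b) for b in t.finger_state) for t in trials]
    by_key: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        by_key.setdefault(key, []).append(i)

    folds: list[list[int]] = [[] for _ in range(k)]
    for key in sorted(by_key):
        idx = np.array(by_key[key])
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))

    out = []
    for f in range(k):
        valid = sorted(folds[f])
        train = sorted(i for g in range(k) if g != f for i in folds[g])
        out.append((train, valid))
    return out


def compare_models(
    per_trial_scores: np.ndarray,
    model_names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[dict]:
    """Pairwise paired t-tests with Bonferroni correction.

    ``per_trial_scores`` is (n_models, n_trials); each pair is tested on the
    per-trial score differences. Zero-variance differences are reported as
    exact ties (p = 1, t = 0).
    """
    scores = np.asarray(per_trial_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need a (>=2 models, trials) score matrix")
    m = scores.shape[0]
    names = list(model_names) if model_names else [f"model{i}" for i in range(m)]
    n_comparisons = m * (m - 1) // 2
    threshold = alpha / n_comparisons

    results = []
    for i in range(m):
        for j in range(i + 1, m):
            d = scores[i] - scores[j]
            if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0) and \
                    np.allclose(d, d[0] if d.size else 0.0):
                if np.allclose(d, 0.0):
                    t_stat, p_raw = 0.0, 1.0
                else:
                    t_stat = float("inf") if d[0] > 0 else float("-inf")
                    p_raw = 0.0
            else:
                t_stat, p_raw = sp_stats.ttest_rel(scores[i], scores[j])
                t_stat, p_raw = float(t_stat), float(p_raw)
            results.append(
                {
                    "pair": (names[i], names[j]),
                    "t": t_stat,
                    "p_raw": p_raw,
                    "alpha_adjusted": threshold,
                    "significant": bool(p_raw < threshold),
                    "n_comparisons": n_comparisons,
                }
            )
    return results
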