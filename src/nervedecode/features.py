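"""Temporal feature extraction over overlapped 100-ms windows.

Fourteen scalar features are computed per channel per window; a 4-s,
16-channel trial at 5 kHz with a 20-ms step yields a 224 x 200 matrix
(channel-major rows: ch1 F1..F14, ch2 F1..F14, ...).

Conventions (fixed here because the usual formulas leave them open):

* sgn(u) in the counting features (ZC, SSC, WA, MPR) is the indicator
  1[u > 0]; ties count as zero events.
* logarithms are natural (MFL, LD); LD floors |x_i| at 1e-12, and MFL of a
  zero-variation window is defined as 0 so every feature is finite and an
  all-zero window maps to (approximately) the zero vector.
* x_std is the sample standard deviation (N-1 denominator).
* V3 uses the signed real cube root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import Trial

FEATURE_IDS = (
    "ZC", "SSC", "WL", "WA", "MAB", "MSQ", "RMS",
    "V3", "LD", "DABS", "MFL", "MPR", "MAVS", "WMA",
)
N_FEATURES = len(FEATURE_IDS)

LD_FLOOR = 1e-12

DEFAULT_WINDOW_MS = 100.0
DEFAULT_STEP_MS = 20.0


@dataclass
class FeatureWindow:
    """One channel's samples over a single feature window."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        if self.x.size < 3:
            raise ValueError("feature window needs at least 3 samples")

    @property
    def x_std(self) -> float:
        return float(self.x.std(ddof=1))


def _wma_weights(n: int) -> np.ndarray:
    """Half weight on the first and last quarter of the window (1-based
    index i gets weight 1 iff 0.25*N <= i <= 0.75*N)."""
    i = np.arange(1, n + 1)
    return np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)


def feature_block(windows: np.ndarray) -> np.ndarray:
    """Compute all 14 features for a stack of windows.

    ``windows`` has shape (..., N); the result has shape (..., 14) ordered
    as ``FEATURE_IDS``.
    """
    w = np.asarray(windows, dtype=float)
    n = w.shape[-1]
    if n < 3:
        raise ValueError("feature windows need at least 3 samples")

    mean = w.mean(axis=-1, keepdims=True)
    demeaned = w - mean
    diff = np.diff(w, axis=-1)
    abs_w = np.abs(w)
    abs_diff = np.abs(diff)
    std = w.std(axis=-1, ddof=1)

    zc = (-demeaned[..., :-1] * demeaned[..., 1:] > 0).sum(axis=-1)
    ssc = (-diff[..., 1:] * diff[..., :-1] > 0).sum(axis=-1)
    wl = abs_diff.sum(axis=-1)
    wa = (abs_diff > std[..., None]).sum(axis=-1)
    mab = abs_w.mean(axis=-1)
    msq = (w ** 2).mean(axis=-1)
    rms = np.sqrt(msq)
    v3 = np.cbrt((w ** 3).mean(axis=-1))
    ld = np.exp(np.log(np.maximum(abs_w, LD_FLOOR)).mean(axis=-1))
    sumsq_diff = (diff ** 2).sum(axis=-1)
    dabs = np.sqrt(sumsq_diff / (n - 1))
    with np.errstate(divide="ignore"):
        mfl = np.where(sumsq_diff > 0, 0.5 * np.log(sumsq_diff), 0.0)
    mpr = (abs_w > std[..., None]).sum(axis=-1)
    half = n // 2
    mavs = (
        abs_w[..., :half].sum(axis=-1) - abs_w[..., half:].sum(axis=-1)
    ) / half
    wma = (abs_w * _wma_weights(n)).mean(axis=-1)

    return np.stack(
        [zc, ssc, wl, wa, mab, msq, rms, v3, ld, dabs, mfl, mpr, mavs, wma],
        axis=-1,
    ).astype(float)


def compute_feature(feature_id: str, window: FeatureWindow | np.ndarray) -> float:
    """Single feature value for one window; ``feature_id`` in F1..F14 or a
    mnemonic from ``FEATURE_IDS``."""
    if isinstance(feature_id, str) and feature_id.upper().startswith("F") and \
            feature_id[1:].isdigit():
        idx = int(feature_id[1:]) - 1
        if not 0 <= idx < N_FEATURES:
            raise ValueError(f"unknown feature id: {feature_id!r}")
    else:
        try:
            idx = FEATURE_IDS.index(str(feature_id).upper())
        except ValueError:
            raise ValueError(f"unknown feature id: {feature_id!r}") from None
    x = window.x if isinstance(window, FeatureWindow) else np.asarray(window, float)
    if x.size < 3:
        raise ValueError("feature window needs at least 3 samples")
    return float(feature_block(x)[idx])


@dataclass
class FeatureMatrix:
    """Per-trial decoder input: (16 ch x 14 features) x time steps."""

    values: np.ndarray  # (224, n_steps)
    row_index: tuple[tuple[int, str], ...]  # (channel, feature id) per row
    norm_constants: np.ndarray | None = None  # (14,), per feature type

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


def row_index(n_channels: int = 16) -> tuple[tuple[int, str], ...]:
    """Channel-major (channel, feature) ordering of matrix rows."""
    return tuple(
        (ch, fid) for ch in range(n_channels) for fid in FEATURE_IDS
    )


def _windows_ending_at_steps(
    padded: np.ndarray, n_win: int, n_step: int, n_cols: int
) -> np.ndarray:
    """(channels, n_cols, n_win) windows stepping by ``n_step``; column j
    ends ``(j+1) * n_step`` samples past the pad boundary."""
    view = sliding_window_view(padded, n_win, axis=1)
    return view[:, : (n_cols - 1) * n_step + 1 : n_step]


def extract_grid(
    samples: np.ndarray,
    sample_rate: float,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> np.ndarray:
    """Feature columns on the global 20-ms grid of a whole recording.

    Column j (0-based) is computed from the ``window_ms`` of samples ending
    at time (j+1) * step_ms; the first window_ms/step_ms - 1 columns are
    left-zero-padded (no earlier context exists at the recording start).
    Any 4-s trial starting at sample s (a multiple of the step) is the slice
    ``grid[:, s // n_step : s // n_step + 200]``.
    """
    samples = np.asarray(samples, dtype=float)
    n_win = int(round(window_ms / 1000.0 * sample_rate))
    n_step = int(round(step_ms / 1000.0 * sample_rate))
    if n_win % n_step:
        raise ValueError("window must be an integer number of steps")
    n_cols = samples.shape[1] // n_step
    pad = n_win - n_step
    n_ch = samples.shape[0]

    out = np.empty((n_ch * N_FEATURES, n_cols))
    # Per-channel to bound the strided-view expansion's memory footprint.
    for ch in range(n_ch):
        padded = np.concatenate([np.zeros(pad), samples[ch]])[None, :]
        wins = _windows_ending_at_steps(padded, n_win, n_step, n_cols)
        out[ch * N_FEATURES : (ch + 1) * N_FEATURES] = feature_block(
            wins[0]
        ).T
    return out


def feature_matrix(
    trial: Trial,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> FeatureMatrix:
    """Assemble the per-trial feature matrix (224 x 200 for a 4-s trial).

    Column t (1-based) is computed from the ``window_ms`` of samples ending
    at t * step_ms into the trial. The first window_ms/step_ms - 1 columns
    need samples from before the trial start: real preceding samples from
    the parent recording are used when available (pseudo-online), otherwise
    the window is left-zero-padded.
    """
    if abs(window_ms / step_ms - 5.0) > 1e-9:
        raise ValueError("window/step must be 5 (80% overlap)")
    fs = trial.sample_rate
    n_win = int(round(window_ms / 1000.0 * fs))
    n_step = int(round(step_ms / 1000.0 * fs))
    if trial.window_samples % n_step:
        raise ValueError("trial length is not a whole number of steps")
    n_cols = trial.window_samples // n_step
    pad = n_win - n_step

    n_ch = trial.signal.shape[0]
    context = np.zeros((n_ch, pad))
    if trial.parent is not None and trial.start_index > 0:
        avail = min(pad, trial.start_index)
        context[:, pad - avail :] = trial.parent.samples[
            :, trial.start_index - avail : trial.start_index
        ]
    padded = np.concatenate([context, trial.signal], axis=1)

    wins = _windows_ending_at_steps(padded, n_win, n_step, n_cols)
    feats = feature_block(wins)  # (ch, n_cols, 14)
    values = feats.transpose(0, 2, 1).reshape(n_ch * N_FEATURES, n_cols)
    return FeatureMatrix(values=values, row_index=row_index(n_ch))


def fit_norm_constants(
    values: np.ndarray, percentile: float = 99.0, floor: float = 1e-12
) -> np.ndarray:
    """One positive constant per feature type, shared across channels:
    the ``percentile`` of |value| over the fit set.

    ``values`` is any (n_ch * 14, n_cols) stack of feature columns from the
    *training split only*; held-out data must reuse the returned constants.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] % N_FEATURES:
        raise ValueError("expected a (channels*14, columns) array")
    n_ch = values.shape[0] // N_FEATURES
    per_feature = np.abs(
        values.reshape(n_ch, N_FEATURES, -1).transpose(1, 0, 2).reshape(
            N_FEATURES, -1
        )
    )
    consts = np.percentile(per_feature, percentile, axis=1)
    return np.maximum(consts, floor)


def fit_normalizer(
    matrices: list[FeatureMatrix], percentile: float = 99.0
) -> np.ndarray:
    """Spec-surface wrapper over ``fit_norm_constants`` for FeatureMatrix
    lists."""
    if not matrices:
        raise ValueError("need at least one matrix")
    stacked = np.concatenate([m.values for m in matrices], axis=1)
    return fit_norm_constants(stacked, percentile=percentile)


def apply_normalizer(values: np.ndarray, norm_constants: np.ndarray) -> np.ndarray:
    """Divide each row by its feature type's constant (no refitting)."""
    values = np.asarray(values, dtype=float)
    consts = np.asarray(norm_constants, dtype=float)
    if consts.shape != (N_FEATURES,):
        raise ValueError("norm_constants must have shape (14,)")
    if (consts <= 0).any():
        raise ValueError("norm_constants must be strictly positive")
    n_ch = values.shape[0] // N_FEATURES
    return values / np.tile(consts, n_ch)[:, None]


def normalize(matrix: FeatureMatrix, norm_constants: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=apply_normalizer(matrix.values, norm_constants),
        row_index=matrix.row_index,
        norm_constants=np.asarray(norm_constants, float).copy(),
    )
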