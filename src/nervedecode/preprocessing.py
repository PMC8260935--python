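"""Raw-recording conditioning and pseudo-online trial cutting.

The decoding pipeline consumes 4-s causal windows stepped at 100 ms over a
band-limited 5 kHz stream; each window becomes one ``Trial`` whose label is
derived from the glove trajectory within the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .gestures import N_FINGERS
from .synth import N_DOF, NerveRecording, TrajectorySet

#: Trajectory/feature step inside a trial (s): one label per 20 ms.
TRAJ_STEP_S = 0.02

DEFAULT_ACTIVITY_THRESHOLD = 0.1


@dataclass
class Trial:
    """One causal 4-s slice of a session.

    ``signal`` is a *view* into the parent recording (no copy); mutating the
    parent mutates the trial. ``trajectory`` holds one ground-truth value per
    20-ms step, sampled at each step's end. ``t_end`` is the time of the
    trial's last sample in the parent recording.
    """

    signal: np.ndarray  # (16, window_samples), view
    trajectory: np.ndarray  # (10, window_s / 20 ms)
    finger_state: np.ndarray  # (5,) int8
    t_end: float
    start_index: int
    end_index: int  # exclusive
    sample_rate: float
    parent: NerveRecording | None = field(default=None, repr=False)

    @property
    def window_samples(self) -> int:
        return self.end_index - self.start_index

    @property
    def n_steps(self) -> int:
        return self.trajectory.shape[1]


def bandlimit(
    recording: NerveRecording,
    low_hz: float = 25.0,
    high_hz: float = 600.0,
    target_rate: float = 5000.0,
    order: int = 5,
) -> NerveRecording:
    """Downsample to ``target_rate`` then band-pass to [low_hz, high_hz].

    Zero-phase (forward-backward) Butterworth filtering; an anti-alias
    low-pass precedes decimation. Offline use only — a real-time port must
    substitute causal filters.
    """
    if not low_hz < high_hz:
        raise ValueError("band edges inverted")
    if high_hz >= target_rate / 2:
        raise ValueError("high_hz must be below the target Nyquist rate")
    if recording.sample_rate < target_rate:
        raise ValueError("recording rate must be >= target_rate")
    ratio = recording.sample_rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(
            f"decimation ratio {ratio} is not an integer multiple"
        )

    x = recording.samples
    if q > 1:
        sos_aa = sps.butter(
            8, 0.45 * target_rate, btype="lowpass",
            fs=recording.sample_rate, output="sos",
        )
        x = sps.sosfiltfilt(sos_aa, x, axis=1)[:, ::q]

    sos = sps.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=target_rate,
        output="sos",
    )
    x = sps.sosfiltfilt(sos, x, axis=1)
    return NerveRecording(
        samples=np.ascontiguousarray(x),
        sample_rate=target_rate,
        channel_nerve=recording.channel_nerve,
    )


def trial_count(n_samples: int, n_window: int, n_step: int) -> int:
    """Number of causal windows; exact integer-sample arithmetic."""
    if n_window > n_samples:
        raise ValueError("window longer than recording")
    return (n_samples - n_window) // n_step + 1


def cut_trials(
    recording: NerveRecording,
    trajectories: TrajectorySet,
    window_s: float = 4.0,
    step_s: float = 0.1,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> list[Trial]:
    """Cut a session into overlapping causal trials.

    Trials end at t = window_s, window_s + step_s, ...; a finger is labelled
    active when either of its DOF exceeds ``activity_threshold`` anywhere in
    the window. Counting and slicing are done in integer sample indices to
    avoid float rounding.
    """
    fs = recording.sample_rate
    if trajectories.sample_rate != fs:
        raise ValueError("recording and trajectories must share a sample rate")
    if trajectories.n_samples != recording.n_samples:
        raise ValueError("recording and trajectories must be time-aligned")

    n_window = int(round(window_s * fs))
    n_step = int(round(step_s * fs))
    n_traj_step = int(round(TRAJ_STEP_S * fs))
    if n_window % n_traj_step:
        raise ValueError("window must be a whole number of 20-ms steps")
    n_cols = n_window // n_traj_step

    n = trial_count(recording.n_samples, n_window, n_step)
    # Trajectory value at the end of each 20-ms step inside the window.
    col_offsets = (np.arange(1, n_cols + 1) * n_traj_step) - 1

    trials: list[Trial] = []
    traj = trajectories.values
    for i in range(n):
        start = i * n_step
        end = start + n_window
        tr = traj[:, start + col_offsets]
        window_max = traj[:, start:end].max(axis=1)  # per DOF
        finger_active = (
            window_max.reshape(N_FINGERS, 2).max(axis=1) > activity_threshold
        )
        trials.append(
            Trial(
                signal=recording.samples[:, start:end],
                trajectory=tr,
                finger_state=finger_active.astype(np.int8),
                t_end=end / fs,
                start_index=start,
                end_index=end,
                sample_rate=fs,
                parent=recording,
            )
        )
    return trials


def bitrate(
    n_channels: int, rate_per_channel_hz: float, bits_per_value: int
) -> float:
    """Aggregate stream rate in kbps: channels x values/s x bits / 1000."""
    if n_channels <= 0 or rate_per_channel_hz <= 0 or bits_per_value < 0:
        raise ValueError("n_channels and rate must be positive, bits >= 0")
    return n_channels * rate_per_channel_hz * bits_per_value / 1000.0
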