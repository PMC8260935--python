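"""Synthetic training-session generator.

Emulates a mirrored-bilateral recording session: 16 nerve channels (1-8
"median", 9-16 "ulnar") carrying band-limited 25-600 Hz stochastic activity
whose per-channel amplitude is modulated by the intent envelopes of the
active fingers, time-locked to 10-DOF glove trajectories in [0, 1]. Each
gesture repetition is one cycle alternating rest -> flex -> rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .gestures import FINGERS, GestureCode, codebook, lookup

N_CHANNELS = 16
N_DOF = 10
CARRIER_BAND = (25.0, 600.0)

#: Per-finger joint gains: one shared intent envelope drives both DOF of a
#: finger, scaled for the MCP and PIP joints respectively.
MCP_GAIN = 1.0
PIP_GAIN = 0.9


def default_gain_map() -> np.ndarray:
    """Default 16x5 finger->channel modulation gain matrix.

    Each finger projects a Gaussian bump of gain across neighbouring
    channels, thumb-to-little laid out across the array; the thumb is
    restricted to the median group (channels 1-8), so its gain on the ulnar
    group is exactly zero.
    """
    centers = np.array([1.5, 4.5, 7.0, 10.0, 13.5])  # thumb..little
    sigma = 1.7
    ch = np.arange(N_CHANNELS)[:, None]
    gains = np.exp(-0.5 * ((ch - centers[None, :]) / sigma) ** 2)
    gains[8:, 0] = 0.0  # thumb: median-nerve localization
    gains[gains < 1e-3] = 0.0
    return gains


@dataclass
class SessionConfig:
    """Parameters of one synthetic recording session."""

    n_repetitions: int = 10
    sample_rate: float = 5000.0
    cycle_duration: float = 4.0
    snr_db: float = 20.0
    channel_gain_map: np.ndarray = field(default_factory=default_gain_map)
    rng_seed: int = 0
    baseline: float = 0.25
    rise_time: float = 0.4
    flex_start_frac: float = 0.2
    flex_end_frac: float = 0.8
    #: False: all repetitions of one gesture are contiguous (one recording
    #: block per gesture); True: the schedule cycles through the gesture
    #: list, which spreads every gesture across the session timeline.
    interleave: bool = False

    def __post_init__(self) -> None:
        self.channel_gain_map = np.asarray(self.channel_gain_map, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.sample_rate <= 2 * CARRIER_BAND[1]:
            raise ValueError(
                f"sample_rate must exceed {2 * CARRIER_BAND[1]:.0f} Hz "
                f"(twice the {CARRIER_BAND[1]:.0f} Hz band edge)"
            )
        if math.isnan(self.snr_db) or self.snr_db == -math.inf:
            # +inf is meaningful (no additive noise); NaN / -inf are not.
            raise ValueError("snr_db must be a real number or +inf")
        if self.channel_gain_map.shape != (N_CHANNELS, len(FINGERS)):
            raise ValueError("channel_gain_map must be 16 x 5")
        if (self.channel_gain_map < 0).any():
            raise ValueError("channel_gain_map must be non-negative")
        thumb_ulnar = self.channel_gain_map[8:, 0]
        if (np.abs(thumb_ulnar) > 1e-6).any():
            raise ValueError("thumb gain on ulnar channels (9-16) must be ~0")
        if not 0 <= self.flex_start_frac < self.flex_end_frac <= 1:
            raise ValueError("flex window fractions must satisfy 0<=start<end<=1")

    def with_(self, **kw) -> "SessionConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "n_repetitions": self.n_repetitions,
            "sample_rate": self.sample_rate,
            "cycle_duration": self.cycle_duration,
            "snr_db": self.snr_db,
            "channel_gain_map": self.channel_gain_map.tolist(),
            "rng_seed": self.rng_seed,
            "baseline": self.baseline,
            "rise_time": self.rise_time,
            "flex_start_frac": self.flex_start_frac,
            "flex_end_frac": self.flex_end_frac,
            "interleave": self.interleave,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "channel_gain_map" in d:
            d["channel_gain_map"] = np.asarray(d["channel_gain_map"], float)
        return cls(**d)


@dataclass
class NerveRecording:
    """Multi-channel time series with its rate and channel->nerve map."""

    samples: np.ndarray  # (16, T)
    sample_rate: float
    channel_nerve: tuple[str, ...] = tuple(
        ["median"] * 8 + ["ulnar"] * 8
    )

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, T) matrix")
        if len(self.channel_nerve) != self.samples.shape[0]:
            raise ValueError("channel_nerve length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class TrajectorySet:
    """10-DOF finger-joint trajectories in [0, 1], 0 = resting.

    Rows 2k and 2k+1 (0-based) are the MCP and PIP joints of finger k
    (thumb-first ordering).
    """

    values: np.ndarray  # (10, T)
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_DOF:
            raise ValueError("values must be a (10, T) matrix")
        if self.values.size and (
            self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise ValueError("trajectory values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def cycle_envelope(config: SessionConfig, t: np.ndarray) -> np.ndarray:
    """Raised-cosine rest->flex->rest intent envelope over one cycle.

    ``t`` is time within the cycle, in seconds. The envelope is 0 outside
    [flex_start, flex_end] * cycle_duration, 1 on the interior plateau, with
    raised-cosine transitions of ``rise_time`` seconds.
    """
    c = config.cycle_duration
    a = config.flex_start_frac * c
    b = config.flex_end_frac * c
    r = min(config.rise_time, (b - a) / 2)
    env = np.zeros_like(t, dtype=float)
    rising = (t >= a) & (t < a + r)
    env[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - a) / r))
    env[(t >= a + r) & (t <= b - r)] = 1.0
    falling = (t > b - r) & (t <= b)
    env[falling] = 0.5 * (1 - np.cos(np.pi * (b - t[falling]) / r))
    return env


def gesture_schedule(
    config: SessionConfig, gestures: list[GestureCode]
) -> list[dict]:
    """Deterministic repetition schedule: one entry per 4-s cycle.

    Blocked order (default): all repetitions of one gesture back-to-back.
    Interleaved order (``config.interleave``): cycle through the gesture
    list ``n_repetitions`` times.
    """
    if config.interleave:
        ordered = [g for _ in range(config.n_repetitions) for g in gestures]
    else:
        ordered = [g for g in gestures for _ in range(config.n_repetitions)]
    sched = []
    t = 0.0
    for g in ordered:
        sched.append(
            {"name": g.name, "start": t, "end": t + config.cycle_duration}
        )
        t += config.cycle_duration
    return sched


def finger_envelopes(
    config: SessionConfig, gestures: list[GestureCode]
) -> np.ndarray:
    """(5, T) per-finger intent envelopes for the whole session."""
    fs = config.sample_rate
    n_cycle = int(round(config.cycle_duration * fs))
    t_cycle = np.arange(n_cycle) / fs
    env_cycle = cycle_envelope(config, t_cycle)
    sched = gesture_schedule(config, gestures)
    by_name = {g.name: g for g in gestures}
    env = np.zeros((len(FINGERS), n_cycle * len(sched)))
    for k, entry in enumerate(sched):
        g = by_name[entry["name"]]
        for f in g.active_fingers:
            env[f, k * n_cycle : (k + 1) * n_cycle] = env_cycle
    return env


def _bandlimited_carrier(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to the carrier band."""
    white = rng.standard_normal((n_channels, n_samples))
    sos = sps.butter(4, CARRIER_BAND, btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, white, axis=1)
    std = carrier.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return carrier / std


def generate_session(
    config: SessionConfig, gestures: list[GestureCode] | None = None
) -> tuple[NerveRecording, TrajectorySet]:
    """Simulate one session: nerve-like recording + aligned glove truth.

    Each channel is ``(baseline + sum_f gain[ch,f] * envelope_f(t)) *
    carrier(t) + noise(t)`` where the carrier is unit-variance 25-600 Hz
    Gaussian noise and the additive white noise is scaled so that the
    modulated component's variance over the session exceeds the noise
    variance by ``snr_db`` decibels (per channel). Identical (config,
    gestures) produce bit-identical output.
    """
    if gestures is None:
        gestures = codebook()
    gestures = [g if isinstance(g, GestureCode) else lookup(g) for g in gestures]
    config.validate()

    fs = config.sample_rate
    env = finger_envelopes(config, gestures)  # (5, T)
    n_total = env.shape[1]

    rng = np.random.default_rng(config.rng_seed)
    carrier = _bandlimited_carrier(rng, N_CHANNELS, n_total, fs)
    # Noise occupies the same 25-600 Hz band as the carrier so that snr_db
    # genuinely trades off decodability (out-of-band white noise would be
    # averaged away by the downstream 100-ms feature windows).
    noise_draw = _bandlimited_carrier(rng, N_CHANNELS, n_total, fs)

    modulation = config.channel_gain_map @ env  # (16, T)
    amplitude = config.baseline + modulation
    samples = amplitude * carrier

    if config.snr_db != math.inf:
        # Per-channel SNR = modulated-component variance during activity /
        # additive-noise variance. Conditioning on active samples makes the
        # SNR independent of how much of the session is rest.
        mod_sig = modulation * carrier
        mod_var = np.zeros(N_CHANNELS)
        for ch in range(N_CHANNELS):
            active = modulation[ch] > 0
            if active.any():
                mod_var[ch] = mod_sig[ch, active].var()
        noise_var = mod_var / (10.0 ** (config.snr_db / 10.0))
        samples = samples + np.sqrt(noise_var)[:, None] * noise_draw

    traj = np.zeros((N_DOF, n_total))
    traj[0::2] = MCP_GAIN * env
    traj[1::2] = PIP_GAIN * env

    recording = NerveRecording(samples=samples, sample_rate=fs)
    trajectories = TrajectorySet(values=traj, sample_rate=fs)
    return recording, trajectories
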