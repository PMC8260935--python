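"""Session/model persistence and provenance stamping.

A session is stored as one ``.npz`` array container (``samples`` 16xT,
``trajectories`` 10xT) plus a JSON sidecar carrying the generating config,
the gesture schedule, the seed, and a config hash. Trajectories can also be
exported as CSV (one column per DOF).
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path

import numpy as np

from . import __version__
from .gestures import FINGERS
from .synth import NerveRecording, SessionConfig, TrajectorySet

DOF_NAMES = tuple(
    f"{finger}_{joint}" for finger in FINGERS for joint in ("MCP", "PIP")
)


def config_hash(payload: dict) -> str:
    """Stable digest of a JSON-serializable config document."""
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def provenance(cfg_hash: str, seed: int) -> dict:
    return {"config_hash": cfg_hash, "seed": seed, "code_version": __version__}


def save_session(
    path: str | Path,
    recording: NerveRecording,
    trajectories: TrajectorySet,
    config: SessionConfig,
    schedule: list[dict] | None = None,
) -> Path:
    """Write session arrays to ``<path>.npz`` and metadata to
    ``<path>.json``; returns the npz path."""
    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    npz_path = path.with_suffix(".npz")
    np.savez(
        npz_path,
        samples=recording.samples,
        trajectories=trajectories.values,
    )
    cfg = config.to_dict()
    sidecar = {
        "config": cfg,
        "schedule": schedule or [],
        "sample_rate": recording.sample_rate,
        "channel_nerve": list(recording.channel_nerve),
        **provenance(config_hash(cfg), config.rng_seed),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return npz_path


def load_session(
    path: str | Path,
) -> tuple[NerveRecording, TrajectorySet, SessionConfig, list[dict]]:
    path = Path(path)
    if path.suffix == ".npz":
        path = path.with_suffix("")
    with np.load(path.with_suffix(".npz")) as data:
        samples = data["samples"]
        traj = data["trajectories"]
    meta = json.loads(path.with_suffix(".json").read_text())
    config = SessionConfig.from_dict(meta["config"])
    recording = NerveRecording(
        samples=samples,
        sample_rate=meta["sample_rate"],
        channel_nerve=tuple(meta["channel_nerve"]),
    )
    trajectories = TrajectorySet(values=traj, sample_rate=meta["sample_rate"])
    return recording, trajectories, config, meta["schedule"]


def export_trajectories_csv(path: str | Path, trajectories: TrajectorySet) -> Path:
    """CSV with one column per DOF (header = DOF names)."""
    path = Path(path)
    header = ",".join(DOF_NAMES)
    np.savetxt(
        path, trajectories.values.T, delimiter=",", header=header,
        comments="", fmt="%.6f",
    )
    return path


def save_models(path: str | Path, bundle: dict) -> Path:
    """Pickle a model bundle (classifier, regressors, norm constants,
    provenance)."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh)
    return path


def load_models(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return pickle.load(fh)
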