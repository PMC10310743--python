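"""HDF5 persistence (NPZ fallback) for stimuli, models, RDMs and results.

Archives carry a format version attribute; readers reject unknown majors.
Rule-based models persist their raw inputs plus a registry key so the rule
can be rebuilt on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .drsa import LagProfile
from .feature_models import RULE_BUILDERS, ModelTimeSeries
from .rdm import RDMSeries, squareform_at
from .synthetic_stimuli import FrameStack, GazeTrace, MarkerTrajectories

FORMAT_VERSION = "1.0"

__all__ = [
    "FORMAT_VERSION",
    "save_stimuli", "load_stimuli",
    "save_models", "load_models",
    "save_rdms", "load_rdms",
    "save_lag_profiles", "load_lag_profiles",
    "export_rdm_csv",
]


def _check_version(attrs) -> None:
    version = attrs.get("format_version")
    if version is None:
        raise ValueError("file has no format_version attribute")
    major = str(version).split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise ValueError(f"unsupported archive format version {version!r}")


def _is_npz(path: str | Path) -> bool:
    return str(path).endswith(".npz")


# ---------------------------------------------------------------------------
# stimuli


def save_stimuli(
    path: str | Path,
    traj: MarkerTrajectories | None = None,
    frames: FrameStack | None = None,
    gaze: GazeTrace | None = None,
    params: dict | None = None,
) -> None:
    if traj is None and frames is None and gaze is None:
        raise ValueError("nothing to save")
    fs = next(o.fs for o in (traj, frames, gaze) if o is not None)
    if _is_npz(path):
        payload = {"format_version": np.bytes_(FORMAT_VERSION), "fs": fs,
                   "params": np.bytes_(json.dumps(params or {}))}
        if traj is not None:
            payload["kinematics"] = traj.positions
            payload["stimulus_ids"] = np.array(traj.stimulus_ids, dtype="S")
        if frames is not None:
            payload["frames"] = frames.frames
        if gaze is not None:
            payload["gaze"] = gaze.gaze
        np.savez(path, **payload)
        return
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["fs"] = fs
        f.attrs["params"] = json.dumps(params or {})
        if traj is not None:
            d = f.create_dataset("kinematics", data=traj.positions)
            d.attrs["stimulus_ids"] = json.dumps(traj.stimulus_ids)
        if frames is not None:
            f.create_dataset("frames", data=frames.frames)
        if gaze is not None:
            f.create_dataset("gaze", data=gaze.gaze)


def load_stimuli(
    path: str | Path,
) -> tuple[MarkerTrajectories | None, FrameStack | None, GazeTrace | None, dict]:
    if _is_npz(path):
        with np.load(path) as z:
            version = z["format_version"].item().decode()
            if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
                raise ValueError(f"unsupported archive format version {version!r}")
            fs = float(z["fs"])
            params = json.loads(z["params"].item().decode())
            traj = frames = gaze = None
            if "kinematics" in z:
                ids = [s.decode() for s in z["stimulus_ids"]]
                traj = MarkerTrajectories(z["kinematics"], fs=fs, stimulus_ids=ids)
            if "frames" in z:
                frames = FrameStack(z["frames"], fs=fs)
            if "gaze" in z:
                gaze = GazeTrace(z["gaze"], fs=fs)
        return traj, frames, gaze, params
    with h5py.File(path, "r") as f:
        _check_version(f.attrs)
        fs = float(f.attrs["fs"])
        params = json.loads(f.attrs.get("params", "{}"))
        traj = frames = gaze = None
        if "kinematics" in f:
            ids = json.loads(f["kinematics"].attrs.get("stimulus_ids", "[]"))
            traj = MarkerTrajectories(f["kinematics"][()], fs=fs,
                                      stimulus_ids=ids or [])
        if "frames" in f:
            frames = FrameStack(f["frames"][()], fs=fs)
        if "gaze" in f:
            gaze = GazeTrace(f["gaze"][()], fs=fs)
    return traj, frames, gaze, params


# ---------------------------------------------------------------------------
# models


def save_models(path: str | Path, models: dict[str, ModelTimeSeries]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        grp = f.create_group("models")
        for name, m in models.items():
            g = grp.create_group(name)
            g.attrs["fs"] = m.fs
            g.attrs["metric"] = m.metric
            g.attrs["extra"] = json.dumps(m.extra)
            if m.features is not None:
                g.create_dataset("features", data=m.features)
            else:
                g.create_dataset("rule_inputs", data=m.rule_inputs)
                g.attrs["rule_kind"] = m.rule_kind


def load_models(path: str | Path) -> dict[str, ModelTimeSeries]:
    out: dict[str, ModelTimeSeries] = {}
    with h5py.File(path, "r") as f:
        _check_version(f.attrs)
        for name, g in f["models"].items():
            fs = float(g.attrs["fs"])
            metric = str(g.attrs["metric"])
            extra = json.loads(g.attrs.get("extra", "{}"))
            if "features" in g:
                out[name] = ModelTimeSeries(name=name, fs=fs, metric=metric,
                                            features=g["features"][()], extra=extra)
            else:
                kind = str(g.attrs["rule_kind"])
                if kind not in RULE_BUILDERS:
                    raise ValueError(f"unknown pairwise rule kind {kind!r}")
                out[name] = RULE_BUILDERS[kind](g["rule_inputs"][()], fs, name, extra)
    return out


# ---------------------------------------------------------------------------
# RDM series


def save_rdms(path: str | Path, rdms: dict[str, RDMSeries]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        grp = f.create_group("rdms")
        for name, r in rdms.items():
            g = grp.create_group(name)
            g.create_dataset("values", data=r.values)
            g.attrs["n_stimuli"] = r.n_stimuli
            g.attrs["fs"] = r.fs
            g.attrs["metric"] = r.metric
            g.attrs["steps"] = json.dumps(list(r.steps))
            g.attrs["meta"] = json.dumps(r.meta)


def load_rdms(path: str | Path) -> dict[str, RDMSeries]:
    out: dict[str, RDMSeries] = {}
    with h5py.File(path, "r") as f:
        _check_version(f.attrs)
        for name, g in f["rdms"].items():
            out[name] = RDMSeries(
                values=g["values"][()],
                n_stimuli=int(g.attrs["n_stimuli"]),
                fs=float(g.attrs["fs"]),
                metric=str(g.attrs["metric"]),
                name=name,
                steps=tuple(json.loads(g.attrs.get("steps", "[]"))),
                meta=json.loads(g.attrs.get("meta", "{}")),
            )
    return out


# ---------------------------------------------------------------------------
# lag profiles


def save_lag_profiles(
    path: str | Path, profiles: dict[str, LagProfile], config: dict | None = None
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config"] = json.dumps(config or {})
        grp = f.create_group("drsa")
        for name, p in profiles.items():
            g = grp.create_group(name)
            g.create_dataset("lags_s", data=p.lags_s)
            g.create_dataset("values", data=p.values)
            g.create_dataset("n_averaged", data=p.n_averaged)
            g.attrs["fs"] = p.fs
            g.attrs["estimator"] = p.estimator


def load_lag_profiles(path: str | Path) -> tuple[dict[str, LagProfile], dict]:
    out: dict[str, LagProfile] = {}
    with h5py.File(path, "r") as f:
        _check_version(f.attrs)
        config = json.loads(f.attrs.get("config", "{}"))
        for name, g in f["drsa"].items():
            out[name] = LagProfile(
                lags_s=g["lags_s"][()], values=g["values"][()],
                n_averaged=g["n_averaged"][()], fs=float(g.attrs["fs"]),
                test_model=name, estimator=str(g.attrs["estimator"]),
            )
    return out, config


def export_rdm_csv(path: str | Path, r: RDMSeries, t: int) -> None:
    """Write the square RDM at one time point as CSV for inspection."""
    mat = squareform_at(r, t)
    labels = [f"stim{i:02d}" for i in range(r.n_stimuli)]
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(path)
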