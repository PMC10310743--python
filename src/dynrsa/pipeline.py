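"""End-to-end workflow: stimuli -> models -> RDMs -> dRSA -> statistics."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .drsa import subsample_and_average
from .feature_models import (
    ModelTimeSeries,
    gaze_model,
    motion_from_features,
    motion_view_invariant,
    optical_flow_model,
    pixelwise_model,
    posture_view_dependent,
    posture_view_invariant,
)
from .io import save_lag_profiles, save_models, save_stimuli
from .neural_sim import ImplantSpec, spawn_subject_specs
from .stats import GroupLagProfiles, cluster_permutation_test, fisher_z
from .synthetic_stimuli import generate_gaze, generate_kinematics, render_frames

log = logging.getLogger(__name__)

__all__ = ["build_model_suite", "run_pipeline"]


def build_model_suite(
    traj, frames=None, gaze=None, sigma: float = 5.0,
    vertical_axis: int = 2, names: list[str] | None = None,
) -> dict[str, ModelTimeSeries]:
    """Compute the requested stimulus-feature models from raw stimulus data.

    Video-based models need ``frames``; the gaze model needs ``gaze``.
    Derivative models (motion, acceleration) are derived from the posture
    features via the shared half-sample-grid convention.
    """
    available = {
        "pixelwise", "flow_magnitude", "flow_direction",
        "posture_vd", "posture_vi", "motion_vd", "motion_vi",
        "accel_vd", "gaze",
    }
    names = list(names) if names is not None else sorted(available)
    unknown = set(names) - available
    if unknown:
        raise ValueError(f"unknown model names: {sorted(unknown)}")

    out: dict[str, ModelTimeSeries] = {}
    need_flow = {"flow_magnitude", "flow_direction"} & set(names)
    if "pixelwise" in names or need_flow:
        if frames is None:
            raise ValueError("video-based models requested but no frames given")
    if "pixelwise" in names:
        out["pixelwise"] = pixelwise_model(frames, sigma=sigma)
    if need_flow:
        mag, direc = optical_flow_model(frames, sigma=sigma)
        if "flow_magnitude" in names:
            out["flow_magnitude"] = mag
        if "flow_direction" in names:
            out["flow_direction"] = direc

    posture = posture_view_dependent(traj)
    if "posture_vd" in names:
        out["posture_vd"] = posture
    if "posture_vi" in names:
        out["posture_vi"] = posture_view_invariant(traj, vertical_axis)
    motion = None
    if {"motion_vd", "accel_vd"} & set(names):
        motion = motion_from_features(posture, name="motion_vd")
    if "motion_vd" in names:
        out["motion_vd"] = motion
    if "accel_vd" in names:
        out["accel_vd"] = motion_from_features(motion, name="accel_vd")
    if "motion_vi" in names:
        out["motion_vi"] = motion_view_invariant(traj, vertical_axis)
    if "gaze" in names:
        if gaze is None:
            raise ValueError("gaze model requested but no gaze traces given")
        out["gaze"] = gaze_model(gaze)
    return {n: out[n] for n in names}


def run_pipeline(config: AnalysisConfig, outdir: str | Path) -> dict:
    """Execute the full workflow and persist results under ``outdir``.

    Stages: simulate stimuli, compute models, run the subsampling dRSA loop
    per simulated subject, and (with >= 5 subjects) group cluster
    statistics.  Each stage failure aborts with the stage name; per-stage
    timings and all seeds are written to run_log.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: list[dict] = []
    results: dict = {"config": config.to_dict()}

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            value = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings.append({"stage": name, "seconds": time.perf_counter() - t0})
        log.info("stage %s: %.2f s", name, timings[-1]["seconds"])
        return value

    sc = config.stimuli

    def _stimuli():
        traj = generate_kinematics(sc.n_stimuli, sc.n_markers, sc.duration_s,
                                   sc.fs, sc.cutoff_hz, seed=config.seed)
        need_frames = bool(
            {"pixelwise", "flow_magnitude", "flow_direction"} & set(config.models.names))
        frames = render_frames(traj, sc.height, sc.width, sc.marker_sigma) if need_frames else None
        gz = generate_gaze(sc.n_stimuli, sc.duration_s, sc.fs, sc.cutoff_hz,
                           seed=config.seed + 1) if "gaze" in config.models.names else None
        save_stimuli(outdir / "stimuli.h5", traj, frames, gz,
                     params={"seed": config.seed})
        return traj, frames, gz

    traj, frames, gz = _stage("simulate-stimuli", _stimuli)

    models = _stage("compute-models", lambda: build_model_suite(
        traj, frames, gz, sigma=config.models.sigma,
        vertical_axis=config.models.vertical_axis, names=config.models.names))
    _stage("save-models", lambda: save_models(outdir / "models.h5", models))

    implant = ImplantSpec(
        components=[(n, float(w), float(l)) for n, w, l in config.neural.implants],
        noise_weight=config.neural.noise_weight, seed=config.seed + 2)
    test_models = config.test_models or list(models)

    def _drsa():
        subject_specs = spawn_subject_specs(implant, config.neural.n_subjects)
        per_subject = []
        for subj, spec in enumerate(subject_specs):
            cfg = config.drsa
            profiles = subsample_and_average(
                models, spec, cfg, test_models=test_models,
                estimator=config.estimator, kernel_ms=config.kernel_ms)
            per_subject.append(profiles)
            log.info("subject %d/%d done", subj + 1, len(subject_specs))
        return per_subject

    per_subject = _stage("drsa", _drsa)
    save_lag_profiles(outdir / "drsa.h5", per_subject[0], config=config.to_dict())
    results["profiles"] = per_subject

    rows = []
    for name in test_models:
        for subj, profiles in enumerate(per_subject):
            p = profiles[name]
            for lag, val, n in zip(p.lags_s, p.values, p.n_averaged):
                rows.append({"model": name, "subject": subj, "lag_s": lag,
                             "value": val, "n_averaged": n})
    pd.DataFrame(rows).to_csv(outdir / "lag_profiles.csv", index=False)

    if config.neural.n_subjects >= 5:
        def _stats():
            out = {}
            for name in test_models:
                group = GroupLagProfiles.from_profiles(
                    [p[name] for p in per_subject])
                group.values = fisher_z(group.values)
                group.transformed = True
                out[name] = cluster_permutation_test(
                    group, sample_alpha=config.stats.sample_alpha,
                    cluster_alpha=config.stats.cluster_alpha,
                    n_perm=config.stats.n_perm, seed=config.seed + 3)
            return out

        cluster_results = _stage("stats", _stats)
        results["clusters"] = cluster_results
        rows = []
        for name, res in cluster_results.items():
            for c in res.clusters:
                rows.append({"model": name, **{k: v for k, v in c.items()
                                               if not k.endswith("index")}})
        pd.DataFrame(rows).to_csv(outdir / "clusters.csv", index=False)

    config.to_yaml(outdir / "config.yaml")
    pd.DataFrame(timings).to_csv(outdir / "run_log.csv", index=False)
    results["timings"] = timings
    return results
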