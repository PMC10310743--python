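"""Stimulus-feature models.

Each model either exposes per-timepoint feature vectors (pixelwise, optical
flow, view-dependent posture/motion, gaze) or, where pair-specific alignment
makes features non-vectorizable (view-invariant posture/motion), a pairwise
dissimilarity rule applied to stored raw inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_ilk

from .synthetic_stimuli import FrameStack, GazeTrace, MarkerTrajectories

log = logging.getLogger(__name__)

__all__ = [
    "ModelTimeSeries",
    "pixelwise_model",
    "optical_flow_model",
    "posture_view_dependent",
    "posture_view_invariant",
    "motion_view_invariant",
    "motion_from_features",
    "gaze_model",
    "view_invariant_posture_dissim",
    "constrained_vertical_procrustes",
]

PairwiseRule = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class ModelTimeSeries:
    """Per-stimulus, per-timepoint representation of one stimulus model.

    Exactly one of ``features`` / ``pairwise_rule`` drives dissimilarity:

    * ``features`` (n_stimuli, n_feat, n_time): pairwise dissimilarity is the
      model metric applied to feature vectors at matching time points.
    * ``pairwise_rule``: a callable ``rule(a, b) -> float`` applied to the
      per-timepoint columns of ``rule_inputs`` (n_stimuli, n_in, n_time).
    """

    name: str
    fs: float
    metric: str  # "one_minus_pearson" | "euclidean"
    features: np.ndarray | None = None
    pairwise_rule: PairwiseRule | None = None
    rule_inputs: np.ndarray | None = None
    rule_kind: str | None = None  # registry key for persistence
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in ("one_minus_pearson", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")
        has_feat = self.features is not None
        has_rule = self.pairwise_rule is not None
        if has_feat == has_rule:
            raise ValueError("exactly one of features / pairwise_rule must be set")
        if has_rule and self.rule_inputs is None:
            raise ValueError("pairwise_rule models need rule_inputs")
        arr = self.features if has_feat else self.rule_inputs
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError("feature arrays must be (n_stimuli, n_feat, n_time)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"model {self.name!r}: non-finite feature values")
        if has_feat:
            self.features = arr
        else:
            self.rule_inputs = arr

    @property
    def _data(self) -> np.ndarray:
        return self.features if self.features is not None else self.rule_inputs

    @property
    def n_stimuli(self) -> int:
        return self._data.shape[0]

    @property
    def n_time(self) -> int:
        return self._data.shape[2]

    def slice_time(self, starts, length: int) -> "ModelTimeSeries":
        """Extract a window per stimulus (one start per stimulus, or a scalar)."""
        starts = np.broadcast_to(np.asarray(starts, dtype=int), (self.n_stimuli,))
        data = self._data
        if (starts < 0).any() or (starts + length > self.n_time).any():
            raise ValueError("slice window outside the series")
        sliced = np.stack([data[s, :, a : a + length] for s, a in enumerate(starts)])
        kw = dict(name=self.name, fs=self.fs, metric=self.metric,
                  rule_kind=self.rule_kind, extra=dict(self.extra))
        if self.features is not None:
            return ModelTimeSeries(features=sliced, **kw)
        return ModelTimeSeries(pairwise_rule=self.pairwise_rule, rule_inputs=sliced, **kw)


# ---------------------------------------------------------------------------
# video-based models


def pixelwise_model(frames: FrameStack, sigma: float = 5.0) -> ModelTimeSeries:
    """Gaussian-smoothed grayscale luminance, vectorized per frame."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = np.asarray(frames.frames, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("frames contain non-finite values")
    smoothed = ndimage.gaussian_filter(arr, sigma=(0, sigma, sigma, 0))
    n_stim, h, w, n_time = smoothed.shape
    feats = smoothed.reshape(n_stim, h * w, n_time)
    return ModelTimeSeries(name="pixelwise", fs=frames.fs,
                           metric="one_minus_pearson", features=feats)


def _interp_half_grid(d: np.ndarray) -> np.ndarray:
    """Resample derivative samples from the half-sample grid to the frame grid.

    ``d`` holds differences along its last axis: d[..., i] belongs between
    frames i and i+1 (time i + 0.5).  Linear interpolation back onto integer
    frames gives the two-sided average in the interior and duplicates the
    nearest difference at both edges, keeping the series length unchanged.
    """
    n = d.shape[-1] + 1
    out = np.empty(d.shape[:-1] + (n,), dtype=d.dtype)
    out[..., 0] = d[..., 0]
    out[..., -1] = d[..., -1]
    if n > 2:
        out[..., 1:-1] = 0.5 * (d[..., :-1] + d[..., 1:])
    return out


def optical_flow_model(
    frames: FrameStack, sigma: float = 5.0, radius: int = 7
) -> tuple[ModelTimeSeries, ModelTimeSeries]:
    """Dense per-pixel optical flow between consecutive frames.

    Uses iterative Lucas-Kanade flow, spatially smoothed with the same
    Gaussian as the pixelwise model, then split into scalar magnitude
    (n_pixels features) and raw 2D direction vectors (2*n_pixels features;
    unnormalized, so zero-flow pixels stay well defined).  Flow estimated
    between frames t-1 and t sits on the half-sample grid and is linearly
    interpolated back onto the frame grid (edges duplicated).
    """
    if frames.n_time < 2:
        raise ValueError("optical flow needs at least 2 frames")
    arr = np.asarray(frames.frames, dtype=np.float64)
    n_stim, h, w, n_time = arr.shape
    n_pix = h * w
    mag = np.empty((n_stim, n_pix, n_time - 1))
    direc = np.empty((n_stim, 2 * n_pix, n_time - 1))
    for s in range(n_stim):
        for t in range(1, n_time):
            prev, cur = arr[s, :, :, t - 1], arr[s, :, :, t]
            if np.ptp(prev) == 0 and np.ptp(cur) == 0:
                v = np.zeros((2, h, w))
            else:
                v = optical_flow_ilk(prev, cur, radius=radius)
                v = ndimage.gaussian_filter(v, sigma=(0, sigma, sigma))
            mag[s, :, t - 1] = np.hypot(v[0], v[1]).ravel()
            direc[s, :, t - 1] = v.reshape(2 * n_pix)
    mag = _interp_half_grid(mag)
    direc = _interp_half_grid(direc)
    m = ModelTimeSeries(name="flow_magnitude", fs=frames.fs,
                        metric="one_minus_pearson", features=mag)
    d = ModelTimeSeries(name="flow_direction", fs=frames.fs,
                        metric="one_minus_pearson", features=direc)
    return m, d


# ---------------------------------------------------------------------------
# kinematic models


def posture_view_dependent(traj: MarkerTrajectories) -> ModelTimeSeries:
    """Flattened 3D marker coordinates in the common world frame."""
    n_stim, n_marker, _, n_time = traj.positions.shape
    feats = traj.positions.reshape(n_stim, n_marker * 3, n_time)
    return ModelTimeSeries(name="posture_vd", fs=traj.fs,
                           metric="one_minus_pearson", features=feats)


def constrained_vertical_procrustes(
    a: np.ndarray, b: np.ndarray, vertical_axis: int = 2
) -> tuple[float, np.ndarray]:
    """Align marker set ``b`` to ``a`` by translation plus rotation about the
    vertical axis, minimizing the sum of squared coordinate differences.

    Returns (theta, b_aligned) where theta is the optimal rotation angle.
    The 2D Procrustes problem in the horizontal plane has the closed form
    theta* = atan2(sum(ay*bx - ax*by), sum(ax*bx + ay*by)) on centered
    coordinates; the vertical component is matched by translation alone.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("inputs must both be (n_markers, 3)")
    if a.shape[0] < 2:
        raise ValueError("alignment needs at least 2 markers")
    h = [i for i in range(3) if i != vertical_axis]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ah, bh = a[:, h] - ca[h], b[:, h] - cb[h]
    num = float(np.sum(ah[:, 1] * bh[:, 0] - ah[:, 0] * bh[:, 1]))
    den = float(np.sum(ah[:, 0] * bh[:, 0] + ah[:, 1] * bh[:, 1]))
    theta = float(np.arctan2(num, den)) if (num != 0 or den != 0) else 0.0
    b_aligned = _rotate_vertical(b - cb, theta, vertical_axis) + ca
    return theta, b_aligned


def _rotate_vertical(p: np.ndarray, theta: float, vertical_axis: int = 2) -> np.ndarray:
    """Rotate points/vectors (n, 3) by theta about the vertical axis."""
    h = [i for i in range(3) if i != vertical_axis]
    c, s = np.cos(theta), np.sin(theta)
    out = p.copy()
    out[:, h[0]] = c * p[:, h[0]] - s * p[:, h[1]]
    out[:, h[1]] = s * p[:, h[0]] + c * p[:, h[1]]
    return out


def _one_minus_pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return np.nan
    return 1.0 - float(x @ y) / (nx * ny)


def view_invariant_posture_dissim(
    posture_a: np.ndarray, posture_b: np.ndarray, vertical_axis: int = 2
) -> float:
    """Dissimilarity between two postures after constrained alignment.

    Aligns b to a (translation + vertical-axis rotation), takes 1 - Pearson
    on the aligned coordinates, repeats in the opposite direction, and
    returns the mean — alignment direction matters for 1 - r, so both are
    averaged.  Symmetric by construction.
    """
    a = np.asarray(posture_a, dtype=np.float64).reshape(-1, 3)
    b = np.asarray(posture_b, dtype=np.float64).reshape(-1, 3)
    _, b_to_a = constrained_vertical_procrustes(a, b, vertical_axis)
    _, a_to_b = constrained_vertical_procrustes(b, a, vertical_axis)
    d1 = _one_minus_pearson(a.ravel(), b_to_a.ravel())
    d2 = _one_minus_pearson(b.ravel(), a_to_b.ravel())
    return 0.5 * (d1 + d2)


def posture_view_invariant(
    traj: MarkerTrajectories, vertical_axis: int = 2
) -> ModelTimeSeries:
    """Posture model whose pairwise rule removes viewpoint (translation and
    vertical-axis rotation) before the correlation distance."""
    n_stim, n_marker, _, n_time = traj.positions.shape
    inputs = traj.positions.reshape(n_stim, n_marker * 3, n_time)

    def rule(a: np.ndarray, b: np.ndarray) -> float:
        return view_invariant_posture_dissim(a, b, vertical_axis)

    return ModelTimeSeries(
        name="posture_vi", fs=traj.fs, metric="one_minus_pearson",
        pairwise_rule=rule, rule_inputs=inputs, rule_kind="posture_view_invariant",
        extra={"vertical_axis": vertical_axis},
    )


def _motion_window_inputs(traj: MarkerTrajectories) -> np.ndarray:
    """Stack [x(t_prev); x(t_next); 1/(t_next - t_prev)] per time point.

    t_prev = max(t-1, 0), t_next = min(t+1, n-1): the centered two-sided
    difference matches the half-sample-grid interpolation used by
    motion_from_features in the interior and its edge duplication.
    """
    n_stim, n_marker, _, n_time = traj.positions.shape
    flat = traj.positions.reshape(n_stim, n_marker * 3, n_time)
    t = np.arange(n_time)
    t_prev = np.maximum(t - 1, 0)
    t_next = np.minimum(t + 1, n_time - 1)
    scale = 1.0 / (t_next - t_prev)
    out = np.empty((n_stim, 2 * n_marker * 3 + 1, n_time))
    out[:, : n_marker * 3, :] = flat[:, :, t_prev]
    out[:, n_marker * 3 : 2 * n_marker * 3, :] = flat[:, :, t_next]
    out[:, -1, :] = scale[None, :]
    return out


def motion_view_invariant(
    traj: MarkerTrajectories, vertical_axis: int = 2
) -> ModelTimeSeries:
    """Marker motion compared after pairwise viewpoint alignment.

    For each stimulus pair the rotation aligning the (window-averaged)
    posture of one stimulus to the other is applied to the other's motion
    vectors (translation cancels in differences) before 1 - Pearson; both
    alignment directions are averaged.
    """
    inputs = _motion_window_inputs(traj)
    n_coord = (inputs.shape[1] - 1) // 2

    def rule(a: np.ndarray, b: np.ndarray) -> float:
        a0, a1, sa = a[:n_coord], a[n_coord : 2 * n_coord], a[-1]
        b0, b1, sb = b[:n_coord], b[n_coord : 2 * n_coord], b[-1]
        pa = (0.5 * (a0 + a1)).reshape(-1, 3)
        pb = (0.5 * (b0 + b1)).reshape(-1, 3)
        va = ((a1 - a0) * sa).reshape(-1, 3)
        vb = ((b1 - b0) * sb).reshape(-1, 3)
        th_ba, _ = constrained_vertical_procrustes(pa, pb, vertical_axis)
        th_ab, _ = constrained_vertical_procrustes(pb, pa, vertical_axis)
        d1 = _one_minus_pearson(va.ravel(), _rotate_vertical(vb, th_ba, vertical_axis).ravel())
        d2 = _one_minus_pearson(vb.ravel(), _rotate_vertical(va, th_ab, vertical_axis).ravel())
        return 0.5 * (d1 + d2)

    return ModelTimeSeries(
        name="motion_vi", fs=traj.fs, metric="one_minus_pearson",
        pairwise_rule=rule, rule_inputs=inputs, rule_kind="motion_view_invariant",
        extra={"vertical_axis": vertical_axis},
    )


def motion_from_features(model: ModelTimeSeries, name: str | None = None) -> ModelTimeSeries:
    """First difference along time, resampled back onto the original grid.

    The difference x(i) - x(i-1) belongs between frames i-1 and i; linear
    interpolation onto integer frames keeps all models on one time grid (the
    first and last samples duplicate their nearest difference).  Apply twice
    for acceleration.
    """
    if model.features is None:
        raise ValueError("motion_from_features requires a feature-based model")
    if model.n_time < 2:
        raise ValueError("need at least 2 time points for a derivative")
    d = np.diff(model.features, axis=2)
    feats = _interp_half_grid(d)
    return ModelTimeSeries(
        name=name or f"d_{model.name}", fs=model.fs,
        metric=model.metric, features=feats,
    )


def gaze_model(gaze: GazeTrace) -> ModelTimeSeries:
    """Eye-position model: 4 gaze values compared by Euclidean distance
    (too few values for a reliable correlation estimate)."""
    return ModelTimeSeries(name="gaze", fs=gaze.fs, metric="euclidean",
                           features=gaze.gaze.copy())


# registry used by persistence to rebuild rule-based models
RULE_BUILDERS: dict[str, Callable[..., ModelTimeSeries]] = {}


def _register_rules() -> None:
    def build_posture_vi(inputs, fs, name, extra):
        n_marker = inputs.shape[1] // 3
        traj = MarkerTrajectories(
            positions=inputs.reshape(inputs.shape[0], n_marker, 3, inputs.shape[2]),
            fs=fs,
        )
        m = posture_view_invariant(traj, vertical_axis=extra.get("vertical_axis", 2))
        m.name = name
        return m

    def build_motion_vi(inputs, fs, name, extra):
        va = extra.get("vertical_axis", 2)
        n_coord = (inputs.shape[1] - 1) // 2
        proto = motion_view_invariant(
            MarkerTrajectories(
                positions=np.zeros((3, n_coord // 3, 3, 2)), fs=fs
            ),
            vertical_axis=va,
        )
        return ModelTimeSeries(
            name=name, fs=fs, metric="one_minus_pearson",
            pairwise_rule=proto.pairwise_rule, rule_inputs=inputs,
            rule_kind="motion_view_invariant", extra=dict(extra),
        )

    RULE_BUILDERS["posture_view_invariant"] = build_posture_vi
    RULE_BUILDERS["motion_view_invariant"] = build_motion_vi


_register_rules()
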