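"""Seed-reproducible synthetic stimulus sets.

Produces smooth, band-limited marker kinematics, grayscale frame stacks
rendered from the kinematics, and low-dimensional gaze traces.  The three
outputs form a hierarchy of correlated feature levels (frames are a
deterministic function of the kinematics), which is the statistical premise
the downstream analysis relies on.

Units are arbitrary: every downstream dissimilarity is correlation-based or
globally rescaled, so physical scales are irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerTrajectories",
    "FrameStack",
    "GazeTrace",
    "generate_kinematics",
    "render_frames",
    "generate_gaze",
]


@dataclass
class MarkerTrajectories:
    """Per-stimulus 3D kinematic marker time series.

    positions has shape (n_stimuli, n_markers, 3, n_time).  Axis 2 of the
    coordinate triple is "up" by convention (configurable downstream).
    """

    positions: np.ndarray
    fs: float
    stimulus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 4 or self.positions.shape[2] != 3:
            raise ValueError(
                "positions must have shape (n_stimuli, n_markers, 3, n_time), "
                f"got {self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.stimulus_ids:
            self.stimulus_ids = [f"stim{i:02d}" for i in range(self.n_stimuli)]
        if len(self.stimulus_ids) != self.n_stimuli:
            raise ValueError("stimulus_ids length must match n_stimuli")

    @property
    def n_stimuli(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def n_time(self) -> int:
        return self.positions.shape[3]


@dataclass
class FrameStack:
    """Grayscale luminance frames in [0, 1], shape (n_stimuli, H, W, n_time)."""

    frames: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must have shape (n_stimuli, H, W, n_time), got {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.size and (self.frames.min() < 0 or self.frames.max() > 1):
            raise ValueError("frame luminance must lie within [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_stimuli(self) -> int:
        return self.frames.shape[0]

    @property
    def n_time(self) -> int:
        return self.frames.shape[3]


@dataclass
class GazeTrace:
    """x/y positions for two eyes, shape (n_stimuli, 4, n_time)."""

    gaze: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.gaze = np.asarray(self.gaze, dtype=np.float64)
        if self.gaze.ndim != 3 or self.gaze.shape[1] != 4:
            raise ValueError(
                f"gaze must have shape (n_stimuli, 4, n_time), got {self.gaze.shape}"
            )
        if not np.all(np.isfinite(self.gaze)):
            raise ValueError("gaze contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_stimuli(self) -> int:
        return self.gaze.shape[0]

    @property
    def n_time(self) -> int:
        return self.gaze.shape[2]


def _check_generation_params(
    n_stimuli: int, duration_s: float, fs: float, cutoff_hz: float
) -> int:
    if n_stimuli < 3:
        raise ValueError("need at least 3 stimuli to form an RDM")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 2 * cutoff_hz:
        raise ValueError("fs must exceed twice cutoff_hz (Nyquist)")
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    n_time = int(round(duration_s * fs))
    if n_time < 2:
        raise ValueError("duration_s * fs must give at least 2 samples")
    return n_time


def _bandlimited_traces(
    rng: np.random.Generator,
    n_channels: int,
    n_time: int,
    duration_s: float,
    cutoff_hz: float,
    n_components: int,
    amplitude: float,
) -> np.ndarray:
    """Sum of random-phase sinusoids with frequencies on the Fourier grid.

    Frequencies are drawn uniformly from the grid multiples of 1/duration
    below the cutoff, so the signal is exactly band-limited over the
    generated window (no spectral leakage).
    """
    k_max = int(np.floor(cutoff_hz * duration_s))
    if k_max < 1:
        raise ValueError(
            "cutoff_hz * duration_s < 1: no representable frequency below cutoff"
        )
    t = np.arange(n_time) / (n_time / duration_s)
    out = np.zeros((n_channels, n_time))
    for c in range(n_channels):
        ks = rng.integers(1, k_max + 1, size=n_components)
        freqs = ks / duration_s
        phases = rng.uniform(0, 2 * np.pi, size=n_components)
        amps = amplitude * rng.uniform(0.5, 1.5, size=n_components) / (1.0 + freqs)
        out[c] = (amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(axis=0)
    return out


def generate_kinematics(
    n_stimuli: int,
    n_markers: int,
    duration_s: float,
    fs: float,
    cutoff_hz: float = 2.0,
    seed: int = 0,
    n_components: int = 6,
    body_scale: float = 1.0,
    motion_scale: float = 0.4,
    viewpoint_scatter: bool = True,
) -> MarkerTrajectories:
    """Generate smooth, band-limited marker trajectories.

    Each stimulus gets its own RNG stream spawned from the master seed, so
    adding stimuli never perturbs existing ones.  Each marker oscillates
    around a stimulus-independent body-like base offset; all motion is a sum
    of ``n_components`` random-phase sinusoids below ``cutoff_hz``.

    With ``viewpoint_scatter`` (default) every stimulus additionally gets a
    time-constant global rotation about the vertical axis and a horizontal
    offset, so stimuli differ in viewpoint: view-dependent and
    view-invariant feature levels then dissociate, as they must for the
    downstream models to be separable.
    """
    if n_markers < 1:
        raise ValueError("need at least one marker")
    n_time = _check_generation_params(n_stimuli, duration_s, fs, cutoff_hz)

    master = np.random.SeedSequence(seed)
    # first child fixes the shared body layout, the rest are per-stimulus
    layout_ss, *stim_ss = master.spawn(n_stimuli + 1)
    layout_rng = np.random.default_rng(layout_ss)
    base = layout_rng.normal(0.0, body_scale, size=(n_markers, 3))

    positions = np.empty((n_stimuli, n_markers, 3, n_time))
    for s in range(n_stimuli):
        rng = np.random.default_rng(stim_ss[s])
        traces = _bandlimited_traces(
            rng, n_markers * 3, n_time, duration_s, cutoff_hz, n_components, motion_scale
        )
        pos = base[:, :, None] + traces.reshape(n_markers, 3, n_time)
        if viewpoint_scatter:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            c, si = np.cos(theta), np.sin(theta)
            x, y = pos[:, 0, :].copy(), pos[:, 1, :].copy()
            pos[:, 0, :] = c * x - si * y
            pos[:, 1, :] = si * x + c * y
            pos[:, 0, :] += rng.normal(0.0, 0.5 * body_scale)
            pos[:, 1, :] += rng.normal(0.0, 0.5 * body_scale)
        positions[s] = pos
    return MarkerTrajectories(positions=positions, fs=fs)


def render_frames(
    traj: MarkerTrajectories,
    height: int,
    width: int,
    marker_sigma: float = 2.0,
    seed: int = 0,
    fill_fraction: float = 0.9,
) -> FrameStack:
    """Render each frame as a sum of isotropic Gaussian blobs.

    The depth axis (index 1) is dropped orthographically; horizontal (axis 0)
    maps to columns and the vertical axis (index 2) to rows.  One global
    affine scaling fits the full stimulus set into the central
    ``fill_fraction`` of the frame, which preserves the posture/motion
    hierarchy across stimuli.  ``seed`` is accepted for interface symmetry;
    rendering is fully deterministic given the trajectories.

    Markers projecting outside the frame (possible only with degenerate
    custom scalings) trigger a warning and are clipped, never an exception.
    """
    del seed  # deterministic given traj
    if height < 4 or width < 4:
        raise ValueError("frame must be at least 4x4 pixels")
    if marker_sigma <= 0:
        raise ValueError("marker_sigma must be positive")

    x = traj.positions[:, :, 0, :]  # horizontal -> columns
    y = traj.positions[:, :, 2, :]  # vertical -> rows

    def _map(coords: np.ndarray, n_pix: int) -> np.ndarray:
        lo, hi = coords.min(), coords.max()
        span = hi - lo
        if span == 0:
            return np.full_like(coords, (n_pix - 1) / 2.0)
        scale = fill_fraction * (n_pix - 1) / span
        return (coords - (lo + hi) / 2.0) * scale + (n_pix - 1) / 2.0

    cols = _map(x, width)
    rows = _map((-y), height)  # flip so "up" renders upward

    out_of_frame = (
        (cols < 0).any() or (cols > width - 1).any()
        or (rows < 0).any() or (rows > height - 1).any()
    )
    if out_of_frame:
        warnings.warn("markers project outside the frame; clipping", stacklevel=2)
        cols = np.clip(cols, 0, width - 1)
        rows = np.clip(rows, 0, height - 1)

    row_idx = np.arange(height)
    col_idx = np.arange(width)
    inv2s2 = 1.0 / (2.0 * marker_sigma**2)
    frames = np.empty((traj.n_stimuli, height, width, traj.n_time), dtype=np.float32)
    for s in range(traj.n_stimuli):
        for t in range(traj.n_time):
            gy = np.exp(-((row_idx[None, :] - rows[s, :, t][:, None]) ** 2) * inv2s2)
            gx = np.exp(-((col_idx[None, :] - cols[s, :, t][:, None]) ** 2) * inv2s2)
            frame = np.einsum("mh,mw->hw", gy, gx)
            np.clip(frame, 0.0, 1.0, out=frame)
            frames[s, :, :, t] = frame
    return FrameStack(frames=frames, fs=traj.fs)


def generate_gaze(
    n_stimuli: int,
    duration_s: float,
    fs: float,
    cutoff_hz: float = 2.0,
    seed: int = 0,
    n_components: int = 6,
    amplitude: float = 1.0,
) -> GazeTrace:
    """Generate smooth 4-channel gaze traces (x, y for two eyes)."""
    n_time = _check_generation_params(n_stimuli, duration_s, fs, cutoff_hz)
    master = np.random.SeedSequence(seed)
    stim_ss = master.spawn(n_stimuli)
    gaze = np.empty((n_stimuli, 4, n_time))
    for s in range(n_stimuli):
        rng = np.random.default_rng(stim_ss[s])
        gaze[s] = _bandlimited_traces(
            rng, 4, n_time, duration_s, cutoff_hz, n_components, amplitude
        )
    return GazeTrace(gaze=gaze, fs=fs)
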