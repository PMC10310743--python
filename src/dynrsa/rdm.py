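"""Time series of vectorized representational dissimilarity matrices.

The canonical pair order is (0,1), (0,2), ..., (0,n-1), (1,2), ...: the
condensed order used by ``scipy.spatial.distance.pdist``.  All RDMSeries in
one analysis must share it; external neural RDMs must be supplied in this
order.

Preprocessing order is fixed: boxcar smoothing, then global min-max
rescaling to [0, 2], then per-timepoint centering.  Each step appends its
name to ``steps`` so the applied sequence is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist

from .feature_models import ModelTimeSeries

log = logging.getLogger(__name__)

__all__ = [
    "RDMSeries",
    "pair_index",
    "compute_rdm_series",
    "smooth_rdm_series",
    "rescale_rdm_series",
    "center_columns",
    "preprocess_rdm_series",
    "squareform_at",
]


def pair_index(n_stimuli: int) -> list[tuple[int, int]]:
    """Canonical (i < j) pair order of the vectorized RDM."""
    return list(combinations(range(n_stimuli), 2))


@dataclass
class RDMSeries:
    """Vectorized lower-triangle dissimilarities, shape (n_pairs, n_time)."""

    values: np.ndarray
    n_stimuli: int
    fs: float
    metric: str
    name: str
    steps: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_pairs, n_time)")
        expected = self.n_stimuli * (self.n_stimuli - 1) // 2
        if self.values.shape[0] != expected:
            raise ValueError(
                f"n_pairs {self.values.shape[0]} != n_stimuli*(n_stimuli-1)/2 = {expected}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    def pair_index(self) -> list[tuple[int, int]]:
        return pair_index(self.n_stimuli)


def _pearson_rdm(features: np.ndarray) -> np.ndarray:
    """1 - Pearson over stimuli pairs for every time point.

    features: (n_stimuli, n_feat, n_time) -> (n_pairs, n_time).
    Zero-variance feature vectors yield NaN dissimilarities.
    """
    n_stim, n_feat, n_time = features.shape
    z = features - features.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norms[:, None, :] > 0, z / np.where(norms[:, None, :] > 0, norms[:, None, :], 1.0), np.nan)
    corr = np.einsum("ift,jft->ijt", z, z)
    iu, ju = np.triu_indices(n_stim, k=1)
    return 1.0 - corr[iu, ju, :]


def compute_rdm_series(model: ModelTimeSeries) -> RDMSeries:
    """Pairwise dissimilarity between stimuli at every time point."""
    if model.n_stimuli < 3:
        raise ValueError("need at least 3 stimuli")
    n_stim, n_time = model.n_stimuli, model.n_time
    if model.features is not None:
        if model.metric == "one_minus_pearson":
            values = _pearson_rdm(model.features)
        else:  # euclidean
            values = np.empty((n_stim * (n_stim - 1) // 2, n_time))
            for t in range(n_time):
                values[:, t] = pdist(model.features[:, :, t], metric="euclidean")
    else:
        pairs = pair_index(n_stim)
        values = np.empty((len(pairs), n_time))
        inputs = model.rule_inputs
        for p, (i, j) in enumerate(pairs):
            for t in range(n_time):
                values[p, t] = model.pairwise_rule(inputs[i, :, t], inputs[j, :, t])

    n_nan = int(np.isnan(values).sum())
    if n_nan:
        frac = n_nan / values.size
        log.warning("model %s: %d NaN dissimilarities (%.1f%%)",
                    model.name, n_nan, 100 * frac)
        if frac > 0.10:
            raise ValueError(
                f"model {model.name!r}: {100 * frac:.1f}% NaN dissimilarities (>10%)"
            )
    return RDMSeries(values=values, n_stimuli=n_stim, fs=model.fs,
                     metric=model.metric, name=model.name, steps=("compute",))


def smooth_rdm_series(r: RDMSeries, kernel_ms: float) -> RDMSeries:
    """Per-pair moving average with a boxcar of round(kernel_ms * fs / 1000)
    samples; edges use a truncated (shrinking) window.  NaNs are excluded
    from window averages (window renormalized)."""
    if kernel_ms < 0:
        raise ValueError("kernel_ms must be >= 0")
    width = int(round(kernel_ms * r.fs / 1000.0))
    if width > r.n_time:
        raise ValueError("smoothing kernel longer than the series")
    if width <= 1:
        return replace(r, values=r.values.copy(), steps=r.steps + ("smooth",))
    half_l = (width - 1) // 2
    half_r = width // 2
    vals = r.values
    finite = np.isfinite(vals)
    filled = np.where(finite, vals, 0.0)
    csum = np.concatenate(
        [np.zeros((vals.shape[0], 1)), np.cumsum(filled, axis=1)], axis=1)
    ccnt = np.concatenate(
        [np.zeros((vals.shape[0], 1)), np.cumsum(finite, axis=1)], axis=1)
    t = np.arange(vals.shape[1])
    lo = np.maximum(t - half_l, 0)
    hi = np.minimum(t + half_r + 1, vals.shape[1])
    sums = csum[:, hi] - csum[:, lo]
    cnts = ccnt[:, hi] - ccnt[:, lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return replace(r, values=out, steps=r.steps + ("smooth",))


def rescale_rdm_series(r: RDMSeries) -> RDMSeries:
    """Affine map so the global min over all pairs and time points becomes 0
    and the global max becomes 2; per-timepoint relative scale preserved."""
    finite = r.values[np.isfinite(r.values)]
    if finite.size == 0:
        raise ValueError("series is all-NaN")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise ValueError("globally constant series has no scale")
    out = (r.values - lo) * (2.0 / (hi - lo))
    return replace(r, values=out, steps=r.steps + ("rescale",))


def center_columns(r: RDMSeries) -> RDMSeries:
    """Remove the mean across pairs from every time slice."""
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(r.values, axis=0, keepdims=True)
    return replace(r, values=r.values - mu, steps=r.steps + ("center",))


def preprocess_rdm_series(r: RDMSeries, kernel_ms: float = 30.0) -> RDMSeries:
    """Fixed-order pipeline: smooth -> rescale -> center."""
    return center_columns(rescale_rdm_series(smooth_rdm_series(r, kernel_ms)))


def squareform_at(r: RDMSeries, t: int) -> np.ndarray:
    """Square symmetric RDM (zero diagonal) at one time point, for export."""
    n = r.n_stimuli
    out = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = r.values[:, t]
    out[ju, iu] = r.values[:, t]
    return out
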