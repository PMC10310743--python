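"""Group-level inference and lag-curve characterization.

Fisher-Z transform of similarity values, one-sided cluster-based
permutation tests (sign-flipping null), jackknifed peak latencies with
single-subject retrieval, representational spread, and Benjamini-Hochberg
FDR for map-style outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .drsa import LagProfile

log = logging.getLogger(__name__)

__all__ = [
    "GroupLagProfiles",
    "ClusterResult",
    "RSCurve",
    "JackknifeLatencies",
    "fisher_z",
    "cluster_permutation_test",
    "jackknife_peak_latency",
    "representational_spread",
    "fdr_correct",
    "THRESHOLD_REGIMES",
]

# (single-sample alpha, cluster-size alpha)
THRESHOLD_REGIMES: dict[str, tuple[float, float]] = {
    "lenient": (0.01, 0.05),
    "strict": (0.001, 0.01),
}


@dataclass
class GroupLagProfiles:
    """Per-subject lag profiles, shape (n_subjects, n_lags)."""

    values: np.ndarray
    lags_s: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.lags_s = np.asarray(self.lags_s, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_subjects, n_lags)")
        if self.values.shape[1] != self.lags_s.size:
            raise ValueError("lags_s length must match n_lags")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if np.isnan(self.values).all(axis=1).any():
            raise ValueError("all-NaN subject rows are not allowed")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_profiles(cls, profiles: list[LagProfile]) -> "GroupLagProfiles":
        lags = profiles[0].lags_s
        for p in profiles[1:]:
            if not np.array_equal(p.lags_s, lags):
                raise ValueError("profiles must share the lag grid")
        return cls(values=np.stack([p.values for p in profiles]), lags_s=lags)


@dataclass
class ClusterResult:
    """Clusters of contiguous supra-threshold lags with permutation p-values."""

    clusters: list[dict]  # lag_start_s, lag_end_s, mass, p_value
    sample_alpha: float
    cluster_alpha: float
    n_perm: int
    t_observed: np.ndarray = field(default=None, repr=False)

    def significant(self) -> list[dict]:
        return [c for c in self.clusters if c["p_value"] <= self.cluster_alpha]


@dataclass
class RSCurve:
    """Representational spread vs. signed distance from the dRSA peak."""

    distances_s: np.ndarray
    rs: np.ndarray
    peak_lag_s: float


@dataclass
class JackknifeLatencies:
    jackknife_s: np.ndarray  # leave-one-out peak latencies
    retrieved_s: np.ndarray  # n*mean(jack) - (n-1)*jack_i
    grand_estimate_s: float  # peak latency of the grand-average curve


def fisher_z(values: np.ndarray, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """Elementwise atanh.  Values exceeding +/-1 in magnitude (possible for
    regression weights) are clipped to +/-clip with a logged warning."""
    arr = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(arr) | np.isnan(arr)):
        raise ValueError("fisher_z input must be finite (NaN allowed)")
    n_clip = int(np.sum(np.abs(arr) >= clip))
    if n_clip:
        log.warning("fisher_z: clipping %d values with |v| >= %g", n_clip, clip)
        arr = np.clip(arr, -clip, clip)
    return np.arctanh(arr)


def _cluster_masses(t: np.ndarray, t_crit: float) -> list[tuple[int, int, float]]:
    """Contiguous runs of t > t_crit as (start, stop_exclusive, mass)."""
    supra = t > t_crit
    if not supra.any():
        return []
    padded = np.concatenate([[False], supra, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b), float(t[a:b].sum())) for a, b in zip(starts, stops)]


def cluster_permutation_test(
    group: GroupLagProfiles,
    sample_alpha: float = 0.01,
    cluster_alpha: float = 0.05,
    n_perm: int = 25_000,
    tail: str = "greater",
    seed: int = 0,
) -> ClusterResult:
    """One-sided cluster-based permutation test against zero.

    Per lag, a one-sample t-statistic against 0 is computed; contiguous lags
    with p < sample_alpha (one-sided) form clusters whose mass is the summed
    t.  The null distribution of the maximum cluster mass is built by random
    sign-flipping of whole subject curves; each cluster's p-value is the
    fraction of null maxima at least as large as its mass (with the +1
    permutation-test correction).
    """
    if tail != "greater":
        raise ValueError("only the 'greater' tail is supported")
    if n_perm < 100:
        log.warning("n_perm=%d is very low; p-values will be coarse", n_perm)
    x = group.values
    n, n_lags = x.shape
    if n < 5:
        log.warning("n_subjects=%d: sign-flip null is coarse below 5 subjects", n)
    if np.isnan(x).any():
        raise ValueError("NaN values in group profiles")

    df = n - 1
    t_crit = float(sps.t.ppf(1.0 - sample_alpha, df))
    sumsq = np.sum(x**2, axis=0)

    def _tstats(signs: np.ndarray) -> np.ndarray:
        m = signs @ x / n
        var = (sumsq / n - m**2) * (n / df)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        return np.where(var > 0, t, 0.0)

    t_obs = _tstats(np.ones((1, n)))[0]
    observed = _cluster_masses(t_obs, t_crit)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _tstats(signs)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        masses = _cluster_masses(t_null[p], t_crit)
        if masses:
            null_max[p] = max(m for _, _, m in masses)

    clusters = []
    for a, b, mass in observed:
        p_val = (1.0 + float(np.sum(null_max >= mass))) / (1.0 + n_perm)
        clusters.append({
            "lag_start_s": float(group.lags_s[a]),
            "lag_end_s": float(group.lags_s[b - 1]),
            "start_index": a,
            "stop_index": b,
            "mass": mass,
            "p_value": p_val,
        })
    return ClusterResult(clusters=clusters, sample_alpha=sample_alpha,
                         cluster_alpha=cluster_alpha, n_perm=n_perm,
                         t_observed=t_obs)


def _peak_index(curve: np.ndarray, mask: np.ndarray, sign: str) -> int:
    vals = curve.copy()
    if sign == "negative":
        vals = -vals
    elif sign == "both":
        vals = np.abs(vals)
    elif sign != "positive":
        raise ValueError("sign must be positive, negative or both")
    vals = np.where(mask & np.isfinite(vals), vals, -np.inf)
    if not np.isfinite(vals).any():
        raise ValueError("no finite values in the search window")
    if np.ptp(vals[np.isfinite(vals)]) == 0:
        raise ValueError("flat curve in the search window: peak undefined")
    return int(np.argmax(vals))  # ties -> earliest lag


def jackknife_peak_latency(
    group: GroupLagProfiles,
    search_window_s: tuple[float, float] | None = None,
    sign: str = "positive",
) -> JackknifeLatencies:
    """Leave-one-out peak latencies with single-subject retrieval.

    Each jackknife value is the peak latency of the mean curve over the
    other n-1 subjects; retrieved_i = n*mean(jack) - (n-1)*jack_i restores
    single-subject variance for standard parametric tests, while
    mean(retrieved) equals mean(jack) exactly.
    """
    x = group.values
    n = group.n_subjects
    if n < 3:
        raise ValueError("jackknife needs at least 3 subjects")
    lags = group.lags_s
    mask = np.ones_like(lags, dtype=bool)
    if search_window_s is not None:
        lo, hi = search_window_s
        if lo >= hi:
            raise ValueError("empty search window")
        mask = (lags >= lo) & (lags <= hi)
        if not mask.any():
            raise ValueError("search window outside the lag range")

    total = x.sum(axis=0)
    jack = np.empty(n)
    for i in range(n):
        loo = (total - x[i]) / (n - 1)
        jack[i] = lags[_peak_index(loo, mask, sign)]
    grand = lags[_peak_index(total / n, mask, sign)]
    retrieved = n * jack.mean() - (n - 1) * jack
    return JackknifeLatencies(jackknife_s=jack, retrieved_s=retrieved,
                              grand_estimate_s=float(grand))


def representational_spread(
    observed: LagProfile, autocorr_only: LagProfile
) -> RSCurve:
    """Excess temporal spread of the observed curve over the
    autocorrelation-only curve.

    Both curves are normalized to 1 at their own (strictly positive) peak,
    shifted so each peak sits at distance 0, and subtracted
    (observed - autocorr_only) on the overlapping distance grid; RS(0) is 0
    by construction.  The autocorr_only input comes from running the full
    estimator on a noise-free self-implant of the model.
    """
    if observed.fs != autocorr_only.fs:
        raise ValueError("profiles must share fs")

    def _norm_peak(p: LagProfile) -> tuple[np.ndarray, int]:
        vals = p.values
        finite = np.isfinite(vals)
        if not finite.any():
            raise ValueError("profile has no finite values")
        idx = int(np.argmax(np.where(finite, vals, -np.inf)))
        peak = vals[idx]
        if not peak > 0:
            raise ValueError("profile needs a strictly positive maximum")
        return vals / peak, idx

    obs, p_obs = _norm_peak(observed)
    auto, p_auto = _norm_peak(autocorr_only)
    d_lo = max(-p_obs, -p_auto)
    d_hi = min(obs.size - 1 - p_obs, auto.size - 1 - p_auto)
    if d_hi < d_lo:
        raise ValueError("no overlapping distance grid after peak alignment")
    d = np.arange(d_lo, d_hi + 1)
    rs = obs[d + p_obs] - auto[d + p_auto]
    rs[d == 0] = 0.0  # exact by construction; guard against rounding
    return RSCurve(distances_s=d / observed.fs, rs=rs,
                   peak_lag_s=float(observed.lags_s[p_obs]))


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= thresh)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask
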