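"""Core dynamic-RSA estimators.

For every (model-time t_x, neural-time t_y) cell the similarity between the
neural RDM slice and the test-model RDM slice is estimated either as a plain
Pearson correlation or as the test model's back-projected coefficient from a
two-stage principal-component regression (PCR) that regresses out the other
models at all time points plus the test model itself at temporally distant
time points (beyond its autocorrelation exclusion window).

Lag convention, fixed project-wide: lag = t_neural - t_model.  A positive
lag means the neural representation follows the stimulus; a negative-lag
peak means the neural RDM predicts a future model state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .feature_models import ModelTimeSeries
from .rdm import RDMSeries, center_columns, compute_rdm_series, rescale_rdm_series, smooth_rdm_series

log = logging.getLogger(__name__)

__all__ = [
    "DRSAConfig",
    "DRSAMatrix",
    "LagProfile",
    "autocorr_exclusion_window",
    "pcr_similarity",
    "drsa_matrix",
    "lag_profile",
    "subsample_and_average",
]

_SV_RTOL = 1e-10  # singular values below max * rtol count as rank deficiency


@dataclass
class DRSAConfig:
    """Parameters of the dRSA estimator and the subsampling loop.

    Defaults mirror the reference pipeline: +/-1 s lag range, 1000
    subsampling iterations of 3-s segments, first-stage components keeping
    at least 0.1% of block variance, at most 75 second-stage components, and
    a 10% shared-variance autocorrelation exclusion threshold.
    """

    lag_range_s: float = 1.0
    n_iterations: int = 1000
    segment_s: float = 3.0
    var_threshold: float = 0.001
    max_components: int = 75
    autocorr_r2_threshold: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_range_s <= 0:
            raise ValueError("lag_range_s must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.segment_s <= 0:
            raise ValueError("segment_s must be positive")
        if not 0 <= self.var_threshold < 1:
            raise ValueError("var_threshold must be in [0, 1)")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if not 0 < self.autocorr_r2_threshold < 1:
            raise ValueError("autocorr_r2_threshold must be in (0, 1)")


@dataclass
class DRSAMatrix:
    """Model-time x neural-time similarity matrix.

    betas[t_x, t_y] holds the similarity of the neural slice at t_y with the
    test model at t_x; cells outside |t_y - t_x| <= lag range are NaN (not
    computed)."""

    betas: np.ndarray
    fs: float
    estimator: str
    test_model: str


@dataclass
class LagProfile:
    """Diagonal average of a DRSAMatrix as a function of lag."""

    lags_s: np.ndarray
    values: np.ndarray
    n_averaged: np.ndarray
    fs: float
    test_model: str = ""
    estimator: str = "pcr"

    def peak_lag(self) -> float:
        """Lag (s) of the highest value; ties broken to the earliest lag."""
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValueError("profile has no finite values")
        vals = np.where(finite, self.values, -np.inf)
        return float(self.lags_s[int(np.argmax(vals))])


def _center_cols(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def autocorr_exclusion_window(model_rdms: RDMSeries, threshold: float = 0.10) -> int:
    """Smallest lag (samples) at which the model shares less than
    ``threshold`` variance with itself, time-averaged.

    Computes mean-over-t of squared Pearson correlation between RDM slices
    at t and t + delta for every delta, and returns the first delta where it
    drops below threshold.  If it never does, the series length is returned
    with a warning (the whole own-model series is then excluded).
    """
    vals = np.where(np.isfinite(model_rdms.values), model_rdms.values, 0.0)
    z = _center_cols(vals)
    norms = np.linalg.norm(z, axis=0)
    norms[norms == 0] = 1.0
    z = z / norms
    corr = z.T @ z
    n_time = corr.shape[0]
    for delta in range(1, n_time):
        r2 = float(np.mean(np.diagonal(corr, offset=delta) ** 2))
        if r2 < threshold:
            return delta
    log.warning("model %s: autocorrelation never drops below %.2f; "
                "excluding the whole series", model_rdms.name, threshold)
    return n_time


def _block_components(block: np.ndarray, var_threshold: float) -> np.ndarray:
    """First-stage PCA of one nuisance block (columns = predictors).

    Columns are centered across pairs; components (score columns U*s) that
    capture at least ``var_threshold`` of the block's total variance are
    kept.  Returns an (n_pairs, k) array, possibly empty.
    """
    if block.shape[1] == 0:
        return np.empty((block.shape[0], 0))
    z = _center_cols(block)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        return np.empty((block.shape[0], 0))
    keep = (s**2 / total) >= var_threshold
    return u[:, keep] * s[keep]


def _second_stage(
    z: np.ndarray, max_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second-stage PCA over the stacked predictors.

    Returns (u_k, s_k, v_k) with at most min(max_components, rank)
    components ordered by explained variance; z ~= (u_k * s_k) @ v_k.T.
    """
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * _SV_RTOL)) if s.size and s[0] > 0 else 0
    k = min(max_components, rank)
    return u[:, :k], s[:k], vt[:k].T


def pcr_similarity(
    neural_slice: np.ndarray,
    test_slice: np.ndarray,
    nuisance_blocks: list[np.ndarray],
    cfg: DRSAConfig,
) -> float:
    """Back-projected PCR coefficient of the test-model slice.

    1. Per nuisance block (n_pairs x n_cols): PCA, keep components with at
       least ``cfg.var_threshold`` of the block's total variance.
    2. Stack kept components with the (centered) test slice; second PCA,
       keep the first min(cfg.max_components, rank) components.
    3. Least-squares regression of the neural slice on the components.
    4. Back-project component coefficients through the second PCA's loadings
       onto the stacked predictors; return the test slice's coefficient.

    With nothing dropped in either stage, this equals the test predictor's
    ordinary multiple-regression coefficient.
    """
    y = np.asarray(neural_slice, dtype=np.float64)
    x = np.asarray(test_slice, dtype=np.float64)
    y = y - y.mean()
    x = x - x.mean()
    if np.linalg.norm(x) == 0 or not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        log.warning("degenerate test or neural slice: NaN beta")
        return float("nan")
    comps = [_block_components(np.asarray(b, dtype=np.float64), cfg.var_threshold)
             for b in nuisance_blocks]
    z = np.column_stack(comps + [x[:, None]]) if comps else x[:, None]
    u_k, s_k, v_k = _second_stage(z, cfg.max_components)
    if s_k.size == 0:
        return float("nan")
    c = (u_k.T @ y) / s_k
    beta = v_k @ c
    return float(beta[-1])


def drsa_matrix(
    neural: RDMSeries,
    test_model: RDMSeries,
    nuisance_models: list[RDMSeries] | None = None,
    cfg: DRSAConfig | None = None,
    estimator: str = "pcr",
) -> DRSAMatrix:
    """Similarity at every (t_x, t_y) cell with |t_y - t_x| <= lag range.

    All series must share fs, pair order and length, and should have been
    preprocessed (smoothed, rescaled, centered).  Columns are re-centered
    defensively (idempotent).  For the PCR estimator the nuisance set at t_x
    is: every nuisance model at all time points, plus the test model itself
    at time points at least its autocorrelation exclusion window away from
    t_x.
    """
    cfg = cfg or DRSAConfig()
    nuisance_models = nuisance_models or []
    for other in [test_model, *nuisance_models]:
        if other.n_pairs != neural.n_pairs or other.n_time != neural.n_time:
            raise ValueError("all RDM series must share n_pairs and n_time")
        if other.fs != neural.fs:
            raise ValueError("all RDM series must share fs")
    n_time = neural.n_time
    lag = int(round(cfg.lag_range_s * neural.fs))

    yv = _center_cols(np.where(np.isfinite(neural.values), neural.values, 0.0))
    xv = _center_cols(np.where(np.isfinite(test_model.values), test_model.values, 0.0))
    betas = np.full((n_time, n_time), np.nan)

    if estimator == "correlation":
        ynorm = np.linalg.norm(yv, axis=0)
        xnorm = np.linalg.norm(xv, axis=0)
        yz = yv / np.where(ynorm > 0, ynorm, 1.0)
        xz = xv / np.where(xnorm > 0, xnorm, 1.0)
        corr = xz.T @ yz
        corr[xnorm == 0, :] = np.nan
        corr[:, ynorm == 0] = np.nan
        tx, ty = np.meshgrid(np.arange(n_time), np.arange(n_time), indexing="ij")
        corr[np.abs(ty - tx) > lag] = np.nan
        betas = corr
    elif estimator == "pcr":
        nuis_comps = [
            _block_components(
                _center_cols(np.where(np.isfinite(m.values), m.values, 0.0)),
                cfg.var_threshold,
            )
            for m in nuisance_models
        ]
        delta = autocorr_exclusion_window(test_model, cfg.autocorr_r2_threshold)
        t_all = np.arange(n_time)
        for tx in range(n_time):
            x = xv[:, tx]
            if np.linalg.norm(x) == 0:
                log.warning("t_x=%d: zero-variance test slice, NaN row", tx)
                continue
            own = xv[:, np.abs(t_all - tx) >= delta]
            own_comps = _block_components(own, cfg.var_threshold)
            z = np.column_stack(nuis_comps + [own_comps, x[:, None]])
            u_k, s_k, v_k = _second_stage(z, cfg.max_components)
            if s_k.size == 0:
                continue
            ty_lo, ty_hi = max(0, tx - lag), min(n_time, tx + lag + 1)
            y = yv[:, ty_lo:ty_hi]
            c = (u_k.T @ y) / s_k[:, None]
            betas[tx, ty_lo:ty_hi] = (v_k[-1, :] @ c)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    return DRSAMatrix(betas=betas, fs=neural.fs, estimator=estimator,
                      test_model=test_model.name)


def lag_profile(m: DRSAMatrix, cfg: DRSAConfig | None = None) -> LagProfile:
    """Average the dRSA matrix along its diagonals.

    Lag ell = t_y - t_x (neural minus model time); the value at ell is the
    mean of betas over all valid (t_x, t_y = t_x + ell) pairs inside the
    segment; n_averaged reports how many cells entered each mean.
    """
    cfg = cfg or DRSAConfig()
    lag = int(round(cfg.lag_range_s * m.fs))
    n_time = m.betas.shape[0]
    if lag >= n_time:
        raise ValueError("lag range exceeds matrix extent")
    lags = np.arange(-lag, lag + 1)
    values = np.empty(lags.size)
    counts = np.empty(lags.size, dtype=int)
    for idx, ell in enumerate(lags):
        diag = np.diagonal(m.betas, offset=int(ell))
        finite = np.isfinite(diag)
        counts[idx] = int(finite.sum())
        values[idx] = diag[finite].mean() if finite.any() else np.nan
    return LagProfile(lags_s=lags / m.fs, values=values, n_averaged=counts,
                      fs=m.fs, test_model=m.test_model, estimator=m.estimator)


# ---------------------------------------------------------------------------
# temporal subsampling and realignment


def _realigned_rdm(
    model: ModelTimeSeries, starts: np.ndarray, seg: int, kernel_ms: float
) -> RDMSeries:
    sliced = model.slice_time(starts, seg)
    r = compute_rdm_series(sliced)
    r = smooth_rdm_series(r, kernel_ms)
    return rescale_rdm_series(r)


def _simulated_neural_segment(
    models: dict[str, ModelTimeSeries],
    spec,  # ImplantSpec; imported lazily to avoid a module cycle
    starts: np.ndarray,
    seg: int,
    kernel_ms: float,
    fs: float,
    rng: np.random.Generator,
) -> RDMSeries:
    """Build a simulated neural RDM segment from lag-shifted implants.

    A component at lag L (seconds) contributes the model RDM computed on
    windows shifted L samples earlier, so the neural slice at realigned time
    t equals the model at t - L.  White uniform noise on [0, 2] scaled by
    the noise weight is added per pair-timepoint.
    """
    total = None
    for name, weight, lag_s in spec.components:
        shift = int(round(lag_s * fs))
        r = _realigned_rdm(models[name], starts - shift, seg, kernel_ms)
        total = weight * r.values if total is None else total + weight * r.values
    any_model = next(iter(models.values()))
    n_stim = any_model.n_stimuli
    n_pairs = n_stim * (n_stim - 1) // 2
    if total is None:
        total = np.zeros((n_pairs, seg))
    if spec.noise_weight > 0:
        total = total + spec.noise_weight * rng.uniform(0.0, 2.0, size=(n_pairs, seg))
    r = RDMSeries(values=total, n_stimuli=n_stim, fs=fs,
                  metric="simulated", name="simulated_neural",
                  steps=("compute", "smooth"))
    return rescale_rdm_series(r)


def _implant_start_bounds(spec, fs: float, n_full: int, seg: int) -> tuple[int, int]:
    """Valid window-start range keeping every lag-shifted window in bounds."""
    shifts = [int(round(lag_s * fs)) for _, _, lag_s in spec.components] or [0]
    lo = max(0, max(shifts))
    hi = n_full - seg + min(0, min(shifts))  # inclusive
    if hi < lo:
        raise ValueError("implant lags leave no valid subsampling window")
    return lo, hi


def subsample_and_average(
    models: dict[str, ModelTimeSeries],
    neural,
    cfg: DRSAConfig,
    test_models: list[str] | None = None,
    estimator: str = "pcr",
    kernel_ms: float = 30.0,
) -> dict[str, LagProfile]:
    """Subsampling-and-realignment loop returning iteration-mean lag profiles.

    Per iteration one uniform window start is drawn independently per
    stimulus (shared between the neural stream and all models of that
    stimulus, so within-stimulus alignment stays intact), every model's RDM
    series is recomputed on the realigned segment, and dRSA + lag profile is
    run for every tested model with all other models as nuisances.

    ``neural`` may be a ModelTimeSeries (feature data realigned like the
    models), an ImplantSpec (a simulated neural stream rebuilt per
    iteration), or — only when the segment spans the full duration, i.e. no
    resampling freedom — a precomputed RDMSeries.
    """
    from .neural_sim import ImplantSpec

    if not models:
        raise ValueError("need at least one model")
    first = next(iter(models.values()))
    fs, n_full, n_stim = first.fs, first.n_time, first.n_stimuli
    for m in models.values():
        if m.fs != fs or m.n_time != n_full or m.n_stimuli != n_stim:
            raise ValueError("all models must share fs, n_time and n_stimuli")
    seg = int(round(cfg.segment_s * fs))
    if seg > n_full:
        raise ValueError("segment_s exceeds the stimulus duration")
    test_models = list(test_models) if test_models is not None else list(models)
    for name in test_models:
        if name not in models:
            raise KeyError(f"unknown test model {name!r}")

    if isinstance(neural, RDMSeries) and seg != n_full:
        raise ValueError(
            "a precomputed neural RDMSeries cannot be realigned; supply "
            "feature data or use segment_s equal to the full duration"
        )
    if seg == n_full and not isinstance(neural, ImplantSpec):
        log.info("segment spans the full duration: single-pass dRSA")

    if isinstance(neural, ImplantSpec):
        lo, hi = _implant_start_bounds(neural, fs, n_full, seg)
    else:
        lo, hi = 0, n_full - seg

    master = np.random.SeedSequence(cfg.seed)
    iter_seeds = master.spawn(cfg.n_iterations)
    sums = {name: None for name in test_models}
    count_sums = {name: None for name in test_models}
    lags_s = None

    for it in range(cfg.n_iterations):
        start_ss, _ = iter_seeds[it].spawn(2)
        start_rng = np.random.default_rng(start_ss)
        starts = start_rng.integers(lo, hi + 1, size=n_stim)

        rdms = {name: center_columns(_realigned_rdm(m, starts, seg, kernel_ms))
                for name, m in models.items()}
        if isinstance(neural, ImplantSpec):
            # noise stream keyed on the implant's own seed so simulated
            # subjects sharing cfg.seed still get independent noise
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([int(neural.seed), int(cfg.seed), it]))
            neural_r = _simulated_neural_segment(
                models, neural, starts, seg, kernel_ms, fs, noise_rng)
        elif isinstance(neural, RDMSeries):
            neural_r = neural
        else:
            neural_r = _realigned_rdm(neural, starts, seg, kernel_ms)
        neural_r = center_columns(neural_r)

        for name in test_models:
            nuis = [rdms[k] for k in models if k != name]
            mat = drsa_matrix(neural_r, rdms[name], nuis, cfg, estimator=estimator)
            prof = lag_profile(mat, cfg)
            if sums[name] is None:
                sums[name] = np.zeros_like(prof.values)
                count_sums[name] = np.zeros_like(prof.values)
                lags_s = prof.lags_s
            finite = np.isfinite(prof.values)
            sums[name][finite] += prof.values[finite]
            count_sums[name] += finite.astype(float)

    out = {}
    for name in test_models:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_vals = np.where(count_sums[name] > 0,
                                 sums[name] / np.maximum(count_sums[name], 1), np.nan)
        out[name] = LagProfile(
            lags_s=lags_s, values=mean_vals,
            n_averaged=count_sums[name].astype(int), fs=fs,
            test_model=name, estimator=estimator,
        )
    return out
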