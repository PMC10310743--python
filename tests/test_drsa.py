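import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from dynrsa import (
    DRSAConfig,
    ImplantSpec,
    autocorr_exclusion_window,
    center_columns,
    compute_rdm_series,
    drsa_matrix,
    lag_profile,
    pcr_similarity,
    preprocess_rdm_series,
    rescale_rdm_series,
    smooth_rdm_series,
    subsample_and_average,
)
from dynrsa.drsa import DRSAMatrix
from dynrsa.feature_models import ModelTimeSeries
from dynrsa.rdm import RDMSeries


def _rdm(values, fs=50.0, n_stimuli=None, name="m"):
    values = np.asarray(values, dtype=float)
    if n_stimuli is None:
        n_stimuli = int((1 + np.sqrt(1 + 8 * values.shape[0])) / 2)
    return RDMSeries(values=values, n_stimuli=n_stimuli, fs=fs,
                     metric="one_minus_pearson", name=name)


class TestConfig:
    def test_shipped_defaults(self):
        cfg = DRSAConfig()
        assert cfg.var_threshold == 0.001
        assert cfg.max_components == 75
        assert cfg.autocorr_r2_threshold == 0.10
        assert cfg.n_iterations == 1000
        assert cfg.segment_s == 3.0
        assert cfg.lag_range_s == 1.0

    @pytest.mark.parametrize("kwargs", [
        dict(lag_range_s=0.0), dict(n_iterations=0), dict(segment_s=-1.0),
        dict(var_threshold=1.0), dict(max_components=0),
        dict(autocorr_r2_threshold=0.0),
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            DRSAConfig(**kwargs)


class TestAutocorrWindow:
    def test_white_series_window_one(self, rng):
        r = _rdm(rng.uniform(0, 2, size=(91, 200)), n_stimuli=14)
        assert autocorr_exclusion_window(r, 0.10) == 1

    def test_matches_brute_force_lag_scan(self, rng):
        raw = rng.uniform(0, 2, size=(45, 120))
        r = smooth_rdm_series(_rdm(raw, n_stimuli=10, fs=1000.0), 7.0)
        window = autocorr_exclusion_window(r, 0.10)
        # independent brute-force scan with pearsonr per (t, t+delta)
        vals = r.values
        n_time = vals.shape[1]

        def mean_r2(delta):
            rs = [pearsonr(vals[:, t], vals[:, t + delta]).statistic ** 2
                  for t in range(n_time - delta)]
            return np.mean(rs)

        expected = next(d for d in range(1, n_time) if mean_r2(d) < 0.10)
        assert window == expected

    def test_never_dropping_returns_length(self):
        r = _rdm(np.tile(np.linspace(0, 2, 6)[:, None], (1, 30)), n_stimuli=4)
        # identical slices at all times: r^2 = 1 at every lag
        assert autocorr_exclusion_window(r, 0.10) == 30


class TestPCRSimilarity:
    def test_self_regression_beta_one(self, rng):
        x = rng.normal(size=40)
        beta = pcr_similarity(x, x, [], DRSAConfig())
        assert beta == pytest.approx(1.0, abs=1e-10)

    def test_equals_ols_when_nothing_dropped(self, rng):
        # 10 predictors, 30 observations, no component dropping
        n = 30
        block = rng.normal(size=(n, 9))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        cfg = DRSAConfig(var_threshold=1e-12, max_components=75)
        beta = pcr_similarity(y, x, [block], cfg)
        # independent direct least-squares oracle on centered predictors
        xc = np.column_stack([block - block.mean(0), x - x.mean()])
        coef = np.linalg.lstsq(xc, y - y.mean(), rcond=None)[0]
        assert beta == pytest.approx(coef[-1], abs=1e-8)

    def test_zero_variance_test_slice_nan(self, rng):
        beta = pcr_similarity(rng.normal(size=20), np.ones(20), [], DRSAConfig())
        assert np.isnan(beta)

    def test_component_cap_respected(self, rng):
        # many predictors, tiny cap: still returns a finite beta
        block = rng.normal(size=(20, 100))
        beta = pcr_similarity(rng.normal(size=20), rng.normal(size=20),
                              [block], DRSAConfig(max_components=5))
        assert np.isfinite(beta)


class TestDRSAMatrix:
    def test_correlation_self_diagonal_one(self, rng):
        r = center_columns(_rdm(rng.uniform(0, 2, size=(10, 40))))
        cfg = DRSAConfig(lag_range_s=0.3)
        m = drsa_matrix(r, r, [], cfg, estimator="correlation")
        assert np.allclose(np.diagonal(m.betas), 1.0, atol=1e-10)

    def test_correlation_matches_pearson_oracle(self, rng):
        neural = center_columns(_rdm(rng.uniform(0, 2, size=(10, 40)), name="n"))
        test = center_columns(_rdm(rng.uniform(0, 2, size=(10, 40)), name="t"))
        cfg = DRSAConfig(lag_range_s=0.3)
        m = drsa_matrix(neural, test, [], cfg, estimator="correlation")
        lag = int(round(0.3 * 50))
        for _ in range(100):
            tx, ty = rng.integers(0, 40, size=2)
            if abs(ty - tx) > lag:
                assert np.isnan(m.betas[tx, ty])
            else:
                expected = pearsonr(test.values[:, tx], neural.values[:, ty]).statistic
                assert m.betas[tx, ty] == pytest.approx(expected, abs=1e-10)

    def test_cells_outside_lag_range_not_computed(self, rng):
        r = center_columns(_rdm(rng.uniform(0, 2, size=(10, 60))))
        cfg = DRSAConfig(lag_range_s=0.2)  # 10 samples at 50 Hz
        for est in ("correlation", "pcr"):
            m = drsa_matrix(r, r, [], cfg, estimator=est)
            tx, ty = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
            assert np.all(np.isnan(m.betas[np.abs(ty - tx) > 10]))

    def test_mismatched_series_error(self, rng):
        a = _rdm(rng.normal(size=(10, 40)))
        b = _rdm(rng.normal(size=(10, 30)))
        with pytest.raises(ValueError):
            drsa_matrix(a, b, [], DRSAConfig())

    def test_pcr_monotonic_with_correlation_on_norm_equalized_series(self, rng):
        # with unit-norm slices beta is a fixed positive multiple of r,
        # so ranks agree; heterogeneous norms break this (see docs)
        vals = rng.normal(size=(28, 50))
        vals -= vals.mean(axis=0)
        vals /= np.linalg.norm(vals, axis=0)
        neural = _rdm(rng.normal(size=(28, 50)), n_stimuli=8, name="n")
        neural = center_columns(neural)
        test = _rdm(vals, n_stimuli=8, name="t")
        # autocorr threshold below the white-noise r^2 floor -> the exclusion
        # window swallows the whole series, so no own-model nuisances remain
        cfg = DRSAConfig(lag_range_s=0.4, var_threshold=0.0, max_components=100,
                         autocorr_r2_threshold=0.001)
        mp = drsa_matrix(neural, test, [], cfg, estimator="pcr")
        mc = drsa_matrix(neural, test, [], cfg, estimator="correlation")
        fin = np.isfinite(mp.betas) & np.isfinite(mc.betas)
        # compare within rows (fixed t_x); neural norms still vary, so
        # normalize those too for the exact statement
        neural.values /= np.linalg.norm(neural.values, axis=0)
        mp2 = drsa_matrix(neural, test, [], cfg, estimator="pcr")
        rho = spearmanr(mp2.betas[fin], mc.betas[fin]).statistic
        assert rho > 0.99


class TestLagProfile:
    def test_constant_matrix(self):
        m = DRSAMatrix(betas=np.full((30, 30), 0.7), fs=50.0,
                       estimator="correlation", test_model="m")
        p = lag_profile(m, DRSAConfig(lag_range_s=0.2))
        assert np.allclose(p.values, 0.7)
        assert np.all(p.n_averaged > 0)

    def test_superdiagonal_peak_matches_diagonal_mean_oracle(self, rng):
        n, k = 40, 3
        betas = np.zeros((n, n))
        vals = rng.uniform(1, 2, size=n - k)
        betas[np.arange(n - k), np.arange(n - k) + k] = vals
        m = DRSAMatrix(betas=betas, fs=50.0, estimator="pcr", test_model="m")
        cfg = DRSAConfig(lag_range_s=0.3)
        p = lag_profile(m, cfg)
        assert p.peak_lag() == pytest.approx(k / 50.0)
        # brute-force diagonal mean oracle
        for idx, ell in enumerate(np.arange(-15, 16)):
            cells = [betas[tx, tx + ell] for tx in range(n)
                     if 0 <= tx + ell < n]
            assert p.values[idx] == pytest.approx(np.mean(cells), abs=1e-12)

    def test_lag_grid_size_100hz(self):
        m = DRSAMatrix(betas=np.zeros((120, 120)), fs=100.0,
                       estimator="pcr", test_model="m")
        p = lag_profile(m, DRSAConfig(lag_range_s=1.0))
        assert p.lags_s.size == 201
        assert p.lags_s[0] == -1.0 and p.lags_s[-1] == 1.0
        assert p.lags_s[100] == 0.0

    def test_symmetric_lags(self):
        m = DRSAMatrix(betas=np.zeros((30, 30)), fs=50.0,
                       estimator="pcr", test_model="m")
        p = lag_profile(m, DRSAConfig(lag_range_s=0.2))
        assert np.allclose(p.lags_s, -p.lags_s[::-1])


class TestTimeReversalSymmetry:
    def test_profile_mirrors(self, rng):
        feats = rng.normal(size=(5, 6, 50))
        m = ModelTimeSeries(name="x", fs=50.0, metric="one_minus_pearson",
                            features=feats)
        r = preprocess_rdm_series(compute_rdm_series(m), 30.0)
        neural = preprocess_rdm_series(compute_rdm_series(ModelTimeSeries(
            name="y", fs=50.0, metric="one_minus_pearson",
            features=feats + 0.3 * rng.normal(size=feats.shape))), 30.0)
        rev = lambda s: RDMSeries(values=s.values[:, ::-1].copy(),
                                  n_stimuli=s.n_stimuli, fs=s.fs,
                                  metric=s.metric, name=s.name)
        cfg = DRSAConfig(lag_range_s=0.3)
        for est in ("correlation", "pcr"):
            fwd = lag_profile(drsa_matrix(neural, r, [], cfg, est), cfg)
            bwd = lag_profile(drsa_matrix(rev(neural), rev(r), [], cfg, est), cfg)
            assert np.allclose(fwd.values, bwd.values[::-1], atol=1e-8)


class TestSubsampleAndAverage:
    def test_full_segment_equals_single_pass(self, kinematic_models):
        models = {k: kinematic_models[k] for k in ["posture_vd", "motion_vd", "gaze"]}
        neural_feats = kinematic_models["posture_vd"]
        cfg = DRSAConfig(lag_range_s=0.6, n_iterations=1, segment_s=2.0, seed=0)
        profs = subsample_and_average(models, neural_feats, cfg,
                                      test_models=["motion_vd"], kernel_ms=30.0)
        # manual single pass on the original alignment
        rdms = {k: center_columns(rescale_rdm_series(smooth_rdm_series(
            compute_rdm_series(m), 30.0))) for k, m in models.items()}
        neural = rdms["posture_vd"]
        nuis = [rdms["posture_vd"], rdms["gaze"]]
        manual = lag_profile(drsa_matrix(neural, rdms["motion_vd"], nuis, cfg), cfg)
        assert np.allclose(profs["motion_vd"].values, manual.values, atol=1e-10)

    def test_seed_determinism(self, kinematic_models):
        models = {k: kinematic_models[k] for k in ["posture_vd", "motion_vd", "gaze"]}
        spec = ImplantSpec(components=[("motion_vd", 1.0, 0.0)],
                           noise_weight=1.0, seed=5)
        cfg = DRSAConfig(lag_range_s=0.4, n_iterations=3, segment_s=1.0, seed=9)
        a = subsample_and_average(models, spec, cfg, test_models=["motion_vd"])
        b = subsample_and_average(models, spec, cfg, test_models=["motion_vd"])
        assert np.array_equal(a["motion_vd"].values, b["motion_vd"].values)

    def test_variance_shrinks_with_iterations(self, kinematic_models):
        models = {k: kinematic_models[k] for k in ["posture_vd", "motion_vd", "gaze"]}
        spec = ImplantSpec(components=[("motion_vd", 1.0, 0.0)],
                          noise_weight=2.0, seed=5)

        def peak_values(n_iter, n_rep):
            out = []
            for rep in range(n_rep):
                cfg = DRSAConfig(lag_range_s=0.4, n_iterations=n_iter,
                                 segment_s=1.0, seed=100 + rep)
                p = subsample_and_average(models, spec, cfg,
                                          test_models=["motion_vd"],
                                          estimator="correlation")
                mid = p["motion_vd"].values.size // 2
                out.append(p["motion_vd"].values[mid])
            return np.var(out, ddof=1)

        v1, v10 = peak_values(1, 10), peak_values(10, 10)
        ratio = v1 / v10
        # expect ~10; wide bounds for 9-dof variance estimates
        assert 2.0 < ratio < 50.0

    def test_precomputed_rdm_requires_full_segment(self, kinematic_models, rng):
        models = {k: kinematic_models[k] for k in ["posture_vd", "gaze"]}
        neural = _rdm(rng.uniform(0, 2, size=(10, 100)))
        cfg = DRSAConfig(lag_range_s=0.4, n_iterations=2, segment_s=1.0, seed=0)
        with pytest.raises(ValueError, match="realign"):
            subsample_and_average(models, neural, cfg)

    def test_segment_longer_than_duration(self, kinematic_models):
        models = {k: kinematic_models[k] for k in ["posture_vd", "gaze"]}
        cfg = DRSAConfig(lag_range_s=0.4, n_iterations=1, segment_s=3.0, seed=0)
        with pytest.raises(ValueError, match="segment"):
            subsample_and_average(models, models["posture_vd"], cfg)
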