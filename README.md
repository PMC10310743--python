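# dynrsa

Dynamic representational similarity analysis (dRSA) on synthetic stimuli.

The package quantifies, at every (model-time, neural-time) pair, how
strongly a time-varying neural representational dissimilarity matrix (RDM)
series matches time-varying stimulus-feature models. A two-stage
principal-component regression (PCR) isolates each model's unique
contribution from collinear, autocorrelated competitor models; diagonal
averaging yields lag profiles whose negative-lag peaks indicate predictive
neural representations. Group inference uses Fisher-Z transforms, one-sided
cluster-based permutation tests, jackknifed peak latencies, and a
representational-spread index. Everything is validated on simulated neural
RDM series with known implanted models.

## Layout

| Module | Purpose |
| --- | --- |
| `dynrsa.synthetic_stimuli` | seed-reproducible marker kinematics, rendered grayscale frames, gaze traces |
| `dynrsa.feature_models` | pixelwise, optical-flow, posture/motion (view-dependent and view-invariant via vertical-axis-constrained Procrustes), acceleration, gaze models |
| `dynrsa.rdm` | per-timepoint RDM series + boxcar smoothing, global 0–2 rescaling, per-timepoint centering |
| `dynrsa.drsa` | PCR and correlation estimators, autocorrelation exclusion, lag profiles, temporal subsampling & realignment |
| `dynrsa.neural_sim` | simulated neural RDM series (weighted lag-shifted implants + uniform noise) |
| `dynrsa.stats` | Fisher-Z, cluster permutation tests, jackknife latencies, representational spread, BH-FDR |
| `dynrsa.cli` / `dynrsa.pipeline` / `dynrsa.io` / `dynrsa.config` | CLI verbs, end-to-end workflow, HDF5/NPZ persistence, YAML config |

Conventions (fixed project-wide): lag = t_neural − t_model (positive lag =
representation follows the stimulus); RDM pair order is
(0,1), (0,2), …, (0,n−1), (1,2), … (scipy `pdist` condensed order);
preprocessing order is smooth → rescale → center.

## CLI

```sh
dynrsa simulate-stimuli --n-stimuli 14 --n-markers 13 --duration 5 --fs 100 --seed 1 -o stimuli.h5
dynrsa compute-models stimuli.h5 --sigma 5 -o models.h5
dynrsa compute-rdms models.h5 --smooth-ms 30 -o rdms.h5
dynrsa simulate-neural rdms.h5 --implant posture_vd:1:0 --noise 3 --seed 1 -o neural.h5
dynrsa run models.h5 --implant posture_vd:1:0 --noise 1 --iterations 1000 --segment 3 --seed 1 -o drsa.h5
dynrsa stats subj*.h5 --model posture_vd --alpha 0.01 --cluster-alpha 0.05 --n-perm 25000
dynrsa demo --seed 1 -o demo/
```

`dynrsa demo` runs a small end-to-end implant-recovery validation.

## Python API sketch

```python
import dynrsa as d
from dynrsa.pipeline import build_model_suite

traj = d.generate_kinematics(5, 8, 2.0, 50.0, cutoff_hz=4.0, seed=7)
frames = d.render_frames(traj, 32, 30, marker_sigma=2.0)
gaze = d.generate_gaze(5, 2.0, 50.0, cutoff_hz=4.0, seed=8)
models = build_model_suite(traj, frames, gaze, sigma=2.0)

cfg = d.DRSAConfig(lag_range_s=0.6, n_iterations=100, segment_s=1.5, seed=3)
spec = d.ImplantSpec(components=[("motion_vd", 1.0, -0.1)], noise_weight=1.0, seed=11)
profiles = d.subsample_and_average(models, spec, cfg, kernel_ms=30.0)
print(profiles["motion_vd"].peak_lag())  # ~ -0.1 s (predictive implant)
```
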