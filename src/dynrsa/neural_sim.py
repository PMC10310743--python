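"""Simulated "neural" RDM series with known implanted models.

A simulated neural series is a weighted sum of lag-shifted model RDM series
plus temporally white uniform noise.  Recovering the implanted models and
lags through the full estimation pipeline is the package's primary
validation route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rdm import RDMSeries

__all__ = ["ImplantSpec", "simulate_neural_rdm", "NOISE_RATIO_PRESETS",
           "spawn_subject_specs"]

# implant-to-noise weight ratios used in the validation sweeps
NOISE_RATIO_PRESETS: dict[str, float] = {"1:0": 0.0, "1:1": 1.0, "1:5": 5.0, "1:10": 10.0}


@dataclass
class ImplantSpec:
    """Recipe for one simulated neural RDM series.

    components: (model name, weight >= 0, lag_s) triples.  A component at
    lag L makes the neural slice at time t equal the model at time t - L
    (positive lag = neural follows the stimulus).  noise_weight scales an
    additive uniform U(0, 2) noise series with no temporal autocorrelation
    (support chosen to match the rescaled RDM range).
    """

    components: list[tuple[str, float, float]] = field(default_factory=list)
    noise_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, weight, lag_s in self.components:
            if not np.isfinite(weight) or weight < 0:
                raise ValueError(f"component {name!r}: weight must be finite and >= 0")
            if not np.isfinite(lag_s):
                raise ValueError(f"component {name!r}: lag must be finite")
        if not np.isfinite(self.noise_weight) or self.noise_weight < 0:
            raise ValueError("noise_weight must be finite and >= 0")
        if not self.components and self.noise_weight == 0:
            raise ValueError("need at least one component or noise_weight > 0")


def simulate_neural_rdm(
    models: dict[str, RDMSeries] | list[RDMSeries], spec: ImplantSpec
) -> RDMSeries:
    """Weighted sum of lag-shifted model RDM series plus uniform noise.

    Lags are rounded to integer samples (RDM slices are not band-limited
    objects, so interpolation would be unjustified).  Shift edges are
    truncated to the range where every component is valid; the number of
    samples cut from the start is recorded in ``meta['t0_offset']`` so
    callers can crop model series to match.  All input series are expected
    on the common rescaled 0-2 range and time-aligned.
    """
    if isinstance(models, list):
        models = {m.name: m for m in models}
    if not models:
        raise ValueError("need at least one model series")
    first = next(iter(models.values()))
    n_pairs, n_time, fs = first.n_pairs, first.n_time, first.fs
    for m in models.values():
        if m.n_pairs != n_pairs or m.n_time != n_time or m.fs != fs:
            raise ValueError("model series must be time-aligned with equal pair counts")

    shifts = []
    for name, _, lag_s in spec.components:
        if name not in models:
            raise KeyError(f"unknown model {name!r} in implant spec")
        shift = int(round(lag_s * fs))
        if abs(shift) >= n_time:
            raise ValueError(f"lag shift of {name!r} exceeds the series length")
        shifts.append(shift)

    start = max([0] + [s for s in shifts if s > 0])
    stop = n_time + min([0] + [s for s in shifts if s < 0])
    if stop <= start:
        raise ValueError("implant lags leave no common valid time range")
    n_valid = stop - start

    total = np.zeros((n_pairs, n_valid))
    for (name, weight, _), shift in zip(spec.components, shifts):
        total += weight * models[name].values[:, start - shift : stop - shift]
    if spec.noise_weight > 0:
        rng = np.random.default_rng(spec.seed)
        total += spec.noise_weight * rng.uniform(0.0, 2.0, size=(n_pairs, n_valid))

    return RDMSeries(
        values=total, n_stimuli=first.n_stimuli, fs=fs,
        metric="simulated", name="simulated_neural",
        meta={"t0_offset": start, "implant": [list(c) for c in spec.components],
              "noise_weight": spec.noise_weight},
    )


def spawn_subject_specs(spec: ImplantSpec, n_subjects: int) -> list[ImplantSpec]:
    """Independent noise seeds per simulated subject, identical implants."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    return [
        ImplantSpec(components=list(spec.components),
                    noise_weight=spec.noise_weight,
                    seed=int(child.generate_state(1)[0]))
        for child in children
    ]
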