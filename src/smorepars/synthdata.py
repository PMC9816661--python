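"""Synthetic calibration data with known ground truth.

Real calibration data for this pipeline are xenograft tumor-volume
time-courses: replicate volume curves rising sigmoidally toward a plateau
around 2,000 mm^3, measured by caliper every few days.  This module emulates
that data shape from a von Bertalanffy generator with multiplicative
lognormal noise (volumes are positive and caliper error scales with size),
so every step downstream of data ingestion can be exercised against a known
ground truth.  It can also package replicate ABM runs into the same
mean +/- SE dataset schema for end-to-end closure tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .abm import ABMConfig, run_replicates
from .fitting import GrowthDataset
from .surrogate import SMParams, solve

#: default vB generator: plateau (alpha/beta)^(1/(1-gamma)) = 2000 mm^3,
#: gamma = 2/3 (surface-limited growth), beta = 0.18 /day
DEFAULT_GENERATOR = dict(
    model="von_bertalanffy",
    values={"alpha": 0.18 * 2000.0 ** (1.0 / 3.0), "gamma": 2.0 / 3.0, "beta": 0.18},
    N0=50.0,
    unit="mm3",
)


@dataclass
class SynthConfig:
    """Configuration of the xenograft-style synthetic data generator."""

    generator: SMParams = None
    times: np.ndarray = None  # measurement days
    n_replicates: int = 8
    noise_cv: float = 0.05  # coefficient of variation of multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator is None:
            self.generator = SMParams(**DEFAULT_GENERATOR)
        if self.times is None:
            self.times = np.arange(0.0, 40.0, 3.0)  # 14 points, every 3 days
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate(config: SynthConfig) -> GrowthDataset:
    """Replicate noisy trajectories -> mean +/- SE dataset with ground truth.

    Each replicate is the generator trajectory multiplied pointwise by
    lognormal noise with unit mean and coefficient of variation ``noise_cv``.
    The generating parameters are recorded in the dataset metadata.
    """
    rng = np.random.default_rng(config.seed)
    y = solve(config.generator, config.times)
    if config.noise_cv > 0:
        # lognormal with E=1, CV=noise_cv
        s2 = np.log(1.0 + config.noise_cv**2)
        noise = rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=(config.n_replicates, len(y)))
        reps = y[None, :] * noise
    else:
        reps = np.tile(y, (config.n_replicates, 1))
    z = reps.mean(axis=0)
    se = reps.std(axis=0, ddof=1) / np.sqrt(config.n_replicates) if config.n_replicates > 1 else np.zeros_like(z)
    ds = GrowthDataset(config.times, z, se, unit=config.generator.unit, provenance="synthetic")
    ds.meta["truth"] = dict(config.generator.values)
    ds.meta["N0"] = config.generator.N0
    ds.meta["seed"] = config.seed
    return ds


def generate_abm_reference(
    p_div: float,
    div_lim: int,
    reps: int,
    config: Optional[ABMConfig] = None,
) -> GrowthDataset:
    """Replicate ABM cell-count curves -> mean +/- SE dataset (times in days).

    Stands in for "experimental" data in closure tests where the generating
    (p_div, div_lim) is known.  Replicate r runs with seed config.seed + r.
    """
    base = config or ABMConfig()
    cfg = ABMConfig(**{**_cfg_dict(base), "p_div": p_div, "div_lim": int(div_lim)})
    runs = run_replicates(cfg, reps)
    counts = np.stack([r.n_cells for r in runs]).astype(float)
    z = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros_like(z)
    ds = GrowthDataset(runs[0].time_days, z, se, unit="cells", provenance="abm")
    ds.meta["p_div"] = p_div
    ds.meta["div_lim"] = int(div_lim)
    ds.meta["seeds"] = [r.config.seed for r in runs]
    return ds


def _cfg_dict(cfg: ABMConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)
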