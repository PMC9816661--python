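"""End-to-end orchestration of the six-step surrogate calibration strategy.

1. Formulate the surrogate from the calibration data (a growth-law ODE for
   volume time-courses).
2. Sweep the ABM over a (p_div, div_lim) grid with seeded replicates and
   average the output into mean +/- SE datasets.
3. Select the surrogate by AIC/BIC over the candidate growth laws.
4. Fit the surrogate at every grid node, profile beta and gamma, and
   interpolate the 95% CI endpoints into confidence surfaces.
5. Fit the surrogate to the calibration ("experimental") data, profile, and
   infer the identifiable beta-gamma combination.
6. Project data-admissible (beta, gamma) pairs through the surfaces,
   intersect per pair, union over pairs: the data-consistent ABM region.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .abm import ABMConfig
from .fitting import (
    DegenerateCombinationError,
    FitResult,
    GrowthDataset,
    IdentifiableCombination,
    LikelihoodProfile,
    fit,
    infer_combination,
    profile,
    profile_pairs,
)
from .regions import ParameterRegion, infer_data_region, make_grid, region_from_pairs
from .surfaces import ConfidenceSurface, build_surface, collect_nodes, save_surfaces
from .surrogate import MODEL_PARAMS, ModelScore, information_criteria, pooled_score, select_model
from .synthdata import SynthConfig, generate, generate_abm_reference


@dataclass
class PipelineConfig:
    p_div_values: Sequence[float] = (0.05, 0.125, 0.245)
    div_lim_values: Sequence[int] = (8, 12, 15)
    replicates: int = 6
    abm: ABMConfig = field(default_factory=ABMConfig)
    candidate_models: Sequence[str] = ("von_bertalanffy",)
    #: calibration data: a GrowthDataset, a SynthConfig, or None (default synth)
    experimental: object = None
    seed: int = 0
    n_starts: int = 20
    sm_params: Sequence[str] = ("beta", "gamma")
    region_resolution: int = 101
    n_beta_samples: int = 25

    def __post_init__(self) -> None:
        if len(set(self.p_div_values)) < 2 or len(set(self.div_lim_values)) < 2:
            raise ValueError("grid needs >= 2 distinct values per axis")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (standard errors need spread)")


@dataclass
class PipelineResult:
    selected_model: str
    model_scores: List[ModelScore]
    node_fits: Dict[Tuple[float, int], FitResult]
    node_profiles: Dict[Tuple[float, int], Dict[str, LikelihoodProfile]]
    surfaces: Dict[str, ConfidenceSurface]
    experimental_fit: FitResult
    experimental_profiles: Dict[str, LikelihoodProfile]
    combination: Optional[IdentifiableCombination]
    region: ParameterRegion
    report: dict


def run_grid_sweep(config: PipelineConfig) -> Dict[Tuple[float, int], GrowthDataset]:
    """Seeded replicate ABM runs at every grid node, averaged into datasets.

    Node k gets base seed config.seed + 1000*k (replicate r adds r), keeping
    nodes and replicates on distinct, reproducible streams.
    """
    datasets: Dict[Tuple[float, int], GrowthDataset] = {}
    k = 0
    for p in config.p_div_values:
        for d in config.div_lim_values:
            cfg = ABMConfig(**{**asdict(config.abm), "seed": config.seed + 1000 * k})
            try:
                datasets[(p, int(d))] = generate_abm_reference(p, int(d), config.replicates, cfg)
            except Exception as exc:
                raise RuntimeError(f"ABM sweep failed at node (p_div={p}, div_lim={d})") from exc
            k += 1
    return datasets


def _select(config: PipelineConfig, datasets: Dict) -> Tuple[str, List[ModelScore]]:
    if len(config.candidate_models) == 1:
        m = config.candidate_models[0]
        return m, []
    pooled = []
    for model in config.candidate_models:
        per = []
        for key, ds in datasets.items():
            fr = fit(model, ds, n_starts=config.n_starts, seed=config.seed)
            k = len(MODEL_PARAMS[model])
            per.append(information_criteria(fr.chi2, len(ds), k, model, str(key)))
        pooled.append(pooled_score(model, per))
    return select_model(pooled)


def _experimental_dataset(config: PipelineConfig) -> GrowthDataset:
    exp = config.experimental
    if exp is None:
        exp = SynthConfig(seed=config.seed + 777)
    if isinstance(exp, SynthConfig):
        return generate(exp)
    if isinstance(exp, GrowthDataset):
        return exp
    raise TypeError("experimental must be a GrowthDataset, SynthConfig or None")


def run_full(config: PipelineConfig, out_dir: Optional[str] = None) -> PipelineResult:
    """Execute steps 2-6 and return every intermediate artifact."""
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    datasets = run_grid_sweep(config)
    selected, scores = _select(config, datasets)

    node_fits: Dict[Tuple[float, int], FitResult] = {}
    node_profiles: Dict[Tuple[float, int], Dict[str, LikelihoodProfile]] = {}
    for key, ds in datasets.items():
        fr = fit(selected, ds, n_starts=config.n_starts, seed=config.seed)
        node_fits[key] = fr
        node_profiles[key] = {
            p: profile(fr, ds, p) for p in config.sm_params
        }

    surfaces = {
        p: build_surface(collect_nodes(node_profiles, p, strict=False))
        for p in config.sm_params
    }
    if out:
        save_surfaces(out / "surfaces.json", surfaces)

    exp_ds = _experimental_dataset(config)
    exp_fit = fit(selected, exp_ds, n_starts=config.n_starts, seed=config.seed)
    exp_profiles = {p: profile(exp_fit, exp_ds, p) for p in config.sm_params}

    beta_prof = exp_profiles["beta"]
    pairs = profile_pairs(beta_prof, selected)
    combination: Optional[IdentifiableCombination] = None
    try:
        combination = infer_combination(pairs)
    except DegenerateCombinationError:
        combination = None

    grid = make_grid(surfaces["beta"], config.region_resolution, config.region_resolution)
    lo = beta_prof.ci_lower if not beta_prof.lower_open else float(beta_prof.grid.min())
    hi = beta_prof.ci_upper if not beta_prof.upper_open else float(beta_prof.grid.max())
    if combination is not None:
        region = infer_data_region(
            surfaces["beta"], surfaces["gamma"], combination,
            (lo, hi), config.n_beta_samples, grid,
        )
    else:
        region = region_from_pairs(surfaces["beta"], surfaces["gamma"], pairs, grid)

    report = {
        "selected_model": selected,
        "experimental_params": exp_fit.params.values,
        "experimental_chi2": exp_fit.chi2,
        "beta_ci": [beta_prof.ci_lower, beta_prof.ci_upper],
        "beta_open": [beta_prof.lower_open, beta_prof.upper_open],
        "combination": combination.to_dict() if combination else None,
        "region": region.summary(),
        "node_params": {str(k): f.params.values for k, f in node_fits.items()},
        "node_ci": {
            str(k): {p: [pr.ci_lower, pr.ci_upper] for p, pr in profs.items()}
            for k, profs in node_profiles.items()
        },
        "seed": config.seed,
    }
    if out:
        region.to_csv(out / "region.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)

    return PipelineResult(
        selected_model=selected, model_scores=scores, node_fits=node_fits,
        node_profiles=node_profiles, surfaces=surfaces,
        experimental_fit=exp_fit, experimental_profiles=exp_profiles,
        combination=combination, region=region, report=report,
    )
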