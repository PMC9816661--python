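"""Stochastic 3D on-lattice simulator of stem-cell-driven vascular tumor growth.

The simulation domain is a 1 mm cube shared by two lattices: a 50^3 tumor
lattice (20 um site spacing, one cell per site) and a 10-fold finer 500^3
vessel lattice (2 um).  The tumor is seeded with stem and progenitor cells
packed into one corner; mature perfused vessels run along the boundary faces
nearest that corner.  Each iteration (~6 h) performs, in order: perfusion
update, oxygenation classification (distance to nearest perfused vessel site
vs the oxygen diffusion limit), sprouting / tip migration / anastomosis,
cell divisions, cell migrations, and senescent cell death.

Progenitor cells divide with probability ``p_div`` per iteration until their
lineage has used ``div_lim`` divisions, then senesce (remaining on the
lattice, blocking space, until removed with probability
``senescent_death_prob`` per iteration).  Stem cells divide rarely and
symmetrically with a small probability, otherwise producing a fresh
progenitor.  Hypoxic cells divide at a reduced probability and migrate at
the high rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._kernels import MOORE, division_kernel, migration_kernel
from .vasculature import (
    Vasculature,
    anastomose,
    initial_vasculature,
    maybe_branch,
    migrate_tips,
    update_perfusion,
)


class ConfigurationError(ValueError):
    pass


@dataclass
class ABMConfig:
    """Baseline ABM parameters; p_div and div_lim default to the centers of
    their calibration ranges (0.05-0.245 and 8-15)."""

    p_div: float = 0.125
    div_lim: int = 12
    stem_div_prob: float = 0.05
    stem_symmetric_prob: float = 0.05
    n_stem_init: int = 20
    n_prog_init: int = 80
    n_vessels_init: int = 8
    high_migration_rate: float = 8.3  # um/hour
    low_migration_rate: float = 0.83  # um/hour
    p_high_migratory_daughter: float = 0.05
    max_branch_prob: float = 0.2  # per segment per iteration
    senescent_death_prob: float = 0.1  # per iteration
    n_iterations: int = 300
    hours_per_iteration: float = 6.0
    domain_side: float = 1.0  # mm
    tumor_lattice_n: int = 50
    vessel_lattice_n: int = 500
    oxygen_radius: float = 100.0  # um, O2 diffusion limit from perfused vessels
    vegf_radius: float = 200.0  # um, hypoxic-cell influence range for sprouting
    tip_speed: float = 20.0  # um per iteration
    anastomosis_radius: float = 20.0  # um
    hypoxic_div_factor: float = 0.5  # multiplies division probability
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "p_div": self.p_div, "stem_div_prob": self.stem_div_prob,
            "stem_symmetric_prob": self.stem_symmetric_prob,
            "p_high_migratory_daughter": self.p_high_migratory_daughter,
            "max_branch_prob": self.max_branch_prob,
            "senescent_death_prob": self.senescent_death_prob,
            "hypoxic_div_factor": self.hypoxic_div_factor,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.div_lim < 1:
            raise ConfigurationError("div_lim must be >= 1")
        if self.vessel_lattice_n % self.tumor_lattice_n != 0:
            raise ConfigurationError("tumor lattice must divide vessel lattice")
        for name in ("n_stem_init", "n_prog_init", "n_vessels_init", "n_iterations"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def site_spacing_um(self) -> float:
        return self.domain_side * 1000.0 / self.tumor_lattice_n

    @property
    def fine_spacing_um(self) -> float:
        return self.domain_side * 1000.0 / self.vessel_lattice_n

    @property
    def refinement(self) -> int:
        return self.vessel_lattice_n // self.tumor_lattice_n

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ABMConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ABMState:
    """Lattice occupancy of cells and vessels at one iteration."""

    iteration: int
    pos: np.ndarray  # (N, 3) int64 tumor-lattice coordinates
    phenotype: np.ndarray  # uint8: 0 stem, 1 progenitor
    divisions_used: np.ndarray  # int64
    migratory: np.ndarray  # uint8: 0 low, 1 high
    senescent: np.ndarray  # bool
    hypoxic: np.ndarray  # bool
    occ: np.ndarray  # bool (n, n, n)
    vessels: Vasculature
    cumulative_divisions: int = 0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))  # iteration-0 centroid
    _oxy_cache: Optional[Tuple[int, cKDTree]] = None

    @property
    def n_cells(self) -> int:
        return len(self.pos)

    @property
    def n_stem(self) -> int:
        return int(np.sum(self.phenotype == 0))

    @property
    def n_hypoxic(self) -> int:
        return int(np.sum(self.hypoxic))

    def check_invariants(self, config: ABMConfig) -> None:
        """One cell per site, confinement, senescence and occupancy accounting."""
        n = config.tumor_lattice_n
        if len(self.pos):
            if self.pos.min() < 0 or self.pos.max() >= n:
                raise AssertionError("cell outside lattice bounds")
            flat = (self.pos[:, 0] * n + self.pos[:, 1]) * n + self.pos[:, 2]
            if len(np.unique(flat)) != len(flat):
                raise AssertionError("two cells share a lattice site")
            if not np.all(self.occ[tuple(self.pos.T)]):
                raise AssertionError("occupancy grid out of sync")
        if int(self.occ.sum()) != len(self.pos):
            raise AssertionError("occupancy count mismatch")
        prog = self.phenotype == 1
        if np.any(self.divisions_used[prog] > config.div_lim):
            raise AssertionError("progenitor exceeded div_lim")
        if np.any(self.senescent & (self.phenotype == 0)):
            raise AssertionError("senescent stem cell")


@dataclass
class ABMTimeSeries:
    """Per-iteration population counts plus the final spatial snapshot."""

    iterations: np.ndarray
    n_cells: np.ndarray
    n_hypoxic: np.ndarray
    n_stem: np.ndarray
    cumulative_divisions: np.ndarray
    final_cell_pos: np.ndarray
    final_cell_phenotype: np.ndarray
    final_cell_migratory: np.ndarray
    final_cell_senescent: np.ndarray
    final_vessel_points: np.ndarray
    final_vessel_perfused: np.ndarray
    origin: np.ndarray
    config: ABMConfig

    @property
    def time_hours(self) -> np.ndarray:
        return self.iterations * self.config.hours_per_iteration

    @property
    def time_days(self) -> np.ndarray:
        return self.time_hours / 24.0

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "iteration": self.iterations,
            "time_hours": self.time_hours,
            "n_cells": self.n_cells,
            "n_hypoxic": self.n_hypoxic,
            "n_stem": self.n_stem,
            "cum_divisions": self.cumulative_divisions,
        }).to_csv(path, index=False)

    def snapshot_to_csv(self, cells_path, vessels_path) -> None:
        import pandas as pd

        status = np.where(self.final_cell_senescent, "senescent", "cycling")
        pd.DataFrame({
            "x": self.final_cell_pos[:, 0], "y": self.final_cell_pos[:, 1],
            "z": self.final_cell_pos[:, 2],
            "phenotype": np.where(self.final_cell_phenotype == 0, "stem", "progenitor"),
            "migratory_class": np.where(self.final_cell_migratory == 1, "high", "low"),
            "status": status,
        }).to_csv(cells_path, index=False)
        pd.DataFrame({
            "x": self.final_vessel_points[:, 0], "y": self.final_vessel_points[:, 1],
            "z": self.final_vessel_points[:, 2],
            "perfused": self.final_vessel_perfused.astype(int),
        }).to_csv(vessels_path, index=False)


# ---------------------------------------------------------------------------
# operations


def _corner_sites(n_lattice: int, n_total: int) -> np.ndarray:
    """First n_total lattice sites ordered by distance from the origin corner."""
    side = min(n_lattice, 10)
    if n_total > side**3:
        raise ConfigurationError(
            f"initial cell count {n_total} exceeds corner-region capacity {side**3}"
        )
    g = np.mgrid[0:side, 0:side, 0:side].reshape(3, -1).T
    key = (g**2).sum(axis=1)
    order = np.lexsort((g[:, 2], g[:, 1], g[:, 0], key))
    return g[order[:n_total]]


def initialize(config: ABMConfig) -> ABMState:
    """Initial state: corner-packed tumor, mature vessels on adjacent faces."""
    rng = np.random.default_rng(config.seed)
    n_total = config.n_stem_init + config.n_prog_init
    sites = _corner_sites(config.tumor_lattice_n, n_total)

    phenotype = np.ones(n_total, dtype=np.uint8)
    if n_total:
        stem_idx = rng.choice(n_total, size=config.n_stem_init, replace=False)
        phenotype[stem_idx] = 0
    migratory = (rng.random(n_total) < config.p_high_migratory_daughter).astype(np.uint8)

    n = config.tumor_lattice_n
    occ = np.zeros((n, n, n), dtype=bool)
    if n_total:
        occ[tuple(sites.T)] = True

    state = ABMState(
        iteration=0,
        pos=sites.astype(np.int64),
        phenotype=phenotype,
        divisions_used=np.zeros(n_total, dtype=np.int64),
        migratory=migratory,
        senescent=np.zeros(n_total, dtype=bool),
        hypoxic=np.zeros(n_total, dtype=bool),
        occ=occ,
        vessels=initial_vasculature(config.vessel_lattice_n, config.n_vessels_init),
        origin=sites.mean(axis=0) if n_total else np.zeros(3),
    )
    classify_oxygenation(state, config)
    return state


def classify_oxygenation(state: ABMState, config: ABMConfig) -> ABMState:
    """Mark cells normoxic iff within oxygen_radius (um) of a perfused vessel site.

    The KD-tree over perfused sites is cached and rebuilt only when the
    perfused point count changes (the perfused set only ever grows).
    """
    if state.n_cells == 0:
        return state
    perfused = state.vessels.perfused_points()
    if len(perfused) == 0:
        state.hypoxic[:] = True
        return state
    if state._oxy_cache is None or state._oxy_cache[0] != len(perfused):
        tree = cKDTree(perfused * config.fine_spacing_um)
        state._oxy_cache = (len(perfused), tree)
    tree = state._oxy_cache[1]
    d, _ = tree.query(state.pos * config.site_spacing_um, k=1)
    state.hypoxic = d > config.oxygen_radius
    return state


def attempt_divisions(state: ABMState, config: ABMConfig, rng: np.random.Generator) -> ABMState:
    """One division sweep over all cells (shuffled order)."""
    if state.n_cells == 0:
        return state
    seed = int(rng.integers(2**31))
    d_pos, d_phen, d_used, d_mig, d_hyp, nd = division_kernel(
        state.occ, state.pos, state.phenotype, state.divisions_used,
        state.migratory, state.senescent, state.hypoxic,
        config.p_div, config.stem_div_prob, config.stem_symmetric_prob,
        config.p_high_migratory_daughter, config.hypoxic_div_factor,
        config.div_lim, MOORE, seed,
    )
    if nd:
        state.pos = np.concatenate([state.pos, d_pos])
        state.phenotype = np.concatenate([state.phenotype, d_phen])
        state.divisions_used = np.concatenate([state.divisions_used, d_used])
        state.migratory = np.concatenate([state.migratory, d_mig])
        state.senescent = np.concatenate(
            [state.senescent, (d_phen == 1) & (d_used >= config.div_lim)]
        )
        state.hypoxic = np.concatenate([state.hypoxic, d_hyp])
        state.cumulative_divisions += int(nd)
    return state


def attempt_migrations(state: ABMState, config: ABMConfig, rng: np.random.Generator) -> ABMState:
    """One migration sweep (shuffled order); hypoxic cells use the high rate."""
    if state.n_cells == 0:
        return state
    h = config.hours_per_iteration / config.site_spacing_um
    seed = int(rng.integers(2**31))
    migration_kernel(
        state.occ, state.pos, state.migratory, state.hypoxic,
        config.low_migration_rate * h, config.high_migration_rate * h,
        MOORE, seed,
    )
    return state


def _senescent_death(state: ABMState, config: ABMConfig, rng: np.random.Generator) -> int:
    if state.n_cells == 0 or config.senescent_death_prob <= 0:
        return 0
    dies = state.senescent & (rng.random(state.n_cells) < config.senescent_death_prob)
    n_dead = int(dies.sum())
    if n_dead:
        state.occ[tuple(state.pos[dies].T)] = False
        keep = ~dies
        state.pos = state.pos[keep]
        state.phenotype = state.phenotype[keep]
        state.divisions_used = state.divisions_used[keep]
        state.migratory = state.migratory[keep]
        state.senescent = state.senescent[keep]
        state.hypoxic = state.hypoxic[keep]
    return n_dead


def step(state: ABMState, config: ABMConfig, rng: np.random.Generator) -> dict:
    """Advance one iteration; returns a ledger {divisions, deaths, moves...}.

    Order: perfusion update -> oxygenation -> sprouting -> tip migration ->
    anastomosis -> divisions -> migrations -> senescent death.
    """
    update_perfusion(state.vessels)
    classify_oxygenation(state, config)

    hyp_um = state.pos[state.hypoxic] * config.site_spacing_um
    maybe_branch(
        state.vessels, hyp_um, config.vegf_radius, config.max_branch_prob,
        config.fine_spacing_um, rng,
    )
    cells_fine = state.pos * config.refinement
    migrate_tips(
        state.vessels, cells_fine, config.tip_speed, config.fine_spacing_um,
        config.vessel_lattice_n,
    )
    anastomose(state.vessels, config.anastomosis_radius, config.fine_spacing_um)

    n_before = state.n_cells
    divs_before = state.cumulative_divisions
    attempt_divisions(state, config, rng)
    attempt_migrations(state, config, rng)
    deaths = _senescent_death(state, config, rng)
    state.iteration += 1
    return {
        "divisions": state.cumulative_divisions - divs_before,
        "deaths": deaths,
        "n_before": n_before,
        "n_after": state.n_cells,
    }


def run_simulation(config: ABMConfig, check_invariants: bool = False) -> ABMTimeSeries:
    """Run the configured number of iterations and collect the time series."""
    rng = np.random.default_rng(config.seed)
    state = initialize(config)
    n_it = config.n_iterations
    rec = {k: np.zeros(n_it, dtype=np.int64) for k in ("n_cells", "n_hypoxic", "n_stem", "cum")}
    for t in range(n_it):
        ledger = step(state, config, rng)
        if ledger["n_after"] != ledger["n_before"] + ledger["divisions"] - ledger["deaths"]:
            raise AssertionError("cell-count ledger violated")
        rec["n_cells"][t] = state.n_cells
        rec["n_hypoxic"][t] = state.n_hypoxic
        rec["n_stem"][t] = state.n_stem
        rec["cum"][t] = state.cumulative_divisions
        if check_invariants:
            state.check_invariants(config)
    update_perfusion(state.vessels)
    v_pts, v_flags = state.vessels.all_points()
    return ABMTimeSeries(
        iterations=np.arange(1, n_it + 1),
        n_cells=rec["n_cells"],
        n_hypoxic=rec["n_hypoxic"],
        n_stem=rec["n_stem"],
        cumulative_divisions=rec["cum"],
        final_cell_pos=state.pos.copy(),
        final_cell_phenotype=state.phenotype.copy(),
        final_cell_migratory=state.migratory.copy(),
        final_cell_senescent=state.senescent.copy(),
        final_vessel_points=v_pts,
        final_vessel_perfused=v_flags,
        origin=state.origin.copy(),
        config=config,
    )


def replicate_seeds(root_seed: int, n_reps: int) -> list:
    """Replicate r uses stream seed root + r (recorded in output metadata)."""
    return [int(root_seed) + r for r in range(n_reps)]


def run_replicates(config: ABMConfig, n_reps: int) -> list:
    """Seeded replicate runs; replicate r uses seed = config.seed + r."""
    out = []
    for s in replicate_seeds(config.seed, n_reps):
        cfg = ABMConfig(**{**asdict(config), "seed": s})
        out.append(run_simulation(cfg))
    return out
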