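"""Tumor-module behavior: initialization, oxygenation, division, migration."""

from dataclasses import asdict

import numpy as np
import pytest

from smorepars.abm import (
    ABMConfig,
    ConfigurationError,
    attempt_divisions,
    attempt_migrations,
    classify_oxygenation,
    initialize,
    run_simulation,
    step,
)
from smorepars.vasculature import MatureVessel, Vasculature

from conftest import make_state


def cfg_with(**kw):
    base = dict(seed=3)
    base.update(kw)
    return ABMConfig(**base)


class TestInitialize:
    def test_baseline_counts(self):
        state = initialize(ABMConfig(seed=0))
        assert state.n_cells == 100
        assert state.n_stem == 20
        assert len(state.vessels.mature) == 8
        assert state.iteration == 0
        state.check_invariants(ABMConfig(seed=0))

    def test_cells_cluster_in_origin_corner(self):
        state = initialize(ABMConfig(seed=0))
        assert state.pos.max() < 10

    def test_empty_tumor_is_valid(self):
        state = initialize(cfg_with(n_stem_init=0, n_prog_init=0))
        assert state.n_cells == 0

    def test_same_seed_gives_identical_states(self):
        a = initialize(ABMConfig(seed=7))
        b = initialize(ABMConfig(seed=7))
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.phenotype, b.phenotype)
        assert np.array_equal(a.migratory, b.migratory)

    def test_corner_capacity_exceeded_rejected(self):
        with pytest.raises(ConfigurationError):
            initialize(cfg_with(n_stem_init=500, n_prog_init=600))


class TestOxygenation:
    def test_cell_on_perfused_segment_is_normoxic(self, small_config):
        pts = np.array([[i, 0, 0] for i in range(200)])
        vasc = Vasculature([MatureVessel(pts[0], pts[-1], pts)])
        state = make_state([[0, 0, 0]], small_config, vessels=vasc)
        classify_oxygenation(state, small_config)
        assert not state.hypoxic[0]

    def test_no_perfused_vessels_makes_all_hypoxic(self, small_config):
        state = make_state([[0, 0, 0], [5, 5, 5]], small_config)
        classify_oxygenation(state, small_config)
        assert state.hypoxic.all()

    def test_classification_matches_brute_force_distances(self, small_config):
        # one perfused segment along x at y=z=0 (fine lattice, 10 um spacing here)
        pts = np.array([[i, 0, 0] for i in range(200)])
        vasc = Vasculature([MatureVessel(pts[0], pts[-1], pts)])
        rng = np.random.default_rng(8)
        cells = rng.integers(0, 20, size=(30, 3))
        cells = np.unique(cells, axis=0)
        state = make_state(cells, small_config, vessels=vasc)
        classify_oxygenation(state, small_config)
        fine_um = small_config.fine_spacing_um
        for i, c in enumerate(state.pos):
            d = np.min(np.linalg.norm(pts * fine_um - c * small_config.site_spacing_um, axis=1))
            assert state.hypoxic[i] == (d > small_config.oxygen_radius)

    def test_cells_straddling_oxygen_radius(self, small_config):
        # segment at y=0; cells at y = 1, 2, 3 sites (50, 100, 150 um)
        pts = np.array([[i, 0, 0] for i in range(200)])
        vasc = Vasculature([MatureVessel(pts[0], pts[-1], pts)])
        cfg = ABMConfig(**{**asdict(small_config), "oxygen_radius": 100.0})
        state = make_state([[0, 1, 0], [0, 2, 0], [0, 3, 0]], cfg, vessels=vasc)
        classify_oxygenation(state, cfg)
        # site spacing is 50 um on this 20-site/1mm lattice
        assert list(state.hypoxic) == [False, False, True]


def enumerate_branching(div_lim, n_iters):
    """Deterministic oracle: every cell divides while its lineage has
    divisions left; both products carry the incremented count."""
    counts = []
    cells = [0]
    for _ in range(n_iters):
        nxt = []
        for used in cells:
            if used < div_lim:
                nxt.extend([used + 1, used + 1])
            else:
                nxt.append(used)
        cells = nxt
        counts.append(len(cells))
    return counts


class TestDivisions:
    def test_null_dynamics_preserves_count(self, small_config):
        cfg = ABMConfig(**{**asdict(small_config), "p_div": 0.0, "stem_div_prob": 0.0})
        state = make_state([[5, 5, 5], [6, 6, 6]], cfg)
        attempt_divisions(state, cfg, np.random.default_rng(0))
        assert state.n_cells == 2

    @pytest.mark.parametrize("div_lim,n_iters", [(3, 4), (2, 3)])
    def test_forced_division_matches_branching_enumeration(self, div_lim, n_iters):
        cfg = ABMConfig(
            p_div=1.0, div_lim=div_lim, hypoxic_div_factor=1.0,
            senescent_death_prob=0.0, tumor_lattice_n=20, vessel_lattice_n=200, seed=0,
        )
        state = make_state([[10, 10, 10]], cfg)
        rng = np.random.default_rng(4)
        observed = []
        for _ in range(n_iters):
            attempt_divisions(state, cfg, rng)
            observed.append(state.n_cells)
        assert observed == enumerate_branching(div_lim, n_iters)
        assert state.cumulative_divisions == observed[-1] - 1

    def test_forced_symmetric_stem_division(self, small_config):
        cfg = ABMConfig(**{**asdict(small_config),
                           "stem_div_prob": 1.0, "stem_symmetric_prob": 1.0})
        state = make_state([[5, 5, 5]], cfg, phenotype=[0])
        attempt_divisions(state, cfg, np.random.default_rng(1))
        assert state.n_cells == 2
        assert state.n_stem == 2

    def test_fully_surrounded_cell_cannot_divide(self, small_config):
        cfg = ABMConfig(**{**asdict(small_config), "p_div": 1.0})
        center = np.array([5, 5, 5])
        positions = [center + np.array(o) - 1 for o in np.ndindex(3, 3, 3)]
        state = make_state(positions, cfg)
        # make only the center cell non-senescent so only it attempts
        state.senescent[:] = True
        idx = int(np.where((state.pos == center).all(axis=1))[0][0])
        state.senescent[idx] = False
        n0 = state.n_cells
        attempt_divisions(state, cfg, np.random.default_rng(2))
        assert state.n_cells == n0

    def test_no_progenitor_exceeds_div_lim(self):
        cfg = ABMConfig(p_div=0.6, div_lim=4, n_iterations=25, seed=5)
        ts = run_simulation(cfg, check_invariants=True)
        assert ts.n_cells[-1] > 0


class TestMigrations:
    def test_zero_rate_means_no_movement(self, small_config):
        cfg = ABMConfig(**{**asdict(small_config),
                           "high_migration_rate": 0.0, "low_migration_rate": 0.0})
        state = make_state([[5, 5, 5]], cfg)
        attempt_migrations(state, cfg, np.random.default_rng(0))
        assert np.array_equal(state.pos, [[5, 5, 5]])

    def test_fully_blocked_cells_stay_put(self):
        # a completely filled 3^3 lattice: every cell (26 or fewer neighbours,
        # all occupied or out of bounds) is immobile
        cfg = ABMConfig(tumor_lattice_n=3, vessel_lattice_n=30,
                        high_migration_rate=100.0, low_migration_rate=100.0, seed=0)
        positions = list(np.ndindex(3, 3, 3))
        state = make_state(positions, cfg)
        before = state.pos.copy()
        attempt_migrations(state, cfg, np.random.default_rng(1))
        assert np.array_equal(state.pos, before)

    def test_observed_step_rate_matches_expected_fraction(self):
        """0.83 um/h at 6 h/iter on a 20 um lattice -> 0.249 steps/iteration."""
        cfg = ABMConfig(high_migration_rate=0.83, low_migration_rate=0.83, seed=0)
        expected = 0.83 * 6.0 / 20.0
        state = make_state([[25, 25, 25]], cfg)
        rng = np.random.default_rng(42)
        n_trials = 10_000
        moves = 0
        for _ in range(n_trials):
            before = state.pos[0].copy()
            attempt_migrations(state, cfg, rng)
            moves += not np.array_equal(before, state.pos[0])
            # keep the walker near the interior so no step is ever rejected
            if np.any(state.pos[0] < 5) or np.any(state.pos[0] > 45):
                state.occ[tuple(state.pos[0])] = False
                state.pos[0] = [25, 25, 25]
                state.occ[25, 25, 25] = True
        se = np.sqrt(expected * (1 - expected) / n_trials)
        assert abs(moves / n_trials - expected) < 3 * se


class TestStepAndRun:
    def test_empty_tumor_stays_empty_with_no_sprouts(self):
        cfg = ABMConfig(n_stem_init=0, n_prog_init=0, n_iterations=5, seed=0)
        ts = run_simulation(cfg)
        assert ts.n_cells[-1] == 0
        assert len(ts.final_vessel_points) == 8 * 500  # mature vessels only

    def test_cell_count_ledger_holds_every_iteration(self):
        cfg = ABMConfig(n_iterations=30, seed=9)
        rng = np.random.default_rng(cfg.seed)
        state = initialize(cfg)
        for _ in range(30):
            ledger = step(state, cfg, rng)
            assert ledger["n_after"] == ledger["n_before"] + ledger["divisions"] - ledger["deaths"]

    def test_invariants_preserved_over_run(self):
        cfg = ABMConfig(n_iterations=30, seed=10)
        run_simulation(cfg, check_invariants=True)

    def test_identical_seed_gives_bit_identical_time_series(self):
        cfg = ABMConfig(n_iterations=25, seed=12)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.n_cells, b.n_cells)
        assert np.array_equal(a.cumulative_divisions, b.cumulative_divisions)
        assert np.array_equal(a.final_cell_pos, b.final_cell_pos)
        assert np.array_equal(a.final_vessel_points, b.final_vessel_points)

    def test_record_count_equals_iterations(self):
        cfg = ABMConfig(n_iterations=17, seed=13)
        ts = run_simulation(cfg)
        assert len(ts.n_cells) == 17
        assert np.all(ts.n_hypoxic <= ts.n_cells)
        assert np.all(ts.n_stem <= ts.n_cells)
        assert np.all(np.diff(ts.cumulative_divisions) >= 0)

    def test_aggressive_parameters_grow_larger_tumors(self):
        """Mean final count increases from the low to the high corner of the
        sampled (p_div, div_lim) rectangle."""
        finals = {}
        for p, d in [(0.05, 8), (0.245, 15)]:
            runs = [
                run_simulation(ABMConfig(p_div=p, div_lim=d, n_iterations=80, seed=200 + r))
                for r in range(3)
            ]
            finals[(p, d)] = np.mean([r.n_cells[-1] for r in runs])
        assert finals[(0.245, 15)] > finals[(0.05, 8)]
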