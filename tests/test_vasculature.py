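"""Angiogenesis: sprouting probability, tip chemotaxis, anastomosis, perfusion."""

import numpy as np
import pytest

from smorepars.vasculature import (
    MatureVessel,
    SproutChain,
    Vasculature,
    anastomose,
    initial_vasculature,
    maybe_branch,
    migrate_tips,
    update_perfusion,
)

FINE_UM = 2.0  # 500-site fine lattice over 1 mm
R_VEGF = 200.0
P_MAX = 0.2


def one_segment_vasc():
    pts = np.array([[i, 0, 0] for i in range(500)])
    return Vasculature([MatureVessel(pts[0], pts[-1], pts)])


class TestBranching:
    def test_no_hypoxic_cells_no_sprouts(self):
        vasc = one_segment_vasc()
        new = maybe_branch(vasc, np.empty((0, 3)), R_VEGF, P_MAX, FINE_UM,
                           np.random.default_rng(0))
        assert new == [] and vasc.chains == []

    @pytest.mark.parametrize("dist_um,expected_p", [
        (0.0, P_MAX),
        (100.0, P_MAX * 0.5),
        (200.0, 0.0),
    ])
    def test_branch_frequency_matches_proximity_formula(self, dist_um, expected_p):
        """Monte-Carlo sprout frequency vs max_branch_prob*(1 - d/R)."""
        rng = np.random.default_rng(17)
        hyp = np.array([[250.0, dist_um, 0.0]])  # distance to segment = dist_um
        n_trials = 10_000
        hits = 0
        vasc = one_segment_vasc()
        for _ in range(n_trials):
            vasc.chains = []
            hits += len(maybe_branch(vasc, hyp, R_VEGF, P_MAX, FINE_UM, rng))
        se = np.sqrt(max(expected_p * (1 - expected_p), 1e-9) / n_trials)
        assert abs(hits / n_trials - expected_p) <= 3 * se + 1e-12

    def test_sprout_origin_lies_on_the_segment(self):
        rng = np.random.default_rng(1)
        vasc = one_segment_vasc()
        hyp = np.array([[500.0, 0.0, 0.0]])
        for _ in range(200):
            maybe_branch(vasc, hyp, R_VEGF, P_MAX, FINE_UM, rng)
        assert len(vasc.chains) > 0
        for c in vasc.chains:
            x, y, z = c.points[0]
            assert y == 0 and z == 0 and 0 <= x < 500


class TestTipMigration:
    def test_tip_advances_along_positive_x_toward_cell(self):
        vasc = one_segment_vasc()
        vasc.chains.append(SproutChain(points=[(10, 50, 0)], origin=("mature", 0)))
        cells = np.array([[200, 50, 0]])
        migrate_tips(vasc, cells, tip_speed_um=20.0, fine_spacing_um=FINE_UM,
                     vessel_lattice_n=500)
        tip = vasc.chains[0].tip
        assert tip == (20, 50, 0)  # 10 fine steps due +x

    def test_no_cells_tips_stationary(self):
        vasc = one_segment_vasc()
        vasc.chains.append(SproutChain(points=[(10, 50, 0)], origin=("mature", 0)))
        migrate_tips(vasc, np.empty((0, 3)), 20.0, FINE_UM, 500)
        assert vasc.chains[0].tip == (10, 50, 0)

    def test_equidistant_targets_break_ties_lexicographically(self):
        vasc = one_segment_vasc()
        vasc.chains.append(SproutChain(points=[(100, 100, 100)], origin=("mature", 0)))
        cells = np.array([[100, 100, 160], [100, 160, 100]])  # both 60 away
        migrate_tips(vasc, cells, 20.0, FINE_UM, 500)
        # lexicographically smaller target is (100, 100, 160): move along +z
        assert vasc.chains[0].tip == (100, 100, 110)

    def test_repeat_runs_are_identical(self):
        tips = []
        for _ in range(2):
            vasc = one_segment_vasc()
            vasc.chains.append(SproutChain(points=[(100, 100, 100)], origin=("mature", 0)))
            cells = np.array([[137, 212, 64], [64, 137, 212]])
            for _ in range(5):
                migrate_tips(vasc, cells, 20.0, FINE_UM, 500)
            tips.append(list(vasc.chains[0].points))
        assert tips[0] == tips[1]


def long_chain(start, direction, n, origin=("mature", 0)):
    pts = [tuple(np.asarray(start) + i * np.asarray(direction)) for i in range(n)]
    return SproutChain(points=[tuple(int(v) for v in p) for p in pts], origin=origin)


class TestAnastomosis:
    def test_coincident_tips_fuse_both_chains(self):
        vasc = one_segment_vasc()
        vasc.chains.append(long_chain((100, 100, 0), (0, 1, 0), 30))
        vasc.chains.append(long_chain((100, 158, 0), (0, -1, 0), 30))  # tips meet at y=129/y=100+29
        # both tips at y ~ 129: distance 0
        assert vasc.chains[0].tip == (100, 129, 0)
        assert vasc.chains[1].tip == (100, 129, 0)
        closed = anastomose(vasc, anastomosis_radius_um=20.0, fine_spacing_um=FINE_UM)
        assert closed == [0, 1]
        assert vasc.chains[0].closed and vasc.chains[1].closed

    def test_distant_tips_do_not_fuse(self):
        vasc = one_segment_vasc()
        vasc.chains.append(long_chain((100, 100, 0), (0, 1, 0), 30))
        vasc.chains.append(long_chain((300, 300, 300), (0, 1, 0), 30))
        assert anastomose(vasc, 20.0, FINE_UM) == []

    def test_short_sprouts_are_not_fusion_competent(self):
        vasc = one_segment_vasc()
        vasc.chains.append(SproutChain(points=[(100, 100, 0)], origin=("mature", 0)))
        vasc.chains.append(SproutChain(points=[(100, 101, 0)], origin=("mature", 0)))
        assert anastomose(vasc, 20.0, FINE_UM) == []

    def test_tip_near_stalk_yields_single_connected_component(self):
        """After fusing onto another sprout's stalk the vessel graph is one
        component (verified independently with networkx)."""
        import networkx as nx

        vasc = one_segment_vasc()
        vasc.chains.append(long_chain((100, 0, 0), (0, 1, 0), 60))  # stalk up y
        vasc.chains.append(long_chain((130, 30, 0), (-1, 0, 0), 28))  # tip ends near stalk
        closed = anastomose(vasc, 20.0, FINE_UM)
        assert closed == [1]
        assert vasc.chains[1].target == ("chain", 0)

        g = nx.Graph()
        g.add_node(("mature", 0))
        for j, c in enumerate(vasc.chains):
            g.add_node(("chain", j))
            g.add_edge(("chain", j), c.origin)
            if c.closed:
                g.add_edge(("chain", j), c.target)
        assert nx.number_connected_components(g) == 1


class TestPerfusion:
    def test_open_chain_is_not_perfused(self):
        vasc = one_segment_vasc()
        vasc.chains.append(long_chain((100, 0, 0), (0, 1, 0), 30))
        update_perfusion(vasc)
        assert not vasc.chains[0].perfused

    def test_loop_onto_mature_network_is_perfused(self):
        vasc = one_segment_vasc()
        c = long_chain((100, 0, 0), (0, 1, 0), 30)
        c.closed = True
        c.target = ("mature", 0)
        vasc.chains.append(c)
        update_perfusion(vasc)
        assert vasc.chains[0].perfused

    def test_chain_closing_onto_open_chain_conducts_through_its_stalk(self):
        vasc = one_segment_vasc()
        a = long_chain((100, 0, 0), (0, 1, 0), 60)  # open, origin on mature
        b = long_chain((130, 30, 0), (-1, 0, 0), 28)
        b.closed = True
        b.target = ("chain", 0)
        vasc.chains.extend([a, b])
        update_perfusion(vasc)
        assert not a.perfused  # still open
        assert b.perfused  # loop: mature -> b -> a's stalk -> mature

    def test_random_graphs_match_networkx_connectivity_oracle(self):
        import networkx as nx

        rng = np.random.default_rng(23)
        for _ in range(30):
            n_mat = rng.integers(1, 3)
            mats = []
            for i in range(n_mat):
                pts = np.array([[j, 10 * i, 0] for j in range(50)])
                mats.append(MatureVessel(pts[0], pts[-1], pts))
            vasc = Vasculature(mats)
            n_ch = int(rng.integers(1, 12))
            for j in range(n_ch):
                origin = ("mature", int(rng.integers(n_mat))) if (j == 0 or rng.random() < 0.5) \
                    else ("chain", int(rng.integers(j)))
                c = long_chain((int(rng.integers(200)), int(rng.integers(200)), 0), (0, 0, 1), 3,
                               origin=origin)
                if rng.random() < 0.6:
                    c.closed = True
                    tk = rng.random()
                    if tk < 0.4 or j == 0:
                        c.target = ("mature", int(rng.integers(n_mat)))
                    else:
                        c.target = ("chain", int(rng.integers(j)))
                vasc.chains.append(c)
            update_perfusion(vasc)

            g = nx.Graph()
            for i in range(n_mat):
                g.add_node(("mature", i))
            for j, c in enumerate(vasc.chains):
                g.add_edge(("chain", j), c.origin)
                if c.closed:
                    g.add_edge(("chain", j), c.target)
            mature_reachable = set()
            for i in range(n_mat):
                if ("mature", i) in g:
                    mature_reachable |= nx.node_connected_component(g, ("mature", i))
            for j, c in enumerate(vasc.chains):
                expected = (
                    c.closed
                    and c.origin in mature_reachable
                    and c.target in mature_reachable
                )
                assert vasc.chains[j].perfused == expected, f"chain {j}"

    def test_no_perfused_open_chain_after_update(self):
        vasc = initial_vasculature(500, 8)
        rng = np.random.default_rng(2)
        hyp = rng.uniform(0, 400, (50, 3))
        for _ in range(10):
            maybe_branch(vasc, hyp, R_VEGF, P_MAX, FINE_UM, rng)
            cells = rng.integers(0, 500, (20, 3))
            migrate_tips(vasc, cells, 20.0, FINE_UM, 500)
            anastomose(vasc, 20.0, FINE_UM)
            update_perfusion(vasc)
            for c in vasc.chains:
                assert not (c.perfused and not c.closed)

    def test_segment_count_never_decreases(self):
        vasc = initial_vasculature(500, 8)
        rng = np.random.default_rng(3)
        hyp = rng.uniform(0, 400, (30, 3))
        prev = vasc.n_segments()
        for _ in range(8):
            maybe_branch(vasc, hyp, R_VEGF, P_MAX, FINE_UM, rng)
            cells = rng.integers(0, 500, (15, 3))
            migrate_tips(vasc, cells, 20.0, FINE_UM, 500)
            anastomose(vasc, 20.0, FINE_UM)
            cur = vasc.n_segments()
            assert cur >= prev
            prev = cur
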