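"""Angiogenesis engine: sprouting, tip chemotaxis, anastomosis, perfusion.

The vascular network lives on a fine lattice (10x the tumor-lattice
resolution, matching the smaller calibre of microvessels).  Mature vessels
are straight perfused segments along the boundary faces nearest the initial
tumor.  Hypoxic tumor cells act as VEGF sources: each mature segment with a
hypoxic cell within ``vegf_radius`` may sprout at a random point along it,
with probability scaled linearly by proximity of the nearest hypoxic cell
(``max_branch_prob`` at distance 0, zero at ``vegf_radius``).  Sprout tips
advance toward the nearest cancer cell; a tip coming within
``anastomosis_radius`` of another sprout or a mature segment fuses with it,
closing a loop.  Only loop-closing sprouts carry blood: a sprout chain is
perfused iff it is closed and both its attachment points connect, through the
vessel network, to the mature (perfused) vasculature.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class MatureVessel:
    """One straight, always-perfused vessel: a run of fine-lattice sites."""

    p0: np.ndarray
    p1: np.ndarray
    points: np.ndarray  # (m, 3) int, consecutive sites from p0 to p1


@dataclass
class SproutChain:
    """An angiogenic sprout: ordered fine-lattice sites from origin to tip."""

    points: List[Tuple[int, int, int]]
    origin: Tuple[str, int]  # ("mature", i) or ("chain", j)
    closed: bool = False
    target: Optional[Tuple[str, int]] = None
    perfused: bool = False
    _arr: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def tip(self) -> Tuple[int, int, int]:
        return self.points[-1]

    def as_array(self) -> np.ndarray:
        """Cached (m, 3) int64 view of the chain sites (closed chains freeze)."""
        if self._arr is None or len(self._arr) != len(self.points):
            self._arr = (
                np.array(self.points, dtype=np.int64)
                if self.points else np.empty((0, 3), np.int64)
            )
        return self._arr


class Vasculature:
    """Mature vessels plus sprout chains, with cached point-cloud views."""

    def __init__(self, mature: List[MatureVessel]):
        self.mature = mature
        self.chains: List[SproutChain] = []
        self._mature_points = (
            np.concatenate([m.points for m in mature]) if mature else np.empty((0, 3), int)
        )
        self._mature_owner = np.concatenate(
            [np.full(len(m.points), i) for i, m in enumerate(mature)]
        ) if mature else np.empty(0, int)

    # -- point-cloud views -------------------------------------------------
    def perfused_points(self) -> np.ndarray:
        parts = [self._mature_points]
        parts += [c.as_array() for c in self.chains if c.perfused and c.points]
        return np.concatenate(parts) if parts else np.empty((0, 3), int)

    def all_points(self) -> Tuple[np.ndarray, np.ndarray]:
        """(points, perfused flags) over mature vessels and all chains."""
        pts = [self._mature_points]
        flags = [np.ones(len(self._mature_points), bool)]
        for c in self.chains:
            if c.points:
                pts.append(c.as_array())
                flags.append(np.full(len(c.points), c.perfused))
        return np.concatenate(pts), np.concatenate(flags)

    def n_segments(self) -> int:
        """Total number of unit segments (site-to-site links) in the network."""
        n = sum(max(len(m.points) - 1, 0) for m in self.mature)
        n += sum(max(len(c.points) - 1, 0) + 1 for c in self.chains)  # +1 attachment link
        return n

    def open_tips(self) -> List[int]:
        return [i for i, c in enumerate(self.chains) if not c.closed]


def initial_vasculature(vessel_lattice_n: int, n_vessels: int) -> Vasculature:
    """Straight mature vessels on the three faces adjacent to the tumor corner.

    Candidate lines are taken round-robin over the six (face, direction)
    combinations of the x=0, y=0, z=0 faces, at lateral offsets stepping in
    from the corner (one fifth of the domain, then three fifths, ...).
    """
    vn = vessel_lattice_n
    lines = []
    offsets = [vn // 5 * (2 * k + 1) for k in range(3)]  # 100, 300, 500 um at defaults
    for off in offsets:
        off = min(off, vn - 1)
        # (axis that varies, fixed coords as {axis: value})
        lines.append(("x", {"y": off, "z": 0}))
        lines.append(("y", {"x": off, "z": 0}))
        lines.append(("x", {"y": 0, "z": off}))
        lines.append(("z", {"x": off, "y": 0}))
        lines.append(("y", {"x": 0, "z": off}))
        lines.append(("z", {"x": 0, "y": off}))
    mature = []
    axes = {"x": 0, "y": 1, "z": 2}
    for axis, fixed in lines[:n_vessels]:
        pts = np.zeros((vn, 3), dtype=int)
        pts[:, axes[axis]] = np.arange(vn)
        for k, v in fixed.items():
            pts[:, axes[k]] = v
        mature.append(MatureVessel(pts[0].copy(), pts[-1].copy(), pts))
    return Vasculature(mature)


def _point_segment_distances(points_um: np.ndarray, a_um: np.ndarray, b_um: np.ndarray) -> np.ndarray:
    """Euclidean distances from each point to the segment a-b (all in um)."""
    u = b_um - a_um
    uu = float(u @ u)
    if uu == 0:
        return np.linalg.norm(points_um - a_um, axis=1)
    t = np.clip((points_um - a_um) @ u / uu, 0.0, 1.0)
    proj = a_um + t[:, None] * u
    return np.linalg.norm(points_um - proj, axis=1)


def maybe_branch(
    vasc: Vasculature,
    hypoxic_points_um: np.ndarray,
    vegf_radius: float,
    max_branch_prob: float,
    fine_spacing_um: float,
    rng: np.random.Generator,
) -> List[int]:
    """VEGF-driven sprout initiation; returns ids of newly created chains.

    Branching substrates are the mature segments and — once a sprout loop has
    closed and carries blood — perfused chains, which have functionally
    matured into vasculature (angiogenesis is recursive).  Each hypoxic cell
    is a VEGF source that can recruit at most one sprouting attempt per
    iteration, assigned to its nearest perfused element; an element makes at
    most one attempt per iteration, succeeding with probability
    max_branch_prob * (1 - d_min/vegf_radius), where d_min is the distance to
    the nearest hypoxic cell recruiting it.  The sprout starts at a uniformly
    random site along the element.  Sprouting therefore scales with the
    hypoxic population (tip-cell competition for VEGF) and ceases when
    hypoxia resolves.
    """
    new = []
    if len(hypoxic_points_um) == 0:
        return new

    elements: List[Tuple[Tuple[str, int], np.ndarray]] = [
        (("mature", i), m.points) for i, m in enumerate(vasc.mature)
    ]
    elements += [
        (("chain", j), c.as_array())
        for j, c in enumerate(vasc.chains)
        if c.perfused and c.points
    ]
    all_pts = np.concatenate([pts for _, pts in elements])
    lengths = np.array([len(pts) for _, pts in elements])
    owner = np.repeat(np.arange(len(elements)), lengths)

    # nearest perfused vessel site for every hypoxic cell
    tree = cKDTree(all_pts * fine_spacing_um)
    d, idx = tree.query(hypoxic_points_um, k=1)
    within = d < vegf_radius
    if not np.any(within):
        return new
    recruited: dict = {}
    for dist, site_idx in zip(d[within], idx[within]):
        e = int(owner[site_idx])
        if e not in recruited or dist < recruited[e]:
            recruited[e] = float(dist)

    for e in sorted(recruited):
        d_min = recruited[e]
        p = max_branch_prob * (1.0 - d_min / vegf_radius)
        if rng.random() < p:
            origin, pts = elements[e]
            site = pts[rng.integers(len(pts))]
            vasc.chains.append(
                SproutChain(points=[tuple(int(v) for v in site)], origin=origin)
            )
            new.append(len(vasc.chains) - 1)
    return new


def _discrete_ray(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Successive lattice sites from p (exclusive) to q along the straight line."""
    d = q - p
    n = int(np.max(np.abs(d)))
    if n == 0:
        return np.empty((0, 3), int)
    ts = np.arange(1, n + 1) / n
    sites = np.rint(p + ts[:, None] * d).astype(int)
    keep = np.ones(n, bool)
    keep[1:] = np.any(sites[1:] != sites[:-1], axis=1)
    return sites[keep]


def migrate_tips(
    vasc: Vasculature,
    cell_points_fine: np.ndarray,
    tip_speed_um: float,
    fine_spacing_um: float,
    vessel_lattice_n: int,
) -> None:
    """Advance every open tip toward the nearest cancer cell.

    The tip takes up to tip_speed/fine_spacing unit steps along the discrete
    ray to the nearest cell (squared fine-lattice distance; exact ties broken
    by lowest coordinate-lexicographic order of the cell position), appending
    stalk sites behind it.  No cells -> tips stationary.
    """
    open_ids = vasc.open_tips()
    if not open_ids or len(cell_points_fine) == 0:
        return
    n_steps = max(int(round(tip_speed_um / fine_spacing_um)), 1)
    cells = np.asarray(cell_points_fine, dtype=np.int64)
    # lexicographic rank of each cell position, for deterministic tie-breaks:
    # argmin of d2 * n_cells_pow2 + rank picks min distance, then lowest rank
    order = np.lexsort((cells[:, 2], cells[:, 1], cells[:, 0]))
    rank = np.empty(len(cells), dtype=np.int64)
    rank[order] = np.arange(len(cells))
    pow2 = 1 << int(np.ceil(np.log2(len(cells) + 1)))
    tips = np.array([vasc.chains[ci].tip for ci in open_ids], dtype=np.int64)
    for lo in range(0, len(tips), 64):
        chunk = tips[lo:lo + 64]
        diff = cells[None, :, :] - chunk[:, None, :]
        d2 = np.einsum("tij,tij->ti", diff, diff)
        best = np.argmin(d2 * pow2 + rank[None, :], axis=1)
        for row, ci in enumerate(open_ids[lo:lo + 64]):
            chain = vasc.chains[ci]
            ray = _discrete_ray(chunk[row], cells[best[row]])
            for site in ray[:n_steps]:
                site = np.clip(site, 0, vessel_lattice_n - 1)
                chain.points.append(tuple(int(v) for v in site))


def anastomose(vasc: Vasculature, anastomosis_radius_um: float, fine_spacing_um: float) -> List[int]:
    """Fuse open tips with nearby vasculature; returns ids of newly closed chains.

    A tip within the anastomosis radius of another chain's tip or stalk, or of
    a mature segment, closes its chain onto that element.  A chain's own sites
    are never fusion targets, and a sprout only becomes fusion-competent once
    its stalk is longer than the anastomosis radius (the tip cell must first
    migrate clear of its parent vessel, else every sprout would fuse back at
    birth).
    """
    radius_fine = anastomosis_radius_um / fine_spacing_um
    open_ids = [
        ci for ci in vasc.open_tips() if len(vasc.chains[ci].points) > radius_fine
    ]
    if not open_ids:
        return []

    pts = [vasc._mature_points]
    owner_kind = [np.zeros(len(vasc._mature_points), np.int64)]  # 0 mature, 1 chain
    owner_id = [vasc._mature_owner.astype(np.int64)]
    for j, c in enumerate(vasc.chains):
        arr = c.as_array()
        pts.append(arr)
        owner_kind.append(np.ones(len(arr), np.int64))
        owner_id.append(np.full(len(arr), j, np.int64))
    pts = np.concatenate(pts)
    owner_kind = np.concatenate(owner_kind)
    owner_id = np.concatenate(owner_id)
    tree = cKDTree(pts)

    tips = np.array([vasc.chains[ci].tip for ci in open_ids], dtype=float)
    neighbourhoods = tree.query_ball_point(tips, radius_fine)

    closed_now = []
    for ti, ci in enumerate(open_ids):
        cand = np.asarray(neighbourhoods[ti], dtype=np.intp)
        if len(cand) == 0:
            continue
        chain = vasc.chains[ci]
        p = pts[cand]
        valid = ~((owner_kind[cand] == 1) & (owner_id[cand] == ci))
        if not valid.any():
            continue
        d2 = ((p - tips[ti]) ** 2).sum(axis=1)
        d2[~valid] = np.inf
        idx = cand[int(np.argmin(d2))]
        kind = "mature" if owner_kind[idx] == 0 else "chain"
        chain.closed = True
        chain.target = (kind, int(owner_id[idx]))
        closed_now.append(ci)
    return closed_now


def update_perfusion(vasc: Vasculature) -> None:
    """Mark each chain perfused iff closed with both attachments reaching
    the mature network.

    Connectivity is computed by breadth-first search over the attachment
    graph whose nodes are mature vessels and chains, with an edge for every
    origin or closure attachment (open stalks still conduct the search: a
    loop may close through another sprout's stalk back to a mature vessel).
    """
    n_mat = len(vasc.mature)
    n_ch = len(vasc.chains)
    adj: List[List[int]] = [[] for _ in range(n_mat + n_ch)]

    def node(kind: str, idx: int) -> int:
        return idx if kind == "mature" else n_mat + idx

    for j, c in enumerate(vasc.chains):
        a = node(*c.origin)
        adj[a].append(n_mat + j)
        adj[n_mat + j].append(a)
        if c.closed and c.target is not None:
            b = node(*c.target)
            adj[b].append(n_mat + j)
            adj[n_mat + j].append(b)

    reached = np.zeros(n_mat + n_ch, bool)
    queue = deque(range(n_mat))
    reached[:n_mat] = True
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if not reached[v]:
                reached[v] = True
                queue.append(v)

    for j, c in enumerate(vasc.chains):
        if not c.closed or c.target is None:
            c.perfused = False
            continue
        a_ok = reached[node(*c.origin)]
        b_ok = reached[node(*c.target)]
        c.perfused = bool(a_ok and b_ok)
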