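"""Confidence hypersurfaces of surrogate parameters over ABM parameter space.

Profile-likelihood confidence intervals computed at each sampled
(p_div, div_lim) combination are discrete points on the lower and upper 95%
confidence hypersurfaces of a surrogate parameter.  The surfaces are filled in
by bilinear interpolation on the (irregular) rectangular node grid; no
extrapolation outside the sampled rectangle is permitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator


@dataclass(frozen=True)
class SurfaceNode:
    """Lower/upper 95% bounds of one SM parameter at one ABM grid point."""

    p_div: float
    div_lim: float
    sm_param_name: str
    lower: float
    upper: float
    mle: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.mle <= self.upper):
            raise ValueError(
                f"node at ({self.p_div}, {self.div_lim}) violates lower <= mle <= upper: "
                f"{self.lower}, {self.mle}, {self.upper}"
            )


class UnidentifiableNodeError(ValueError):
    """An open-ended CI cannot seed a surface node; enrich data or grid."""


class OutOfDomainError(ValueError):
    pass


def collect_nodes(
    grid_profiles: Dict[Tuple[float, float], dict],
    sm_param_name: str,
    strict: bool = True,
) -> List[SurfaceNode]:
    """Build surface nodes from per-ABM-combination profile results.

    ``grid_profiles`` maps (p_div, div_lim) to ``{param_name: LikelihoodProfile}``.
    Raises :class:`UnidentifiableNodeError` on any open-ended CI when
    ``strict``; with ``strict=False`` the search-box edge carried by the
    profile stands in for the unbounded side (the surface then states that the
    data do not constrain the parameter beyond the box there).
    """
    nodes = []
    for (p_div, div_lim), profs in grid_profiles.items():
        prof = profs[sm_param_name]
        if strict and (prof.lower_open or prof.upper_open):
            raise UnidentifiableNodeError(
                f"{sm_param_name} CI open-ended at (p_div={p_div}, div_lim={div_lim}); "
                "enrich the ABM data (more replicates/iterations) or the profile grid"
            )
        nodes.append(
            SurfaceNode(p_div, div_lim, sm_param_name, prof.ci_lower, prof.ci_upper, prof.mle)
        )
    return nodes


@dataclass
class ConfidenceSurface:
    """Bilinear lower/upper confidence surfaces over the (p_div, div_lim) rectangle."""

    sm_param_name: str
    p_div_grid: np.ndarray
    div_lim_grid: np.ndarray
    lower_nodes: np.ndarray  # shape (len(p_div_grid), len(div_lim_grid))
    upper_nodes: np.ndarray
    mle_nodes: np.ndarray

    def __post_init__(self) -> None:
        self._lo = RegularGridInterpolator(
            (self.p_div_grid, self.div_lim_grid), self.lower_nodes,
            method="linear", bounds_error=True,
        )
        self._up = RegularGridInterpolator(
            (self.p_div_grid, self.div_lim_grid), self.upper_nodes,
            method="linear", bounds_error=True,
        )

    @property
    def domain(self) -> Tuple[Tuple[float, float], Tuple[float, float]]:
        return (
            (float(self.p_div_grid[0]), float(self.p_div_grid[-1])),
            (float(self.div_lim_grid[0]), float(self.div_lim_grid[-1])),
        )

    def evaluate(self, p_div, div_lim) -> Tuple[np.ndarray, np.ndarray]:
        """Interpolated (lower, upper) bounds at query points (no extrapolation)."""
        pts = np.column_stack([np.ravel(p_div), np.ravel(div_lim)])
        (p0, p1), (d0, d1) = self.domain
        if np.any(pts[:, 0] < p0) or np.any(pts[:, 0] > p1) or \
           np.any(pts[:, 1] < d0) or np.any(pts[:, 1] > d1):
            raise OutOfDomainError(
                f"query outside sampled rectangle [{p0}, {p1}] x [{d0}, {d1}]"
            )
        lo = self._lo(pts)
        up = self._up(pts)
        shape = np.broadcast(np.asarray(p_div), np.asarray(div_lim)).shape
        if shape == ():
            return float(lo[0]), float(up[0])
        return lo.reshape(shape), up.reshape(shape)

    def to_dict(self) -> dict:
        return {
            "sm_param_name": self.sm_param_name,
            "p_div_grid": self.p_div_grid.tolist(),
            "div_lim_grid": self.div_lim_grid.tolist(),
            "lower_nodes": self.lower_nodes.tolist(),
            "upper_nodes": self.upper_nodes.tolist(),
            "mle_nodes": self.mle_nodes.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConfidenceSurface":
        return cls(
            d["sm_param_name"],
            np.asarray(d["p_div_grid"], float),
            np.asarray(d["div_lim_grid"], float),
            np.asarray(d["lower_nodes"], float),
            np.asarray(d["upper_nodes"], float),
            np.asarray(d["mle_nodes"], float),
        )


def build_surface(nodes: Sequence[SurfaceNode]) -> ConfidenceSurface:
    """Assemble a ConfidenceSurface from a complete rectangular node grid.

    Nodes may arrive in any order; every (p_div, div_lim) combination of the
    two axis value sets must be present exactly once.
    """
    if not nodes:
        raise ValueError("no nodes")
    names = {n.sm_param_name for n in nodes}
    if len(names) != 1:
        raise ValueError(f"nodes mix SM parameters: {sorted(names)}")
    p_vals = np.array(sorted({n.p_div for n in nodes}))
    d_vals = np.array(sorted({float(n.div_lim) for n in nodes}))
    if len(p_vals) < 2 or len(d_vals) < 2:
        raise ValueError("need at least 2 distinct values per axis")
    lookup = {(n.p_div, float(n.div_lim)): n for n in nodes}
    if len(lookup) != len(p_vals) * len(d_vals) or len(nodes) != len(lookup):
        raise ValueError(
            f"incomplete or duplicated node grid: {len(nodes)} nodes for "
            f"{len(p_vals)}x{len(d_vals)} rectangle"
        )
    shape = (len(p_vals), len(d_vals))
    lo, up, ml = (np.empty(shape) for _ in range(3))
    for i, p in enumerate(p_vals):
        for j, d in enumerate(d_vals):
            n = lookup[(p, d)]
            lo[i, j], up[i, j], ml[i, j] = n.lower, n.upper, n.mle
    return ConfidenceSurface(nodes[0].sm_param_name, p_vals, d_vals, lo, up, ml)


def save_surfaces(path, surfaces: Dict[str, ConfidenceSurface]) -> None:
    with open(path, "w") as fh:
        json.dump({k: s.to_dict() for k, s in surfaces.items()}, fh, indent=1)


def load_surfaces(path) -> Dict[str, ConfidenceSurface]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: ConfidenceSurface.from_dict(d) for k, d in raw.items()}
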