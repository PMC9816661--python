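"""Data-consistent ABM parameter regions (projection, intersection, union).

A surrogate-parameter value s is *admissible* at an ABM parameter point p if
it lies between the lower and upper confidence surfaces there.  Intersecting
the admissible regions across surrogate parameters gives the ABM region
consistent with one (beta, gamma) choice; the union over all data-admissible
choices — constrained by the identifiable combination — is the region of ABM
parameter space that maps onto the calibration data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .fitting import IdentifiableCombination
from .surfaces import ConfidenceSurface


@dataclass
class ParameterRegion:
    """Boolean admissibility mask over a rectangular (p_div, div_lim) grid."""

    p_div_grid: np.ndarray
    div_lim_grid: np.ndarray
    mask: np.ndarray  # shape (len(p_div_grid), len(div_lim_grid))
    provenance: List[Tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.p_div_grid), len(self.div_lim_grid)):
            raise ValueError("mask shape does not match grids")

    def same_grid(self, other: "ParameterRegion") -> bool:
        return (
            len(self.p_div_grid) == len(other.p_div_grid)
            and len(self.div_lim_grid) == len(other.div_lim_grid)
            and np.allclose(self.p_div_grid, other.p_div_grid)
            and np.allclose(self.div_lim_grid, other.div_lim_grid)
        )

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def area(self) -> float:
        rect = (self.p_div_grid[-1] - self.p_div_grid[0]) * (
            self.div_lim_grid[-1] - self.div_lim_grid[0]
        )
        return self.area_fraction * float(rect)

    def contains(self, p_div: float, div_lim: float) -> bool:
        """Admissibility at the grid point nearest to the query."""
        i = int(np.argmin(np.abs(self.p_div_grid - p_div)))
        j = int(np.argmin(np.abs(self.div_lim_grid - div_lim)))
        return bool(self.mask[i, j])

    def integer_div_lim_points(self) -> np.ndarray:
        """Admissible (p_div, div_lim) points restricted to integer div_lim."""
        pts = []
        for j, d in enumerate(self.div_lim_grid):
            if abs(d - round(d)) < 1e-9:
                for i in np.nonzero(self.mask[:, j])[0]:
                    pts.append((float(self.p_div_grid[i]), int(round(d))))
        return np.array(pts) if pts else np.empty((0, 2))

    def summary(self) -> dict:
        nz = np.nonzero(self.mask)
        box = None
        if len(nz[0]):
            box = {
                "p_div": [float(self.p_div_grid[nz[0].min()]), float(self.p_div_grid[nz[0].max()])],
                "div_lim": [float(self.div_lim_grid[nz[1].min()]), float(self.div_lim_grid[nz[1].max()])],
            }
        return {"area_fraction": self.area_fraction, "area": self.area,
                "bounding_box": box, "provenance": [list(p) for p in self.provenance]}

    def to_csv(self, path) -> None:
        import pandas as pd

        P, D = np.meshgrid(self.p_div_grid, self.div_lim_grid, indexing="ij")
        pd.DataFrame({
            "p_div": P.ravel(), "div_lim": D.ravel(), "admissible": self.mask.ravel().astype(int)
        }).to_csv(path, index=False)


def make_grid(
    surface: ConfidenceSurface, n_p: int = 101, n_d: int = 101
) -> Tuple[np.ndarray, np.ndarray]:
    """Evaluation grid spanning exactly the surface's sampled rectangle."""
    (p0, p1), (d0, d1) = surface.domain
    return np.linspace(p0, p1, n_p), np.linspace(d0, d1, n_d)


def admissible_region(
    surface: ConfidenceSurface,
    s: float,
    grid: Tuple[np.ndarray, np.ndarray],
) -> ParameterRegion:
    """Mask of ABM points where lower(p) <= s <= upper(p)."""
    if not np.isfinite(s):
        raise ValueError("surrogate parameter value must be finite")
    p_grid, d_grid = (np.asarray(g, float) for g in grid)
    P, D = np.meshgrid(p_grid, d_grid, indexing="ij")
    lo, up = surface.evaluate(P, D)
    mask = (lo <= s) & (s <= up)
    return ParameterRegion(p_grid, d_grid, mask, [(surface.sm_param_name, float(s))])


def intersect(regions: Sequence[ParameterRegion]) -> ParameterRegion:
    """Logical AND of admissibility masks on a common grid."""
    return _combine(regions, np.logical_and)


def union(regions: Sequence[ParameterRegion]) -> ParameterRegion:
    """Logical OR of admissibility masks on a common grid."""
    return _combine(regions, np.logical_or)


def _combine(regions: Sequence[ParameterRegion], op) -> ParameterRegion:
    if not regions:
        raise ValueError("no regions to combine")
    first = regions[0]
    mask = first.mask.copy()
    prov = list(first.provenance)
    for r in regions[1:]:
        if not first.same_grid(r):
            raise ValueError("regions are defined on different grids")
        mask = op(mask, r.mask)
        prov.extend(r.provenance)
    return ParameterRegion(first.p_div_grid, first.div_lim_grid, mask, prov)


def infer_data_region(
    beta_surface: ConfidenceSurface,
    gamma_surface: ConfidenceSurface,
    combo: IdentifiableCombination,
    beta_range: Tuple[float, float],
    n_samples: int = 25,
    grid: Tuple[np.ndarray, np.ndarray] | None = None,
) -> ParameterRegion:
    """Experiment-consistent ABM region from sampled (beta, gamma) pairs.

    beta values are sampled evenly across ``beta_range`` (the data-admissible
    95% range), gamma follows from the identifiable combination, and the union
    of the per-pair intersected regions is returned.  Pairs whose gamma falls
    outside the gamma surface simply contribute empty intersections.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if grid is None:
        grid = make_grid(beta_surface)
    betas = np.linspace(beta_range[0], beta_range[1], n_samples)
    pieces = []
    for b in betas:
        g = float(combo(b))
        rb = admissible_region(beta_surface, float(b), grid)
        rg = admissible_region(gamma_surface, g, grid)
        pieces.append(intersect([rb, rg]))
    return union(pieces)


def region_from_pairs(
    beta_surface: ConfidenceSurface,
    gamma_surface: ConfidenceSurface,
    pairs: np.ndarray,
    grid: Tuple[np.ndarray, np.ndarray] | None = None,
) -> ParameterRegion:
    """Union of per-(beta, gamma)-pair intersections for explicit pairs.

    Used when no identifiable combination can be fitted (e.g. gamma is itself
    identifiable) and the admissible pairs are taken straight from the
    below-threshold portion of a profile.
    """
    pairs = np.asarray(pairs, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) == 0:
        raise ValueError("pairs must be a non-empty (m, 2) array")
    if grid is None:
        grid = make_grid(beta_surface)
    pieces = [
        intersect([
            admissible_region(beta_surface, float(b), grid),
            admissible_region(gamma_surface, float(g), grid),
        ])
        for b, g in pairs
    ]
    return union(pieces)
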