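"""Morphology metrics on final tumor/vasculature snapshots.

Implements the end-point comparisons between virtual tumors: farthest-cell
distance from the initial tumor, box-counting fractal dimension of the
vasculature point cloud, tumor surface area and volume from an enclosing
alpha hull after small-component removal, compactness, and Welch two-sample
comparison across replicate simulations.

Compactness uses the dimensionless form

    Comp = (36 pi)^(1/6) * Vol^(1/3) / sqrt(SA)

which equals 1 exactly for a sphere (it is the square root of the classical
sphericity).  The literal variant with SA in place of sqrt(SA) is available
behind a flag for comparison but is not dimensionless.

The enclosing hull is an alpha complex built on scipy's Delaunay
tetrahedralization: tetrahedra with circumradius <= alpha are kept, their
summed volume is the tumor volume, and the once-only boundary triangles give
the surface area.  A convex hull is available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay
from scipy.stats import ttest_ind


@dataclass
class TumorShapeMetrics:
    farthest_distance: float  # um
    fractal_dimension: float
    surface_area: float  # um^2
    volume: float  # um^3
    sa_to_vol: float  # 1/um
    compactness: float


def farthest_cell_distance(points: np.ndarray, origin: np.ndarray, spacing_um: float = 20.0) -> float:
    """Max Euclidean distance (um) from origin over all cell lattice points."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("empty snapshot")
    d = np.linalg.norm((points - np.asarray(origin, float)) * spacing_um, axis=1)
    return float(d.max())


def box_count_dimension(
    points: np.ndarray,
    box_sizes: Optional[Sequence[int]] = None,
    min_points: int = 100,
) -> float:
    """Box-counting (Minkowski) dimension of a 3D occupied-site set.

    ``points`` are integer lattice sites; N(eps) counts occupied eps-boxes for
    dyadic eps, and the dimension is the least-squares slope of log N against
    log(1/eps).  Default sizes are 1, 2, 4, ... up to a quarter of the longest
    bounding-box extent.
    """
    points = np.asarray(points)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (m, 3)")
    pts = np.unique(points, axis=0)
    if len(pts) < max(min_points, 2):
        raise ValueError(f"need at least {max(min_points, 2)} distinct occupied sites, got {len(pts)}")
    pts = pts - pts.min(axis=0)
    extent = int(pts.max())
    if box_sizes is None:
        sizes = []
        s = 1
        while s <= max(extent // 4, 1):
            sizes.append(s)
            s *= 2
        box_sizes = sizes
    box_sizes = sorted(int(s) for s in box_sizes)
    if len(box_sizes) < 4:
        raise ValueError("need at least 4 box sizes; point set too small or sizes too sparse")
    counts = [len(np.unique(pts // s, axis=0)) for s in box_sizes]
    log_eps = np.log(np.asarray(box_sizes, float))
    log_n = np.log(np.asarray(counts, float))
    slope = np.polyfit(log_eps, log_n, 1)[0]
    return float(-slope)


def filter_small_components(
    occupancy: np.ndarray, component_threshold: int = 50
) -> np.ndarray:
    """Remove 26-connected components with voxel count < threshold (strict).

    Eliminates confounding satellite clusters of migrated cells before the
    enclosing-hull computation.  Idempotent.
    """
    structure = np.ones((3, 3, 3), dtype=int)
    labels, n = ndimage.label(occupancy, structure=structure)
    if n == 0:
        return np.zeros_like(occupancy, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes >= component_threshold
    return keep[labels]


def _alpha_complex(points: np.ndarray, alpha: float) -> Tuple[float, float]:
    """(surface area, volume) of the alpha complex of a 3D point cloud."""
    tri = Delaunay(points, qhull_options="QJ")
    tets = tri.points[tri.simplices]  # (m, 4, 3)
    a, b, c, d = tets[:, 0], tets[:, 1], tets[:, 2], tets[:, 3]
    # circumcenter: solve 2 (v_i - a) . x = |v_i|^2 - |a|^2 for each tet
    A = 2.0 * np.stack([b - a, c - a, d - a], axis=1)
    rhs = np.stack(
        [np.einsum("ij,ij->i", v, v) - np.einsum("ij,ij->i", a, a) for v in (b, c, d)],
        axis=1,
    )
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    radius = np.full(len(tets), np.inf)
    if ok.any():
        centers = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
        radius[ok] = np.linalg.norm(centers - a[ok], axis=1)
    # near-degenerate slivers (flat tets between lattice points) have huge
    # circumradii yet tiny extent; excluding them would punch spurious
    # internal boundary faces, so geometrically small tets are kept via a
    # min-enclosing-ball proxy (half the longest edge)
    edges = [b - a, c - a, d - a, c - b, d - b, d - c]
    max_edge = np.max(np.stack([np.linalg.norm(e, axis=1) for e in edges]), axis=0)
    keep = (radius <= alpha) | (max_edge <= 2.0 * alpha)
    if not keep.any():
        raise ValueError("alpha too small: no tetrahedra survive")
    kept = tri.simplices[keep]
    vols = np.abs(np.linalg.det(np.stack([b - a, c - a, d - a], axis=1)[keep])) / 6.0
    volume = float(vols.sum())

    # boundary triangles appear in exactly one kept tetrahedron
    faces = np.concatenate([kept[:, idx] for idx in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))])
    faces = np.sort(faces, axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    p0 = tri.points[boundary[:, 0]]
    e1 = tri.points[boundary[:, 1]] - p0
    e2 = tri.points[boundary[:, 2]] - p0
    area = float(0.5 * np.linalg.norm(np.cross(e1, e2), axis=1).sum())
    return area, volume


def tumor_surface_volume(
    points: np.ndarray,
    component_threshold: int = 50,
    spacing_um: float = 20.0,
    alpha_voxels: float = 3.0,
    method: str = "alpha",
) -> Tuple[float, float]:
    """(surface area um^2, volume um^3) of the hull enclosing the tumor mass.

    Voxels in 26-connected components smaller than ``component_threshold``
    are removed first.  Each surviving voxel contributes its 8 corners (at
    +/- half a voxel around the cell center) so the hull encloses the voxel
    volume rather than the lattice-point skeleton.
    """
    points = np.asarray(points, dtype=int)
    if points.size == 0:
        raise ValueError("empty snapshot")
    mins = points.min(axis=0)
    shifted = points - mins
    occ = np.zeros(shifted.max(axis=0) + 1, dtype=bool)
    occ[tuple(shifted.T)] = True
    kept = filter_small_components(occ, component_threshold)
    if not kept.any():
        raise ValueError(
            f"no component of >= {component_threshold} voxels survives filtering"
        )
    centers = np.argwhere(kept) + mins
    corners = np.array([[i, j, k] for i in (-0.5, 0.5) for j in (-0.5, 0.5) for k in (-0.5, 0.5)])
    cloud = (centers[:, None, :] + corners[None, :, :]).reshape(-1, 3)
    cloud = np.unique(cloud, axis=0) * spacing_um

    if method == "convex":
        hull = ConvexHull(cloud)
        return float(hull.area), float(hull.volume)
    if method != "alpha":
        raise ValueError("method must be 'alpha' or 'convex'")
    return _alpha_complex(cloud, alpha_voxels * spacing_um)


def compactness(surface_area: float, volume: float, literal: bool = False) -> float:
    """Dimensionless shape compactness; 1 for a sphere, < 1 otherwise.

    ``literal=True`` divides by SA instead of sqrt(SA) (the non-dimensionless
    variant); the default form is scale-invariant.
    """
    if not (surface_area > 0 and volume > 0):
        raise ValueError("surface area and volume must be positive")
    pref = (36.0 * np.pi) ** (1.0 / 6.0) * volume ** (1.0 / 3.0)
    return float(pref / surface_area if literal else pref / np.sqrt(surface_area))


def compare_parameter_sets(
    set1_values: Sequence[float], set2_values: Sequence[float]
) -> dict:
    """Replicate summary + Welch two-sample t-test for one end-point metric."""
    x = np.asarray(set1_values, float)
    y = np.asarray(set2_values, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 replicates per parameter set")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        raise ValueError("zero variance in both sets: two-sample test degenerate")
    t, p = ttest_ind(x, y, equal_var=False)
    return {
        "mean1": float(x.mean()), "sd1": float(x.std(ddof=1)),
        "mean2": float(y.mean()), "sd2": float(y.std(ddof=1)),
        "t": float(t), "p_value": float(p),
        "n1": len(x), "n2": len(y),
    }


def snapshot_metrics(
    cell_points: np.ndarray,
    vessel_points: np.ndarray,
    origin: np.ndarray,
    spacing_um: float = 20.0,
    component_threshold: int = 50,
    alpha_voxels: float = 3.0,
    hull_method: str = "alpha",
) -> TumorShapeMetrics:
    """All end-point shape metrics for one final ABM snapshot.

    ``cell_points`` are coarse-lattice cell sites, ``vessel_points`` occupied
    fine-lattice vasculature sites, ``origin`` the iteration-0 tumor centroid
    in coarse-lattice coordinates.
    """
    sa, vol = tumor_surface_volume(
        cell_points, component_threshold, spacing_um, alpha_voxels, hull_method
    )
    return TumorShapeMetrics(
        farthest_distance=farthest_cell_distance(cell_points, origin, spacing_um),
        fractal_dimension=box_count_dimension(vessel_points),
        surface_area=sa,
        volume=vol,
        sa_to_vol=sa / vol,
        compactness=compactness(sa, vol),
    )
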