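"""Weighted least-squares estimation and profile-likelihood uncertainty.

The objective throughout is the weighted sum of squared residuals

    chi^2(p) = sum_i ((z_i - y_i(p)) / sigma_i)^2

where z_i are observed means (ABM replicate averages or tumor volumes),
sigma_i their standard errors, and y_i(p) the surrogate-model trajectory.
Practical identifiability is assessed by profiling: each parameter is fixed
across a grid while the others are re-optimized; the 95% confidence interval
is read off where the profile crosses chi2_min + 3.84 (chi-square 0.95
quantile, 1 df).  A profile that never crosses the threshold on a side marks
that bound as practically unidentifiable (open-ended).

When individual parameters are unidentifiable, the re-optimized nuisance
values harvested along a profile trace out identifiable *combinations*; here a
rational relationship gamma = (beta + a) / (beta + b) is fitted to the
(beta, gamma) pairs from the beta profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .surrogate import MODEL_PARAMS, SMParams, SolverError, solve

SIGMA_FLOOR_FACTOR = 1e-3  # sigma_i floored at this fraction of max(z)
CHI2_95_1DF = 3.84  # chi-square 0.95 quantile, 1 degree of freedom


@dataclass
class GrowthDataset:
    """A mean +/- SE growth time-course (the z_i, sigma_i of the objective)."""

    times: np.ndarray  # strictly increasing; days unless stated otherwise
    z: np.ndarray
    sigma: np.ndarray
    unit: str = "cells"
    provenance: str = "synthetic"  # abm | experimental | synthetic
    time_unit: str = "days"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.times) == len(self.z) == len(sigma)):
            raise ValueError("times, z, sigma must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(sigma < 0):
            raise ValueError("sigma must be non-negative before flooring")
        floor = SIGMA_FLOOR_FACTOR * float(np.max(self.z)) if len(self.z) else 0.0
        self.sigma = np.maximum(sigma, floor)

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time": self.times, "z": self.z, "sigma": self.sigma}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, unit: str = "mm3", provenance: str = "experimental") -> "GrowthDataset":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["time"].values, df["z"].values, df["sigma"].values, unit, provenance)


@dataclass
class FitResult:
    params: SMParams
    chi2: float
    converged: bool
    n_starts: int


@dataclass
class LikelihoodProfile:
    param_name: str
    grid: np.ndarray
    chi2_profile: np.ndarray
    threshold: float
    chi2_min: float
    mle: float
    ci_lower: float  # search-box edge when lower_open (practically unbounded)
    ci_upper: float  # search-box edge when upper_open
    lower_open: bool
    upper_open: bool
    #: re-optimized full parameter vectors at each grid point (canonical order)
    reopt_params: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "param_name": self.param_name,
            "grid": self.grid.tolist(),
            "chi2_profile": self.chi2_profile.tolist(),
            "threshold": self.threshold,
            "chi2_min": self.chi2_min,
            "mle": self.mle,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "lower_open": self.lower_open,
            "upper_open": self.upper_open,
        }


@dataclass
class IdentifiableCombination:
    """Rational identifiable combination gamma = (beta + a) / (beta + b)."""

    a: float
    b: float
    fit_quality: float  # RSS of the rational fit
    beta_range: Tuple[float, float]

    def __call__(self, beta) -> np.ndarray | float:
        beta = np.asarray(beta, dtype=float)
        out = (beta + self.a) / (beta + self.b)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "fit_quality": self.fit_quality,
                "beta_range": list(self.beta_range)}


class FitError(RuntimeError):
    pass


class DegenerateCombinationError(RuntimeError):
    pass


def weighted_ssr(params: SMParams, data: GrowthDataset) -> float:
    """chi^2 = sum_i ((z_i - y_i(params)) / sigma_i)^2."""
    y = solve(params, data.times)
    return float(np.sum(((data.z - y) / data.sigma) ** 2))


def _residuals(theta_log: np.ndarray, model: str, data: GrowthDataset, N0: float) -> np.ndarray:
    names = MODEL_PARAMS[model]
    values = {k: float(np.exp(v)) for k, v in zip(names, theta_log)}
    try:
        y = solve(SMParams(model, values, N0, data.unit), data.times)
    except (SolverError, FloatingPointError, OverflowError):
        return np.full(len(data), 1e8)
    if not np.all(np.isfinite(y)):
        return np.full(len(data), 1e8)
    return np.clip((data.z - y) / data.sigma, -1e8, 1e8)


def default_bounds(model: str, data: GrowthDataset) -> dict:
    """Data-scale-aware log-uniform search bounds per parameter."""
    zmax = float(np.max(data.z))
    if model == "von_bertalanffy":
        return {"alpha": (1e-4, 1e3 * zmax), "gamma": (0.05, 1.8), "beta": (1e-4, 50.0)}
    if model == "generalized_logistic":
        return {"gamma": (1e-4, 50.0), "lam": (0.05, 10.0), "K": (0.5 * zmax, 300.0 * zmax)}
    # generalized Gompertz: plateau ln N = delta/gamma
    return {"lam": (0.05, 3.0), "delta": (1e-4, 1e3), "gamma": (1e-4, 50.0)}


def fit(
    model: str,
    data: GrowthDataset,
    n_starts: int = 20,
    bounds: Optional[dict] = None,
    N0: Optional[float] = None,
    seed: int = 0,
) -> FitResult:
    """Multi-start bounded chi^2 minimization for one growth-law candidate.

    Starts are Latin-hypercube samples over log-uniform parameter boxes; each
    start is refined by trust-region least squares on log-parameters (keeps
    everything positive).  Each model has exactly 3 free parameters: N0 is
    pinned to the recorded initial size (``data.meta["N0"]``, e.g. a known
    inoculum) when present, else to the first observation.
    """
    names = MODEL_PARAMS[model]
    if len(data) <= len(names):
        raise ValueError(f"need more data points ({len(data)}) than parameters ({len(names)})")
    if N0 is None:
        N0 = float(data.meta.get("N0", data.z[0]))
    if N0 <= 0:
        raise ValueError("N0 must be positive; supply N0 explicitly for non-positive z[0]")
    b = dict(default_bounds(model, data))
    if bounds:
        b.update(bounds)
    lo = np.log([b[k][0] for k in names])
    hi = np.log([b[k][1] for k in names])

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)

    best = None
    n_ok = 0
    for x0 in starts:
        try:
            res = least_squares(
                _residuals, x0, bounds=(lo, hi), args=(model, data, N0),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:
            continue
        chi2 = float(2 * res.cost)
        if np.isfinite(chi2):
            n_ok += 1
            if best is None or chi2 < best[0]:
                best = (chi2, res.x)
    if best is None:
        raise FitError(f"all {n_starts} starts failed for {model}")
    values = {k: float(np.exp(v)) for k, v in zip(names, best[1])}
    params = SMParams(model, values, N0, data.unit)
    return FitResult(params=params, chi2=best[0], converged=n_ok > 0, n_starts=n_starts)


# ---------------------------------------------------------------------------
# profile-likelihood engine


def interval_from_profile(
    grid: np.ndarray, chi2: np.ndarray, threshold: float, mle: float
) -> Tuple[float, float, bool, bool]:
    """CI endpoints by linear interpolation at the threshold crossings.

    Walks outward from the MLE on each side; a side whose profile never
    exceeds the threshold is open-ended (endpoint = +/- inf).
    """
    order = np.argsort(grid)
    g, c = np.asarray(grid)[order], np.asarray(chi2)[order]
    i_mle = int(np.argmin(np.abs(g - mle)))

    def cross(side: int) -> Tuple[float, bool]:
        idx = range(i_mle, -1, -1) if side < 0 else range(i_mle, len(g))
        prev = None
        for i in idx:
            if prev is not None and c[prev] <= threshold < c[i]:
                f = (threshold - c[prev]) / (c[i] - c[prev])
                return float(g[prev] + f * (g[i] - g[prev])), False
            prev = i
        return (-np.inf if side < 0 else np.inf), True

    lower, lower_open = cross(-1)
    upper, upper_open = cross(+1)
    return lower, upper, lower_open, upper_open


def profile_generic(
    reopt: Callable[[float, np.ndarray], Tuple[float, np.ndarray]],
    mle_value: float,
    free_mle: np.ndarray,
    chi2_min: float,
    param_name: str = "p",
    grid: Optional[np.ndarray] = None,
    n_grid: int = 41,
    span: float = 10.0,
    max_span: float = 1e4,
    delta: float = CHI2_95_1DF,
    log_scale: bool = True,
    hard_bounds: Optional[Tuple[float, float]] = None,
) -> LikelihoodProfile:
    """Profile one parameter given a re-optimizer over the remaining ones.

    ``reopt(fixed_value, warm_start_free) -> (chi2, free_opt)``.  The default
    grid is ``n_grid`` log-spaced points spanning x/÷ ``span`` around the MLE,
    grown adaptively (up to x/÷ ``max_span``) on any side that has not yet
    crossed the threshold.  ``hard_bounds`` confine the profiled parameter to
    its search box: a side whose profile stays below the threshold up to the
    box edge is flagged practically non-identifiable (open), with the edge
    reported as the interval endpoint.
    """
    if grid is not None:
        grid = np.sort(np.asarray(grid, dtype=float))
        if not (grid[0] <= mle_value <= grid[-1]):
            raise ValueError("grid must bracket the MLE")
        sides = [list(grid[grid < mle_value][::-1]), list(grid[grid > mle_value])]
        adaptive = False
    else:
        if log_scale and mle_value <= 0:
            raise ValueError("log-scale profiling needs a positive MLE value")
        half = (n_grid - 1) // 2
        if log_scale:
            ratios = np.logspace(0, np.log10(span), half + 1)[1:]
            sides = [list(mle_value / ratios), list(mle_value * ratios)]
        else:
            step = np.linspace(0, span, half + 1)[1:]
            sides = [list(mle_value - step), list(mle_value + step)]
        adaptive = True
    if hard_bounds is not None:
        b_lo, b_hi = hard_bounds
        sides[0] = [max(v, b_lo) for v in sides[0]]
        sides[1] = [min(v, b_hi) for v in sides[1]]

    threshold = chi2_min + delta
    pts: List[Tuple[float, float, np.ndarray]] = [(mle_value, chi2_min, np.asarray(free_mle))]

    for s, side in enumerate(sides):
        warm = np.asarray(free_mle)
        crossed = False
        seen = set()
        i = 0
        while i < len(side):
            v = side[i]
            i += 1
            if v in seen:
                continue
            seen.add(v)
            chi2_v, warm = reopt(v, warm)
            pts.append((v, chi2_v, warm))
            crossed = crossed or chi2_v > threshold
            if adaptive and i == len(side) and not crossed:
                last = side[-1]
                at_edge = hard_bounds is not None and (
                    last <= hard_bounds[0] if s == 0 else last >= hard_bounds[1]
                )
                ratio = last / mle_value if s == 1 else mle_value / last
                if log_scale and ratio < max_span and not at_edge:
                    growth = np.logspace(0, np.log10(span) / 2, 5)[1:]
                    ext = last * growth if s == 1 else last / growth
                    if hard_bounds is not None:
                        ext = np.clip(ext, hard_bounds[0], hard_bounds[1])
                    side.extend(ext)
        # open side handled by interval_from_profile

    # refine each threshold crossing by bisection: the first grid point can sit
    # far outside the confidence region, and interpolating across a large chi2
    # jump would badly underestimate the interval
    def refine(side_sign: int) -> None:
        for _ in range(20):
            pts.sort(key=lambda p: p[0])
            g_ = [p[0] for p in pts]
            c_ = [p[1] for p in pts]
            thr = min(chi2_min, min(c_)) + delta
            i_mle = int(np.argmin([abs(v - mle_value) for v in g_]))
            idx = range(i_mle, -1, -1) if side_sign < 0 else range(i_mle, len(g_))
            bracket = None
            prev = None
            for i in idx:
                if prev is not None and c_[prev] <= thr < c_[i]:
                    bracket = (prev, i)
                    break
                prev = i
            if bracket is None:
                return
            a, b = bracket
            va, vb = g_[a], g_[b]
            rel = abs(vb - va) / max(abs(mle_value), abs(va), 1e-300)
            if rel < 2e-3:
                return
            mid = float(np.sqrt(va * vb)) if log_scale and va > 0 else 0.5 * (va + vb)
            chi2_m, warm_m = reopt(mid, np.asarray(pts[a][2] if c_[a] <= thr else pts[b][2]))
            pts.append((mid, chi2_m, warm_m))

    refine(-1)
    refine(+1)

    pts.sort(key=lambda p: p[0])
    g = np.array([p[0] for p in pts])
    c = np.array([p[1] for p in pts])
    free = np.array([p[2] for p in pts])
    chi2_floor = min(chi2_min, float(c.min()))
    threshold = chi2_floor + delta
    lo, up, lo_open, up_open = interval_from_profile(g, c, threshold, mle_value)
    if lo_open:
        lo = float(g.min())  # box edge / grid end: data does not constrain below
    if up_open:
        up = float(g.max())
    return LikelihoodProfile(
        param_name=param_name, grid=g, chi2_profile=c, threshold=threshold,
        chi2_min=chi2_floor, mle=mle_value, ci_lower=lo, ci_upper=up,
        lower_open=lo_open, upper_open=up_open, reopt_params=free,
    )


def profile(
    fit_result: FitResult,
    data: GrowthDataset,
    param_name: str,
    grid: Optional[np.ndarray] = None,
    n_grid: int = 41,
    span: float = 10.0,
    delta: float = CHI2_95_1DF,
    bounds: Optional[dict] = None,
) -> LikelihoodProfile:
    """Profile likelihood of one surrogate-model parameter.

    At each grid value the named parameter is fixed and the remaining ones are
    re-optimized (warm-started from the neighbouring grid point, walking
    outward from the MLE).
    """
    if not fit_result.converged:
        raise FitError("cannot profile a non-converged fit")
    model = fit_result.params.model
    names = MODEL_PARAMS[model]
    if param_name not in names:
        raise ValueError(f"{param_name!r} is not a parameter of {model}")
    i_fix = names.index(param_name)
    i_free = [i for i in range(len(names)) if i != i_fix]
    N0 = fit_result.params.N0

    b = dict(default_bounds(model, data))
    if bounds:
        b.update(bounds)
    lo = np.log([b[names[i]][0] for i in i_free])
    hi = np.log([b[names[i]][1] for i in i_free])

    def reopt(fixed_value: float, warm_free: np.ndarray) -> Tuple[float, np.ndarray]:
        def res_free(x: np.ndarray) -> np.ndarray:
            theta = np.empty(len(names))
            theta[i_fix] = np.log(fixed_value)
            theta[i_free] = x
            return _residuals(theta, model, data, N0)

        x0 = np.clip(warm_free, lo, hi)
        r = least_squares(res_free, x0, bounds=(lo, hi), method="trf",
                          xtol=1e-12, ftol=1e-12, max_nfev=200)
        return float(2 * r.cost), r.x

    theta_mle = np.log(fit_result.params.theta)
    return profile_generic(
        reopt,
        mle_value=float(fit_result.params.values[param_name]),
        free_mle=theta_mle[i_free],
        chi2_min=fit_result.chi2,
        param_name=param_name,
        grid=grid, n_grid=n_grid, span=span, delta=delta,
        hard_bounds=b[param_name],
    )


def profile_pairs(prof: LikelihoodProfile, model: str, below_threshold: bool = True) -> np.ndarray:
    """(fixed, re-optimized gamma) pairs harvested from a beta profile.

    Returns an (m, 2) array of (profiled value, gamma) rows; rows above the
    confidence threshold are dropped when ``below_threshold``.
    """
    if prof.reopt_params is None:
        raise ValueError("profile carries no re-optimized parameters")
    names = MODEL_PARAMS[model]
    free_names = [n for n in names if n != prof.param_name]
    j = free_names.index("gamma")
    gam = np.exp(prof.reopt_params[:, j])
    mask = prof.chi2_profile <= prof.threshold if below_threshold else np.ones(len(gam), bool)
    return np.column_stack([prof.grid[mask], gam[mask]])


def infer_combination(pairs: np.ndarray) -> IdentifiableCombination:
    """Fit gamma = (beta + a) / (beta + b) to (beta, gamma) profile pairs.

    The form is linear in (a, b) after clearing the denominator
    (a - gamma*b = beta*(gamma - 1)), so a linear solve seeds a nonlinear
    refinement on the gamma residuals.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 4:
        raise ValueError("need >= 4 (beta, gamma) pairs")
    beta, gamma = pairs[:, 0], pairs[:, 1]
    if np.ptp(gamma) < 1e-6 * max(1.0, abs(float(np.mean(gamma)))):
        raise DegenerateCombinationError("gamma is (near-)constant along the profile")

    A = np.column_stack([np.ones_like(gamma), -gamma])
    rhs = beta * (gamma - 1.0)
    (a0, b0), *_ = np.linalg.lstsq(A, rhs, rcond=None)

    def res(x: np.ndarray) -> np.ndarray:
        a, b = x
        return (beta + a) / (beta + b) - gamma

    r = least_squares(res, [a0, b0], method="lm", xtol=1e-15, ftol=1e-15)
    a, b = r.x
    if np.any(np.abs(beta + b) < 1e-12):
        raise DegenerateCombinationError("fitted pole lies inside the beta range")
    return IdentifiableCombination(
        a=float(a), b=float(b), fit_quality=float(np.sum(res(r.x) ** 2)),
        beta_range=(float(beta.min()), float(beta.max())),
    )


def save_fit_json(path, fit_result: FitResult, profiles: Sequence[LikelihoodProfile] = ()) -> None:
    payload = {
        "model": fit_result.params.model,
        "values": fit_result.params.values,
        "N0": fit_result.params.N0,
        "unit": fit_result.params.unit,
        "chi2": fit_result.chi2,
        "converged": fit_result.converged,
        "n_starts": fit_result.n_starts,
        "profiles": [p.to_dict() for p in profiles],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
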