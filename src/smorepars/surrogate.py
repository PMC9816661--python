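"""Candidate surrogate growth laws and information-criterion model selection.

Three classical bulk tumor-growth ODEs are supported as surrogate-model (SM)
candidates:

* generalized Gompertz   dN/dt = N^lambda (delta - gamma ln N)
* generalized logistic   dN/dt = gamma N (1 - (N/K)^lambda)
* von Bertalanffy (vB)   dN/dt = alpha N^gamma - beta N

The vB equation is a Bernoulli ODE for gamma != 1 and has the exact solution

    N(t)^(1-gamma) = alpha/beta + (N0^(1-gamma) - alpha/beta) exp(-beta (1-gamma) t)

which is used as the default fast evaluation path; an adaptive ODE solver is
available behind ``method="numerical"`` and is cross-checked against the closed
form in the test suite.  Model comparison uses the Gaussian concentrated-
likelihood forms AIC = n ln(RSS/n) + 2k and BIC = n ln(RSS/n) + k ln n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

MODELS = ("generalized_gompertz", "generalized_logistic", "von_bertalanffy")

#: free parameters of each growth law, in canonical order
MODEL_PARAMS: Dict[str, Tuple[str, ...]] = {
    "generalized_gompertz": ("lam", "delta", "gamma"),
    "generalized_logistic": ("gamma", "lam", "K"),
    "von_bertalanffy": ("alpha", "gamma", "beta"),
}

_GAMMA_ONE_TOL = 1e-6  # vB gamma this close to 1 routes to the exponential limit


@dataclass
class SMParams:
    """Parameter vector of one surrogate growth law.

    ``values`` maps parameter names (see :data:`MODEL_PARAMS`) to positive
    reals; ``N0`` is the initial size in the tagged unit (``cells`` for ABM
    output, ``mm3`` for xenograft-style volumes).
    """

    model: str
    values: Dict[str, float]
    N0: float
    unit: str = "cells"
    #: alternate reading of the generalized-Gompertz nonlinearity
    #: (lambda*N instead of N^lambda); off by default
    gg_linear_in_N: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.unit not in ("cells", "mm3"):
            raise ValueError(f"unit must be 'cells' or 'mm3', got {self.unit!r}")
        missing = set(MODEL_PARAMS[self.model]) - set(self.values)
        if missing:
            raise ValueError(f"missing parameters for {self.model}: {sorted(missing)}")
        for name in MODEL_PARAMS[self.model]:
            if not self.values[name] > 0:
                raise ValueError(f"parameter {name} must be > 0, got {self.values[name]}")
        if not self.N0 > 0:
            raise ValueError("N0 must be > 0")

    @property
    def theta(self) -> np.ndarray:
        """Free parameters as an array in canonical order."""
        return np.array([self.values[k] for k in MODEL_PARAMS[self.model]])

    def replace(self, **updates: float) -> "SMParams":
        vals = dict(self.values)
        n0 = updates.pop("N0", self.N0)
        vals.update(updates)
        return SMParams(self.model, vals, n0, self.unit, self.gg_linear_in_N)


@dataclass
class ModelScore:
    """Goodness-of-fit summary for one candidate on one (or pooled) dataset."""

    model: str
    rss: float
    n: int
    k: int
    aic: float
    bic: float
    dataset: str = ""
    degenerate: bool = False


def rhs(params: SMParams, N) -> np.ndarray | float:
    """Right-hand side dN/dt of the growth law at size ``N`` (scalar or array)."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("N must be non-negative")
    v = params.values
    if params.model == "von_bertalanffy":
        out = v["alpha"] * N ** v["gamma"] - v["beta"] * N
    elif params.model == "generalized_logistic":
        out = v["gamma"] * N * (1.0 - (N / v["K"]) ** v["lam"])
    else:  # generalized Gompertz; dN/dt -> 0 as N -> 0+
        with np.errstate(divide="ignore", invalid="ignore"):
            if params.gg_linear_in_N:
                growth = v["lam"] * N * (v["delta"] - v["gamma"] * np.log(N))
            else:
                growth = N ** v["lam"] * (v["delta"] - v["gamma"] * np.log(N))
        out = np.where(N > 0, growth, 0.0)
    return float(out) if out.ndim == 0 else out


def vb_closed_form(alpha: float, gamma: float, beta: float, N0: float, times) -> np.ndarray:
    """Exact von Bertalanffy trajectory (Bernoulli substitution u = N^(1-gamma)).

    For ``|1-gamma|`` below the degeneracy tolerance the exponential limit
    ``N0 exp((alpha-beta) t)`` is returned.
    """
    t = np.asarray(times, dtype=float)
    if abs(1.0 - gamma) < _GAMMA_ONE_TOL:
        return N0 * np.exp(np.clip((alpha - beta) * t, -700, 700))
    e = 1.0 - gamma
    ab = alpha / beta
    with np.errstate(over="ignore", invalid="ignore"):
        u = ab + (N0**e - ab) * np.exp(np.clip(-beta * e * t, -700, 700))
        # u stays positive for positive params/N0; clip guards roundoff at the fixed point
        out = np.clip(u, 1e-300, None) ** (1.0 / e)
    return np.nan_to_num(out, nan=np.inf, posinf=np.inf)


def gl_closed_form(gamma: float, lam: float, K: float, N0: float, times) -> np.ndarray:
    """Exact generalized-logistic trajectory via u = (N/K)^lambda (plain logistic)."""
    t = np.asarray(times, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        u0 = (N0 / K) ** lam
        u = u0 / (u0 + (1.0 - u0) * np.exp(np.clip(-gamma * lam * t, -700, 700)))
        out = K * np.clip(u, 1e-300, None) ** (1.0 / lam)
    return np.nan_to_num(out, nan=np.inf, posinf=np.inf)


class SolverError(RuntimeError):
    """ODE integration failure, carrying the offending parameters."""


def solve(params: SMParams, times, method: str = "auto") -> np.ndarray:
    """Trajectory N(t) at the requested times (times[0] corresponds to N0).

    ``method="auto"`` uses the exact closed form where one exists (vB,
    generalized logistic) and the ODE solver otherwise; ``"numerical"`` forces
    the adaptive solver (LSODA, rtol 1e-8 / atol 1e-10).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a non-empty strictly increasing 1-D array")
    v = params.values
    if method == "auto":
        # closed forms are anchored at zero; shift so N(times[0]) = N0, the
        # same convention as the initial-value integrator
        if params.model == "von_bertalanffy":
            return vb_closed_form(v["alpha"], v["gamma"], v["beta"], params.N0, t - t[0])
        if params.model == "generalized_logistic":
            return gl_closed_form(v["gamma"], v["lam"], v["K"], params.N0, t - t[0])
    elif method != "numerical":
        raise ValueError(f"method must be 'auto' or 'numerical', got {method!r}")

    t0 = t[0]
    t_span = (t0, t[-1]) if len(t) > 1 else (t0, t0 + 1e-9)
    if params.model == "generalized_gompertz" and method != "numerical":
        return _gg_solve(params, t, t_span)
    sol = solve_ivp(
        lambda tt, y: [rhs(params, max(y[0], 0.0))],
        t_span,
        [params.N0],
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise SolverError(f"ODE solve failed for {params.model} with {v}: {sol.message}")
    return np.clip(sol.y[0], 1e-300, None)


_GG_LOG_CAP = 60.0  # stop integrating once ln N exceeds this (divergent draw)


def _gg_solve(params: SMParams, t: np.ndarray, t_span) -> np.ndarray:
    """Generalized-Gompertz trajectory integrated in u = ln N.

    The u-space form du/dt = e^((lam-1)u) (delta - gamma u) (or
    lam (delta - gamma u) for the linear-in-N variant) is far better
    conditioned than N-space for exploratory parameter draws; a terminal
    event truncates divergent trajectories instead of letting the solver
    grind, and truncated tails are reported as +inf.
    """
    v = params.values
    lam, delta, gamma = v["lam"], v["delta"], v["gamma"]

    if params.gg_linear_in_N:
        du = lambda tt, u: [lam * (delta - gamma * u[0])]
    else:
        du = lambda tt, u: [np.exp(min((lam - 1.0) * u[0], 700.0)) * (delta - gamma * u[0])]

    blowup = lambda tt, u: u[0] - _GG_LOG_CAP
    blowup.terminal = True
    blowup.direction = 1.0
    sol = solve_ivp(du, t_span, [np.log(params.N0)], t_eval=t, method="LSODA",
                    rtol=1e-8, atol=1e-10, events=blowup)
    if not sol.success:
        raise SolverError(f"ODE solve failed for generalized_gompertz with {v}: {sol.message}")
    out = np.full(len(t), np.inf)
    out[: len(sol.t)] = np.exp(np.clip(sol.y[0], -700, 700))
    return out


def information_criteria(rss: float, n: int, k: int, model: str = "", dataset: str = "") -> ModelScore:
    """AIC/BIC from residual sum of squares (Gaussian concentrated likelihood)."""
    if not (n > k >= 1):
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        # degenerate perfect fit: criteria diverge to -inf
        return ModelScore(model, 0.0, n, k, -np.inf, -np.inf, dataset, degenerate=True)
    base = n * np.log(rss / n)
    return ModelScore(model, rss, n, k, base + 2 * k, base + k * np.log(n), dataset)


def relative_likelihood_log(aic_best: float, aic_other: float) -> float:
    """log of exp((AIC_best - AIC_other)/2), the Akaike relative likelihood."""
    return (aic_best - aic_other) / 2.0


def select_model(scores: Iterable[ModelScore]) -> Tuple[str, List[ModelScore]]:
    """Rank fitted candidates by AIC; returns (best model id, sorted scores).

    For multi-dataset candidates pass pooled scores (summed RSS and n, summed
    k) — one ModelScore per candidate.  Ties keep input order (stable sort).
    """
    ranked = sorted(scores, key=lambda s: s.aic)
    if len(ranked) < 2:
        raise ValueError("need at least two candidate scores")
    return ranked[0].model, ranked


def pooled_score(model: str, per_dataset: Sequence[ModelScore]) -> ModelScore:
    """Aggregate per-dataset fits of one candidate: RSS, n and k summed."""
    if not per_dataset:
        raise ValueError("no per-dataset scores")
    rss = float(sum(s.rss for s in per_dataset))
    n = int(sum(s.n for s in per_dataset))
    k = int(sum(s.k for s in per_dataset))
    return information_criteria(rss, n, k, model=model, dataset="pooled")


def scores_to_frame(scores: Sequence[ModelScore]):
    """Model-score table with columns model,dataset,rss,n,k,aic,bic."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"model": s.model, "dataset": s.dataset, "rss": s.rss, "n": s.n,
             "k": s.k, "aic": s.aic, "bic": s.bic}
            for s in scores
        ]
    )
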