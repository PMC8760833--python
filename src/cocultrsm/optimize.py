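"""Locating optima on fitted response surfaces.

Single-response maximization runs seeded multistart local optimization
over the coded design region (the factorial cube by default, a sphere of
radius alpha optionally).  Multiresponse optimization follows the
Derringer–Suich desirability approach: each predicted response is mapped
through a one-sided transform ``d_i`` in [0, 1] and the weighted geometric
mean ``D = (prod d_i**w_i)**(1/sum w_i)`` is maximized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .doe import FactorSpec, decode_levels
from .errors import (
    ConfigurationError,
    DegenerateGoalError,
    DimensionError,
    InvalidParameterError,
    NumericError,
)
from .models import PolynomialModel

__all__ = [
    "Region",
    "DesirabilityGoal",
    "OptimizationResult",
    "evaluate",
    "maximize_response",
    "desirability_transform",
    "global_desirability",
    "maximize_desirability",
    "export_surface_grid",
]


@dataclass(frozen=True)
class Region:
    """Optimization domain in coded units: a cube of half-width ``bound``
    or a sphere of radius ``bound`` centered at the origin."""

    kind: str = "cube"
    bound: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("cube", "sphere"):
            raise InvalidParameterError(f"unknown region kind {self.kind!r}")
        if self.bound <= 0:
            raise InvalidParameterError("region bound must be > 0")

    def contains(self, x, tol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        if self.kind == "cube":
            return bool(np.all(np.abs(x) <= self.bound + tol))
        return float(np.linalg.norm(x)) <= self.bound + tol

    def sample(self, rng: np.random.Generator, n: int, k: int) -> np.ndarray:
        if self.kind == "cube":
            return rng.uniform(-self.bound, self.bound, size=(n, k))
        # uniform in the ball: direction * radius with r ~ U^(1/k)
        v = rng.normal(size=(n, k))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = self.bound * rng.uniform(size=(n, 1)) ** (1.0 / k)
        return v * r


@dataclass(frozen=True)
class DesirabilityGoal:
    """One-sided maximize goal: 0 below ``y_min``, 1 above ``y_max``,
    ``((y - y_min)/(y_max - y_min))**r`` in between; weight ``w`` sets the
    response's importance in the global score."""

    response_name: str
    y_min: float
    y_max: float
    r: float = 1.0
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.y_max <= self.y_min:
            raise DegenerateGoalError(
                f"goal {self.response_name!r}: y_max must exceed y_min"
            )
        if self.r <= 0 or self.w <= 0:
            raise InvalidParameterError("r and w must be > 0")


@dataclass
class OptimizationResult:
    coded_point: np.ndarray
    predicted: dict[str, float]
    natural_point: np.ndarray | None = None
    d_values: dict[str, float] = field(default_factory=dict)
    d_global: float | None = None
    n_restarts_converged: int = 0
    degenerate: bool = False


def evaluate(model: PolynomialModel, coded_point) -> float:
    """Predicted response at one coded point: ``sum_j beta_j prod_i x_i**e_ij``."""
    x = np.asarray(coded_point, dtype=float)
    if x.ndim != 1 or x.shape[0] != model.k:
        raise DimensionError(f"point has shape {x.shape}, model expects ({model.k},)")
    return float(model.predict(x))


def _multistart_maximize(objective, k, region, n_restarts, seed, extra_starts=()):
    """Seeded multistart local maximization; returns (x*, f*, n_converged)."""
    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    starts.extend(region.sample(rng, n_restarts, k))

    def neg(x):
        v = objective(x)
        if not np.isfinite(v):
            raise NumericError("objective produced a non-finite value")
        return -v

    if region.kind == "cube":
        kwargs = {"method": "L-BFGS-B", "bounds": [(-region.bound, region.bound)] * k}
    else:
        kwargs = {
            "method": "SLSQP",
            "constraints": [
                {
                    "type": "ineq",
                    "fun": lambda x: region.bound**2 - float(x @ x),
                }
            ],
        }

    best_x, best_f, n_ok = None, -np.inf, 0
    for x0 in starts:
        res = minimize(neg, x0, tol=1e-9, **kwargs)
        if not np.isfinite(res.fun):
            continue
        if res.success:
            n_ok += 1
        f = -float(res.fun)
        x = np.asarray(res.x)
        if not region.contains(x, tol=1e-6):
            if region.kind == "cube":
                x = np.clip(x, -region.bound, region.bound)
                f = objective(x)
            else:
                continue  # SLSQP wandered infeasible (e.g. unbounded cubic)
        # prefer higher value; among ties prefer the point closer to the origin
        if f > best_f + 1e-9 or (
            abs(f - best_f) <= 1e-9
            and best_x is not None
            and np.linalg.norm(x) < np.linalg.norm(best_x)
        ):
            best_x, best_f = x, f
    if best_x is None:
        raise NumericError("no optimization start converged to a finite value")
    return best_x, best_f, n_ok


def maximize_response(
    model: PolynomialModel,
    region: Region = Region(),
    n_restarts: int = 50,
    seed: int = 0,
    factors: list[FactorSpec] | None = None,
) -> OptimizationResult:
    """Maximize one fitted response over the coded region by multistart
    local optimization; reproducible for a fixed seed."""
    if n_restarts < 1:
        raise InvalidParameterError("n_restarts must be >= 1")
    x, f, n_ok = _multistart_maximize(
        lambda z: model.predict(z), model.k, region, n_restarts, seed
    )
    return OptimizationResult(
        coded_point=x,
        predicted={model.response_name: f},
        natural_point=decode_levels(x, factors) if factors else None,
        n_restarts_converged=n_ok,
    )


def desirability_transform(y_hat: float, goal: DesirabilityGoal) -> float:
    """Map a predicted response into [0, 1] via the one-sided transform."""
    span = goal.y_max - goal.y_min
    t = np.clip((np.asarray(y_hat, dtype=float) - goal.y_min) / span, 0.0, 1.0)
    out = t**goal.r
    return float(out) if np.ndim(y_hat) == 0 else out


def global_desirability(d_values, weights) -> float:
    """Weighted geometric mean ``(prod d_i**w_i)**(1/sum w_i)``; any zero
    desirability annihilates the product."""
    d = np.asarray(d_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise DimensionError("d_values and weights must have equal length")
    if np.any((d < 0) | (d > 1)):
        raise InvalidParameterError("desirabilities must lie in [0, 1]")
    if np.any(w <= 0):
        raise InvalidParameterError("weights must be > 0")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


def maximize_desirability(
    models: list[PolynomialModel],
    goals: list[DesirabilityGoal],
    region: Region = Region(),
    n_restarts: int = 50,
    seed: int = 0,
    factors: list[FactorSpec] | None = None,
) -> OptimizationResult:
    """Maximize the global desirability of several responses jointly.

    The objective is piecewise-smooth (flat wherever a response saturates
    its goal), so a deterministic coarse grid of starting points supplements
    the seeded random restarts.  A landscape where the best achievable D is
    0 is flagged ``degenerate``.
    """
    if len(models) != len(goals):
        raise DimensionError("one goal per model required")
    k = models[0].k
    if any(m.k != k for m in models):
        raise DimensionError("models disagree on factor count")
    by_name = {g.response_name for g in goals}
    if len(by_name) != len(goals):
        raise InvalidParameterError("duplicate response names in goals")
    w = np.array([g.w for g in goals])

    def objective(x):
        d = np.array(
            [desirability_transform(m.predict(x), g) for m, g in zip(models, goals)]
        )
        if np.any(d == 0):
            return 0.0
        return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))

    grid_1d = np.linspace(-region.bound, region.bound, 5)
    mesh = np.stack(np.meshgrid(*([grid_1d] * k)), axis=-1).reshape(-1, k)
    if region.kind == "sphere":
        mesh = mesh[np.linalg.norm(mesh, axis=1) <= region.bound]

    x, f, n_ok = _multistart_maximize(
        objective, k, region, n_restarts, seed, extra_starts=mesh
    )
    predicted = {m.response_name: float(m.predict(x)) for m in models}
    d_values = {
        g.response_name: desirability_transform(predicted[g.response_name], g)
        for g in goals
    }
    degenerate = f <= 0.0
    if degenerate:
        warnings.warn(
            "global desirability is 0 everywhere searched: degenerate landscape",
            stacklevel=2,
        )
    return OptimizationResult(
        coded_point=x,
        predicted=predicted,
        natural_point=decode_levels(x, factors) if factors else None,
        d_values=d_values,
        d_global=f,
        n_restarts_converged=n_ok,
        degenerate=degenerate,
    )


def export_surface_grid(
    model: PolynomialModel,
    fixed: dict[int | str, float],
    grid_resolution: int = 41,
    bound: float = 1.0,
    factor_names: list[str] | None = None,
) -> pd.DataFrame:
    """Tabulate a 2-D slice of the surface for contour/surface plotting.

    ``fixed`` pins ``k - 2`` factors (by index or name) at coded values;
    the remaining two sweep ``[-bound, bound]`` on a ``grid_resolution``²
    lattice.  Returns a tidy table with one row per grid node.
    """
    k = model.k
    if factor_names is None:
        factor_names = [chr(ord("A") + i) for i in range(k)]
    fixed_idx: dict[int, float] = {}
    for key, val in fixed.items():
        i = key if isinstance(key, int) else factor_names.index(key)
        fixed_idx[i] = float(val)
    free = [i for i in range(k) if i not in fixed_idx]
    if len(free) != 2:
        raise ConfigurationError(
            f"exactly 2 free factors required, got {len(free)} (fix the rest)"
        )
    axis = np.linspace(-bound, bound, grid_resolution)
    g1, g2 = np.meshgrid(axis, axis, indexing="ij")
    pts = np.empty((grid_resolution**2, k))
    for i, v in fixed_idx.items():
        pts[:, i] = v
    pts[:, free[0]] = g1.ravel()
    pts[:, free[1]] = g2.ravel()
    return pd.DataFrame(
        {
            factor_names[free[0]]: pts[:, free[0]],
            factor_names[free[1]]: pts[:, free[1]],
            model.response_name: model.predict(pts),
        }
    )
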