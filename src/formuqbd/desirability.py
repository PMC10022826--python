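"""Multi-response desirability optimization over a mixture region.

Each response is mapped to [0, 1] by a linear Derringer-Suich ramp and
the per-response values are combined by a weighted geometric mean.  The
optimal composition is located by seeding a fine grid over the two free
simplex dimensions and polishing the best seeds with a local simplex
search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .mixture_design import MixtureConstraints, ResponseModel, predict

__all__ = [
    "DesirabilityGoal",
    "desirability_value",
    "overall_desirability",
    "optimize_composition",
    "paper_goals",
]

Goal = Literal["minimize", "maximize", "in_range", "target"]


@dataclass(frozen=True)
class DesirabilityGoal:
    """Optimization goal for one response.

    ``lower`` / ``upper`` are the scaling bounds in response units (by
    convention the observed response range); ``weight`` the importance
    (1-5); ``target`` only used by the target goal.
    """

    response: str
    goal: Goal
    lower: float
    upper: float
    weight: float = 1.0
    target: float | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("scaling bounds must satisfy lower < upper")
        if self.weight < 1:
            raise ValueError("importance weight must be >= 1")
        if self.goal == "target" and self.target is None:
            raise ValueError("target goal requires a target value")


def desirability_value(goal: DesirabilityGoal, y: float) -> float:
    """Linear desirability ramp d(y) in [0, 1]."""
    L, U = goal.lower, goal.upper
    if goal.goal == "minimize":
        if y <= L:
            return 1.0
        if y >= U:
            return 0.0
        return (U - y) / (U - L)
    if goal.goal == "maximize":
        if y <= L:
            return 0.0
        if y >= U:
            return 1.0
        return (y - L) / (U - L)
    if goal.goal == "in_range":
        return 1.0 if L <= y <= U else 0.0
    if goal.goal == "target":
        t = goal.target
        if y <= L or y >= U:
            return 0.0
        return (y - L) / (t - L) if y <= t else (U - y) / (U - t)
    raise ValueError(f"unknown goal {goal.goal!r}")


def overall_desirability(
    d_values: Sequence[float],
    weights: Sequence[float],
    in_range_mask: Sequence[bool] | None = None,
    exclude_satisfied_in_range: bool = True,
) -> float:
    """Weighted geometric mean D = (prod d_i^w_i)^(1/sum w_i).

    With ``exclude_satisfied_in_range`` (default), an in-range goal whose
    d equals 1 drops out of the weight sum, mirroring the behaviour of
    common DOE software; set False for strict inclusion.
    """
    d = np.asarray(d_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("desirability values must lie in [0, 1]")
    if in_range_mask is not None and exclude_satisfied_in_range:
        mask = np.asarray(in_range_mask, dtype=bool) & (d >= 1.0)
        d, w = d[~mask], w[~mask]
    if len(d) == 0:
        return 1.0
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


def paper_goals() -> list[DesirabilityGoal]:
    """The five-response optimization criteria for the gastroretentive
    blend: minimize floating lag-time, maximize total floating time,
    minimize 1-h release, keep 12-h release in range, maximize 24-h
    release, scaled to the observed response ranges."""
    return [
        DesirabilityGoal("lag_time_s", "minimize", 18.0, 60.0, weight=5),
        DesirabilityGoal("float_time_h", "maximize", 15.5, 22.0, weight=4),
        DesirabilityGoal("release_1h_pct", "minimize", 13.23, 28.33, weight=3),
        DesirabilityGoal("release_12h_pct", "in_range", 71.58, 87.7, weight=3),
        DesirabilityGoal("release_24h_pct", "maximize", 96.01, 100.15, weight=3),
    ]


def _score(
    x12: np.ndarray,
    models: dict[str, ResponseModel],
    goals: Sequence[DesirabilityGoal],
    constraints: MixtureConstraints,
    exclude_satisfied_in_range: bool,
) -> float:
    x1, x2 = x12
    x3 = constraints.total - x1 - x2
    comp = (x1, x2, x3)
    if not constraints.contains(comp, tol=1e-9):
        return -1.0
    d_vals, weights, mask = [], [], []
    for g in goals:
        y = predict(models[g.response], comp)
        d_vals.append(desirability_value(g, y))
        weights.append(g.weight)
        mask.append(g.goal == "in_range")
    return overall_desirability(
        d_vals, weights, mask, exclude_satisfied_in_range
    )


def optimize_composition(
    models: dict[str, ResponseModel],
    goals: Sequence[DesirabilityGoal],
    constraints: MixtureConstraints | None = None,
    seed: int = 0,
    grid_step: float = 0.5,
    n_polish: int = 10,
    exclude_satisfied_in_range: bool = True,
) -> tuple[tuple[float, float, float], float, dict[str, float]]:
    """Locate the composition maximizing overall desirability.

    A grid at ``grid_step``-percent resolution over the two free simplex
    dimensions seeds a Nelder-Mead polish of the best points.  Returns
    (composition, D, predicted responses); raises if D is zero
    everywhere on the grid.
    """
    if constraints is None:
        constraints = MixtureConstraints()
    missing = [g.response for g in goals if g.response not in models]
    if missing:
        raise KeyError(f"no fitted model for goals: {missing}")

    lo, hi = constraints.lower, constraints.upper
    x1g = np.arange(lo[0], hi[0] + grid_step / 2, grid_step)
    x2g = np.arange(lo[1], hi[1] + grid_step / 2, grid_step)
    scored: list[tuple[float, tuple[float, float]]] = []
    for x1 in x1g:
        for x2 in x2g:
            x3 = constraints.total - x1 - x2
            if not (lo[2] - 1e-9 <= x3 <= hi[2] + 1e-9):
                continue
            D = _score(
                np.array([x1, x2]), models, goals, constraints,
                exclude_satisfied_in_range,
            )
            scored.append((D, (float(x1), float(x2))))
    if not scored:
        raise ValueError("empty feasible grid")
    scored.sort(key=lambda t: (-t[0], t[1]))
    if scored[0][0] <= 0.0:
        raise ValueError("no feasible optimum: desirability is zero everywhere")

    best_D, best_x12 = scored[0]
    for _, x12 in scored[:n_polish]:
        res = optimize.minimize(
            lambda z: -_score(
                z, models, goals, constraints, exclude_satisfied_in_range
            ),
            x0=np.array(x12),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
        )
        if -res.fun > best_D:
            best_D, best_x12 = -res.fun, tuple(res.x)

    x1, x2 = best_x12
    comp = (float(x1), float(x2), float(constraints.total - x1 - x2))
    preds = {g.response: predict(models[g.response], comp) for g in goals}
    return comp, float(best_D), preds
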