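"""Heckel analysis of powder compression data.

The Heckel linearization ln(1/(1 - rho_r)) = K*P + A relates the relative
density of a compact to the applied pressure; the reciprocal of the slope
over the plastic-deformation region is the mean yield pressure Py.  The
linear region can be supplied explicitly or detected automatically by a
sliding-window search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CompressionPoint",
    "HeckelFit",
    "RegionDetectionError",
    "relative_density",
    "heckel_transform",
    "fit_heckel",
]


@dataclass(frozen=True)
class CompressionPoint:
    """One compression measurement: applied pressure plus the tablet
    geometry/weight needed to derive apparent density."""

    pressure_mpa: float
    weight_mg: float
    radius_mm: float
    thickness_mm: float
    true_density: float  # g/mL

    def __post_init__(self) -> None:
        for f in ("pressure_mpa", "weight_mg", "radius_mm", "thickness_mm", "true_density"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def apparent_density(self) -> float:
        """g/mL (mg/mm^3 is numerically identical to g/mL)."""
        return self.weight_mg / (math.pi * self.radius_mm**2 * self.thickness_mm)


def relative_density(point: CompressionPoint) -> float:
    """rho_r = apparent density / true density, in (0, 1]."""
    rho_r = point.apparent_density / point.true_density
    if rho_r > 1.0 + 1e-9:
        raise ValueError(
            f"apparent density {point.apparent_density:.4f} exceeds true "
            f"density {point.true_density}; inconsistent measurement"
        )
    return min(rho_r, 1.0)


def heckel_transform(rho_r: float) -> float:
    """y = ln(1 / (1 - rho_r))."""
    if not 0.0 <= rho_r < 1.0:
        raise ValueError(f"relative density must lie in [0, 1), got {rho_r}")
    return math.log(1.0 / (1.0 - rho_r))


@dataclass(frozen=True)
class HeckelFit:
    slope_K: float         # 1/MPa
    intercept_A: float
    pressure_range: tuple[float, float]
    r_squared: float
    yield_pressure: float  # Py = 1/K, MPa
    n_points: int

    def __post_init__(self) -> None:
        if self.slope_K <= 0:
            raise ValueError("Heckel slope must be positive")


class RegionDetectionError(RuntimeError):
    """No linear window satisfied the auto-detection criteria."""


def _ols(P: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(P, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_heckel(
    points: list[CompressionPoint],
    region: str | tuple[float, float] = "auto",
    min_window: int = 5,
    min_span_frac: float = 0.4,
) -> HeckelFit:
    """Fit the Heckel line and derive the yield pressure.

    ``region='auto'`` slides contiguous windows of at least ``min_window``
    points spanning at least ``min_span_frac`` of the pressure range and
    keeps the window with the highest R².  An explicit ``(lo, hi)``
    pressure range may be given instead.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 compression points")
    pts = sorted(points, key=lambda p: p.pressure_mpa)
    P = np.array([p.pressure_mpa for p in pts])
    y = np.array([heckel_transform(relative_density(p)) for p in pts])

    if region != "auto":
        lo, hi = region
        mask = (P >= lo) & (P <= hi)
        if mask.sum() < 4:
            raise ValueError(f"fewer than 4 points in pressure range [{lo}, {hi}]")
        K, A, r2 = _ols(P[mask], y[mask])
        Psel = P[mask]
    else:
        span = P[-1] - P[0]
        best = None
        n = len(P)
        for i in range(n):
            for j in range(i + min_window - 1, n):
                if P[j] - P[i] < min_span_frac * span:
                    continue
                K, A, r2 = _ols(P[i : j + 1], y[i : j + 1])
                if K <= 0:
                    continue
                if best is None or r2 > best[2]:
                    best = (K, A, r2, i, j)
        if best is None:
            raise RegionDetectionError(
                "no contiguous window met the linearity criteria; supply an "
                "explicit (lo, hi) pressure region"
            )
        K, A, r2, i, j = best
        Psel = P[i : j + 1]

    if K <= 0:
        raise ValueError("fitted Heckel slope is non-positive")
    return HeckelFit(
        slope_K=K,
        intercept_A=A,
        pressure_range=(float(Psel[0]), float(Psel[-1])),
        r_squared=r2,
        yield_pressure=1.0 / K,
        n_points=len(Psel),
    )
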