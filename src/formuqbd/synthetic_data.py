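"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a deterministic function of its parameters and a seed,
producing inputs with the statistical structure the corresponding
analysis stage assumes: internally consistent powder records, Scheffé
response surfaces with additive Gaussian noise, dissolution profiles from
each kinetic model, Heckel-linear compression curves (optionally with a
low-pressure rearrangement phase), and two-compartment oral plasma
profiles with proportional noise.
"""

from __future__ import annotations

import warnings

import numpy as np

from .compaction import CompressionPoint
from .dissolution import DissolutionProfile, _MODEL_FUNCS, _MODEL_ALIASES
from .mixture_design import (
    MixtureConstraints,
    ResponseModel,
    _code,
    _design_matrix,
    n_terms,
    scheffe_terms,
)
from .pbpk import PbpkConfig, PlasmaProfile, two_compartment_oral
from .sedem import PowderRecord, invert_radius

__all__ = [
    "ARCHETYPES",
    "gen_powder_record",
    "gen_mixture_responses",
    "gen_dissolution",
    "gen_heckel",
    "gen_plasma",
]

# Target radius bands per archetype (parameter -> (lo, hi) radius).
ARCHETYPES = {
    "direct_compressible": {
        "bulk_density": (5.0, 7.0),
        "tapped_density": (6.5, 8.5),
        "cohesion_index": (6.0, 9.0),
        "angle_of_repose": (5.5, 8.0),
        "powder_flow_time": (6.0, 9.0),
        "loss_on_drying": (6.0, 9.0),
        "hygroscopicity": (7.0, 9.5),
        "fines_fraction": (6.0, 9.0),
        "homogeneity_index": (5.0, 9.0),
    },
    "cohesive_poor_flow": {
        "bulk_density": (4.0, 6.0),
        "tapped_density": (6.0, 8.0),
        "cohesion_index": (0.5, 3.0),
        "angle_of_repose": (1.0, 4.0),
        "powder_flow_time": (1.0, 4.0),
        "loss_on_drying": (5.0, 8.0),
        "hygroscopicity": (5.0, 8.0),
        "fines_fraction": (4.0, 7.0),
        "homogeneity_index": (4.0, 8.0),
    },
    "fine_hygroscopic": {
        "bulk_density": (2.5, 4.5),
        "tapped_density": (4.0, 6.0),
        "cohesion_index": (3.0, 6.0),
        "angle_of_repose": (3.0, 6.0),
        "powder_flow_time": (3.0, 6.0),
        "loss_on_drying": (2.0, 5.0),
        "hygroscopicity": (1.0, 4.0),
        "fines_fraction": (0.5, 3.5),
        "homogeneity_index": (3.0, 7.0),
    },
}


def gen_powder_record(archetype: str, seed: int = 0) -> PowderRecord:
    """Sample an internally consistent powder record for an archetype.

    Da/Dc are sampled from radius bands and the derived parameters
    (Ie, Ic, IH) recomputed from them; the remaining direct measurements
    are back-computed from sampled radii.
    """
    if archetype not in ARCHETYPES:
        raise KeyError(f"unknown archetype {archetype!r}; use {sorted(ARCHETYPES)}")
    bands = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)

    def draw(pid: str) -> float:
        lo, hi = bands[pid]
        return invert_radius(pid, rng.uniform(lo, hi))

    da = draw("bulk_density")
    dc = draw("tapped_density")
    if dc < da:
        da, dc = dc, da
    return PowderRecord.from_measurements(
        material_name=f"{archetype}_{seed}",
        bulk_density=da,
        tapped_density=dc,
        cohesion_index=draw("cohesion_index"),
        angle_of_repose=draw("angle_of_repose"),
        powder_flow_time=draw("powder_flow_time"),
        loss_on_drying=draw("loss_on_drying"),
        hygroscopicity=draw("hygroscopicity"),
        fines_fraction=draw("fines_fraction"),
        homogeneity_index=draw("homogeneity_index"),
    )


def gen_mixture_responses(
    compositions,
    coefficients,
    order: str = "linear",
    noise_sd: float = 0.0,
    seed: int = 0,
    constraints: MixtureConstraints | None = None,
    coding: str = "pseudo",
) -> np.ndarray:
    """y = Scheffé(x; coefficients) + N(0, sd), independent per row
    (replicated compositions get independent noise)."""
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    beta = np.asarray(coefficients, dtype=float)
    if len(beta) != n_terms(order):
        raise ValueError(
            f"{order} order needs {n_terms(order)} coefficients, got {len(beta)}"
        )
    constraints = constraints or MixtureConstraints()
    coded = np.array([_code(c, constraints, coding) for c in np.atleast_2d(compositions)])
    y = _design_matrix(coded, order) @ beta
    rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, noise_sd, size=len(y))


def true_response_model(
    coefficients, order: str = "linear",
    constraints: MixtureConstraints | None = None,
    coding: str = "pseudo", response_name: str = "y",
) -> ResponseModel:
    """Wrap known coefficients as a ResponseModel (for oracle checks)."""
    constraints = constraints or MixtureConstraints()
    return ResponseModel(
        response=response_name, order=order,
        terms=tuple(scheffe_terms(order)),
        coefficients=tuple(float(b) for b in coefficients),
        coding=coding, r_squared=1.0, adj_r_squared=1.0,
        f_statistic=float("inf"), f_pvalue=0.0, residuals=(),
        constraints=constraints,
    )


def gen_dissolution(
    model: str,
    params: dict[str, float],
    times_h,
    noise_sd: float = 0.0,
    seed: int = 0,
    formulation: str = "synthetic",
) -> DissolutionProfile:
    """Generate a release profile from one of the five kinetic models,
    with additive Gaussian noise, clipped to [0, 105]%."""
    model = _MODEL_ALIASES.get(model, model)
    if model not in _MODEL_FUNCS:
        raise KeyError(f"unknown kinetic model {model!r}")
    func, pnames = _MODEL_FUNCS[model]
    missing = set(pnames) - set(params)
    if missing:
        raise ValueError(f"model {model!r} missing parameters {sorted(missing)}")
    t = np.asarray(times_h, dtype=float)
    f = func(t, *[params[p] for p in pnames])
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=len(t))
    f = np.clip(f, 0.0, 105.0)
    f = np.maximum.accumulate(f)  # keep profiles physically non-decreasing
    return DissolutionProfile(formulation, tuple(t), tuple(f))


def gen_heckel(
    K: float,
    A: float,
    pressures_mpa,
    noise_sd: float = 0.0,
    rearrangement_below_mpa: float | None = None,
    seed: int = 0,
    weight_mg: float = 15.0,
    radius_mm: float = 1.5,
    true_density: float = 1.62,
) -> list[CompressionPoint]:
    """Compression points whose Heckel transform follows y = K*P + A.

    Below ``rearrangement_below_mpa`` the curve is depressed (particle
    rearrangement, densification lagging the plastic line).  The relative
    density implied by y is converted back to a tablet thickness
    consistent with the fixed weight, radius and true density.
    """
    if K <= 0 or A <= 0:
        raise ValueError("Heckel slope and intercept must be positive")
    P = np.asarray(pressures_mpa, dtype=float)
    rng = np.random.default_rng(seed)
    y = K * P + A
    if rearrangement_below_mpa is not None:
        low = P < rearrangement_below_mpa
        # smooth densification deficit vanishing at the region boundary
        deficit = 0.5 * (1.0 - P[low] / rearrangement_below_mpa) ** 2
        y[low] = y[low] - deficit
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(P))
    rho_r = 1.0 - np.exp(-y)
    if np.any(rho_r >= 1.0):
        warnings.warn("generated relative density >= 1 truncated to 0.999999")
        rho_r = np.minimum(rho_r, 0.999999)
    rho_a = rho_r * true_density          # g/mL == mg/mm^3
    thickness = weight_mg / (np.pi * radius_mm**2 * rho_a)
    return [
        CompressionPoint(
            pressure_mpa=float(p),
            weight_mg=weight_mg,
            radius_mm=radius_mm,
            thickness_mm=float(h),
            true_density=true_density,
        )
        for p, h in zip(P, thickness)
    ]


def gen_plasma(
    config: PbpkConfig | None = None,
    ka_h: float = 2.185,
    bioavailable_fraction: float = 0.918,
    dose_mg: float = 60.0,
    times_h=None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> PlasmaProfile:
    """Two-compartment oral closed-form profile with proportional
    (CV-scaled) Gaussian noise."""
    config = config or PbpkConfig()
    t = (
        np.arange(0.0, 24.0 + 1e-9, 0.05)
        if times_h is None
        else np.asarray(times_h, dtype=float)
    )
    c = two_compartment_oral(t, dose_mg, ka_h, config, bioavailable_fraction)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        c = c * (1.0 + rng.normal(0.0, noise_cv, size=len(t)))
    return PlasmaProfile(tuple(t), tuple(np.clip(c, 0.0, None)))
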