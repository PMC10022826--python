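"""SeDeM powder scoring.

Converts measured powder characterization parameters into 0-10 radius
scores, groups them into incidences, and derives the summary indices used
to judge direct-compression suitability (parameter index IP, parametric
profile index IPP, good-compression index IGC).  Also provides the
excipient correction percentage for deficient parameters and the radar
polygon coordinates for diagram export.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

__all__ = [
    "PARAMETERS",
    "INCIDENCES",
    "RELIABILITY_FACTOR_12",
    "PowderRecord",
    "SedemProfile",
    "CorrectionQuery",
    "InfeasibleCorrectionError",
    "compute_radius",
    "invert_radius",
    "build_profile",
    "profile_from_radii",
    "correction_percentage",
    "radar_polygon",
]

#: Canonical parameter order (matches the incidence table ordering).
PARAMETERS = (
    "bulk_density",          # Da, g/mL
    "tapped_density",        # Dc, g/mL
    "interparticle_porosity",  # Ie
    "carr_index",            # Ic, %
    "cohesion_index",        # Icd, N
    "hausner_ratio",         # IH
    "angle_of_repose",       # alpha, degrees
    "powder_flow_time",      # t, s
    "loss_on_drying",        # %HR
    "hygroscopicity",        # %H
    "fines_fraction",        # %Pf, % below 50 um
    "homogeneity_index",     # Itheta
)

#: Short CSV column symbols for each parameter.
SYMBOLS = {
    "bulk_density": "Da",
    "tapped_density": "Dc",
    "interparticle_porosity": "Ie",
    "carr_index": "Ic",
    "cohesion_index": "Icd",
    "hausner_ratio": "IH",
    "angle_of_repose": "alpha",
    "powder_flow_time": "t",
    "loss_on_drying": "HR",
    "hygroscopicity": "H",
    "fines_fraction": "Pf",
    "homogeneity_index": "Itheta",
}

#: Incidence grouping of the 12 parameters.
INCIDENCES = {
    "dimensions": ("bulk_density", "tapped_density"),
    "compressibility": ("interparticle_porosity", "carr_index", "cohesion_index"),
    "flowability": ("hausner_ratio", "angle_of_repose", "powder_flow_time"),
    "lubricity_stability": ("loss_on_drying", "hygroscopicity"),
    "lubricity_dosage": ("fines_fraction", "homogeneity_index"),
}

#: Reliability factor for a 12-parameter profile (regular 12-gon area over
#: circumscribed circle area).  Configurable in :func:`build_profile`.
RELIABILITY_FACTOR_12 = 0.952

# radius = a*v + b for each parameter, clamped to [0, 10]
_LINEAR_FACTORS = {
    "bulk_density": (10.0, 0.0),
    "tapped_density": (10.0, 0.0),
    "interparticle_porosity": (10.0 / 1.2, 0.0),
    "carr_index": (1.0 / 5.0, 0.0),
    "cohesion_index": (1.0 / 20.0, 0.0),
    "hausner_ratio": (-5.0, 15.0),          # (30 - 10v)/2
    "angle_of_repose": (-1.0 / 5.0, 10.0),  # 10 - v/5
    "powder_flow_time": (-0.5, 10.0),       # 10 - v/2
    "loss_on_drying": (-1.0, 10.0),         # 10 - v
    "hygroscopicity": (-0.5, 10.0),         # 10 - v/2
    "fines_fraction": (-1.0 / 5.0, 10.0),   # 10 - v/5
    "homogeneity_index": (500.0, 0.0),
}


def compute_radius(parameter_id: str, measured_value: float) -> float:
    """Convert a measured parameter value into its radius score.

    The linear conversion factor is parameter specific; the result is
    clamped to [0, 10] (out-of-range inputs trigger a warning).

    Parameters
    ----------
    parameter_id : str
        One of :data:`PARAMETERS` (or its short symbol, e.g. ``"Icd"``).
    measured_value : float
        The measured value in the parameter's native units.
    """
    pid = _canonical_id(parameter_id)
    v = float(measured_value)
    if not math.isfinite(v):
        raise ValueError(f"measured value for {pid!r} must be finite, got {v!r}")
    a, b = _LINEAR_FACTORS[pid]
    r = a * v + b
    if r < 0.0 or r > 10.0:
        warnings.warn(
            f"radius for {pid}={v} is {r:.3f}, clamped to [0, 10]",
            stacklevel=2,
        )
    return min(10.0, max(0.0, r))


def invert_radius(parameter_id: str, radius: float) -> float:
    """Back-compute the measured value giving ``radius`` (inverse of
    :func:`compute_radius` on the unclamped range)."""
    pid = _canonical_id(parameter_id)
    a, b = _LINEAR_FACTORS[pid]
    return (float(radius) - b) / a


def _canonical_id(parameter_id: str) -> str:
    if parameter_id in _LINEAR_FACTORS:
        return parameter_id
    for name, sym in SYMBOLS.items():
        if parameter_id == sym:
            return name
    raise KeyError(f"unknown SeDeM parameter id: {parameter_id!r}")


@dataclass(frozen=True)
class PowderRecord:
    """The 12 measured SeDeM parameters for one material.

    Derived quantities (Ie, Ic, IH) must be self-consistent with the
    stored bulk/tapped densities; this is validated on construction.
    """

    material_name: str
    bulk_density: float
    tapped_density: float
    interparticle_porosity: float
    carr_index: float
    cohesion_index: float
    hausner_ratio: float
    angle_of_repose: float
    powder_flow_time: float
    loss_on_drying: float
    hygroscopicity: float
    fines_fraction: float
    homogeneity_index: float

    def __post_init__(self) -> None:
        da, dc = self.bulk_density, self.tapped_density
        if not da > 0:
            raise ValueError("bulk density must be positive")
        if dc < da:
            raise ValueError("tapped density cannot be below bulk density")
        checks = {
            "interparticle_porosity": ((dc - da) / (dc * da), self.interparticle_porosity),
            "carr_index": ((dc - da) / dc * 100.0, self.carr_index),
            "hausner_ratio": (dc / da, self.hausner_ratio),
        }
        for name, (expected, stored) in checks.items():
            if abs(expected - stored) > 1e-6:
                raise ValueError(
                    f"{name}={stored} inconsistent with densities "
                    f"(expected {expected:.8f})"
                )
        if not 0.0 <= self.angle_of_repose <= 90.0:
            raise ValueError("angle of repose must lie in [0, 90] degrees")
        for pct in ("carr_index", "loss_on_drying", "hygroscopicity", "fines_fraction"):
            val = getattr(self, pct)
            if not 0.0 <= val <= 100.0:
                raise ValueError(f"{pct} must lie in [0, 100], got {val}")
        if self.homogeneity_index < 0:
            raise ValueError("homogeneity index must be non-negative")

    @classmethod
    def from_measurements(
        cls, material_name: str, bulk_density: float, tapped_density: float, **kwargs
    ) -> "PowderRecord":
        """Build a record recomputing Ie, Ic and IH from the densities."""
        da, dc = bulk_density, tapped_density
        return cls(
            material_name=material_name,
            bulk_density=da,
            tapped_density=dc,
            interparticle_porosity=(dc - da) / (dc * da),
            carr_index=(dc - da) / dc * 100.0,
            hausner_ratio=dc / da,
            **kwargs,
        )

    def values(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETERS}


@dataclass(frozen=True)
class SedemProfile:
    """Radius scores plus incidence means and summary indices."""

    material_name: str
    radii: dict[str, float]
    incidence_means: dict[str, float]
    parameter_index: float          # IP: fraction of radii >= 5
    parameter_profile_index: float  # IPP: mean radius
    reliability_factor: float
    good_compression_index: float   # IGC = IPP * f
    min_acceptable_index: float = field(default=5.0)

    @property
    def suitable_for_direct_compression(self) -> bool:
        return self.good_compression_index >= self.min_acceptable_index

    def to_json(self, **dumps_kwargs) -> str:
        return json.dumps(asdict(self), **dumps_kwargs)


def build_profile(
    record: PowderRecord, reliability_factor: float = RELIABILITY_FACTOR_12
) -> SedemProfile:
    """Score a powder record into a full SeDeM profile."""
    radii = {p: compute_radius(p, getattr(record, p)) for p in PARAMETERS}
    return profile_from_radii(record.material_name, radii, reliability_factor)


def profile_from_radii(
    material_name: str,
    radii: dict[str, float],
    reliability_factor: float = RELIABILITY_FACTOR_12,
) -> SedemProfile:
    """Assemble a profile from already-computed radius scores."""
    missing = set(PARAMETERS) - set(radii)
    if missing:
        raise ValueError(f"missing radii for parameters: {sorted(missing)}")
    if any(not 0.0 <= radii[p] <= 10.0 for p in PARAMETERS):
        raise ValueError("all radii must lie in [0, 10]")
    incidence_means = {
        group: sum(radii[p] for p in members) / len(members)
        for group, members in INCIDENCES.items()
    }
    ipp = sum(radii[p] for p in PARAMETERS) / len(PARAMETERS)
    ip = sum(1 for p in PARAMETERS if radii[p] >= 5.0) / len(PARAMETERS)
    return SedemProfile(
        material_name=material_name,
        radii=radii,
        incidence_means=incidence_means,
        parameter_index=ip,
        parameter_profile_index=ipp,
        reliability_factor=reliability_factor,
        good_compression_index=ipp * reliability_factor,
    )


class InfeasibleCorrectionError(ValueError):
    """The corrective excipient cannot improve the deficient parameter."""


@dataclass(frozen=True)
class CorrectionQuery:
    """Inputs for the excipient correction-percentage calculation.

    RE is the excipient's radius for the deficient parameter, RP the
    material's radius, and R the target radius (default 5).
    """

    RE: float
    RP: float
    R: float = 5.0

    def __post_init__(self) -> None:
        if self.RE <= self.RP:
            raise InfeasibleCorrectionError(
                f"excipient radius RE={self.RE} must exceed the deficient "
                f"material radius RP={self.RP}"
            )
        if not (self.RP <= self.R <= 10.0):
            raise ValueError(f"target radius R={self.R} must lie in [RP, 10]")


def correction_percentage(query: CorrectionQuery) -> float:
    """Percentage of corrective excipient needed to lift a deficient
    parameter to the target radius: CP = 100 - ((RE - R)/(RE - RP)) * 100.

    If even the pure excipient cannot reach the target (RE <= R), returns
    100 with a warning.
    """
    if query.RE <= query.R:
        warnings.warn(
            f"excipient radius RE={query.RE} does not exceed the target "
            f"R={query.R}; 100% excipient cannot reach the target",
            stacklevel=2,
        )
        return 100.0
    cp = 100.0 - (query.RE - query.R) / (query.RE - query.RP) * 100.0
    return min(100.0, max(0.0, cp))


def radar_polygon(profile: SedemProfile) -> list[tuple[float, float]]:
    """Vertices (angle_degrees, radius) of the 12-sided SeDeM diagram,
    parameters in canonical order at 30-degree spacing starting at 90°
    (first parameter at the top, clockwise)."""
    verts = []
    for i, p in enumerate(PARAMETERS):
        angle = (90.0 - 30.0 * i) % 360.0
        verts.append((angle, profile.radii[p]))
    return verts
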