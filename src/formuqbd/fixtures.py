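"""Packaged reference tables for the gastroretentive minitablet case study.

Payloads mirror the published tables verbatim: formulation compositions
(``table3``), simulation input parameters (``table4``), physicochemical /
buoyancy responses (``table6``), release-kinetics fits (``table7``), and
the immediate-release pharmacokinetic reference values (``ir_pk``).
"""

from __future__ import annotations

from types import MappingProxyType

import pandas as pd

__all__ = ["FIXTURES", "load_fixture"]

# Formulation compositions (% of net formulation).  Variable components
# X1 (methocel K100M), X2 (ethocel 10P), X3 (NaHCO3) sum to 59% with 40%
# drug and 1% lubricant fixed.
_TABLE3_ROWS = [
    # run, X1, X2, X3, lubricant, drug
    ("F1", 44.5, 0.0, 14.6, 1.0, 40.0),
    ("F2", 36.6, 10.0, 12.4, 1.0, 40.0),
    ("F3", 45.0, 4.6, 9.4, 1.0, 40.0),
    ("F4", 39.3, 9.6, 10.1, 1.0, 40.0),
    ("F5", 39.2, 4.9, 14.9, 1.0, 40.0),
    ("F6", 44.2, 9.8, 5.0, 1.0, 40.0),
    ("F7", 44.2, 9.8, 5.0, 1.0, 40.0),
    ("F8", 36.6, 7.4, 15.0, 1.0, 40.0),
    ("F9", 44.5, 0.0, 14.6, 1.0, 40.0),
    ("F10", 45.0, 4.6, 9.4, 1.0, 40.0),
    ("F11", 34.0, 10.0, 15.0, 1.0, 40.0),
    ("F12", 39.3, 9.6, 10.1, 1.0, 40.0),
    ("F13", 40.8, 6.4, 11.8, 1.0, 40.0),
    ("F14", 42.6, 7.9, 8.5, 1.0, 40.0),
    ("F15", 43.0, 3.2, 12.8, 1.0, 40.0),
    ("F16", 39.2, 4.9, 14.9, 1.0, 40.0),
]

# Buoyancy / evaluation responses (means).
_TABLE6_ROWS = [
    # run, weight_mg, friability_pct, hardness, thickness_mm, diameter_mm,
    # content_pct, lag_time_s, float_time_h
    ("F1", 15.62, 0.79, 1.37, 2.19, 3.06, 91.29, 19.0, 16.0),
    ("F2", 15.40, 0.61, 1.27, 2.15, 3.07, 96.70, 35.0, 22.0),
    ("F3", 15.15, 0.71, 1.39, 2.17, 3.06, 99.12, 21.0, 21.5),
    ("F4", 14.35, 0.87, 1.47, 2.12, 3.05, 95.84, 45.0, 18.0),
    ("F5", 14.82, 0.80, 1.43, 2.17, 3.09, 91.60, 31.0, 16.0),
    ("F6", 14.82, 0.86, 1.57, 2.09, 3.08, 91.29, 65.0, 17.0),
    ("F7", 13.92, 0.81, 1.42, 2.16, 3.09, 89.05, 63.0, 18.0),
    ("F8", 14.65, 0.69, 1.47, 2.11, 3.10, 88.92, 23.0, 18.0),
    ("F9", 14.82, 0.84, 1.39, 2.16, 3.09, 93.05, 20.0, 15.5),
    ("F10", 14.85, 0.73, 1.45, 2.17, 3.10, 97.64, 23.0, 17.5),
    ("F11", 15.40, 0.72, 1.51, 2.12, 3.07, 97.40, 18.0, 18.0),
    ("F12", 14.98, 0.82, 1.43, 2.17, 3.09, 92.46, 26.0, 18.5),
    ("F13", 14.80, 0.83, 1.46, 2.09, 3.06, 92.01, 24.0, 19.0),
    ("F14", 14.45, 0.79, 1.38, 2.15, 3.10, 92.01, 34.0, 18.4),
    ("F15", 15.10, 0.86, 1.39, 2.14, 3.09, 93.04, 22.0, 19.0),
    ("F16", 15.60, 0.76, 1.44, 2.14, 3.10, 90.60, 24.0, 17.5),
]

# Release-kinetics fit summary per formulation.
_TABLE7_ROWS = [
    # run, zero_r2, k0, first_r2, k1, higuchi_r2, kH, kp_r2, n, kKP,
    # hixson_r2, kHC
    ("F1", 0.770, 7.862, 0.956, 0.114, 0.979, 19.855, 0.994, 0.591, 16.614, 0.929, 0.032),
    ("F2", 0.956, 6.848, 0.986, 0.111, 0.926, 19.675, 0.997, 0.745, 12.067, 0.988, 0.033),
    ("F3", 0.931, 7.055, 0.977, 0.118, 0.942, 20.405, 0.995, 0.700, 13.717, 0.975, 0.034),
    ("F4", 0.735, 7.155, 0.947, 0.133, 0.984, 21.332, 0.988, 0.543, 19.618, 0.900, 0.037),
    ("F5", 0.938, 7.057, 0.985, 0.118, 0.940, 20.382, 0.998, 0.710, 13.426, 0.984, 0.034),
    ("F6", 0.790, 8.291, 0.949, 0.168, 0.942, 24.448, 0.957, 0.592, 20.422, 0.939, 0.047),
    ("F7", 0.909, 7.310, 0.976, 0.127, 0.955, 21.253, 0.996, 0.668, 15.258, 0.971, 0.036),
    ("F8", 0.830, 7.822, 0.973, 0.150, 0.963, 23.015, 0.983, 0.605, 18.573, 0.956, 0.042),
    ("F9", 0.850, 7.404, 0.980, 0.135, 0.957, 21.723, 0.983, 0.623, 17.065, 0.960, 0.038),
    ("F10", 0.802, 7.330, 0.968, 0.135, 0.978, 21.666, 0.991, 0.580, 18.539, 0.938, 0.037),
    ("F11", 0.738, 8.063, 0.869, 0.157, 0.958, 22.927, 0.957, 0.547, 21.785, 0.850, 0.043),
    ("F12", 0.851, 7.815, 0.982, 0.149, 0.960, 23.102, 0.984, 0.623, 18.029, 0.967, 0.041),
    ("F13", 0.849, 7.850, 0.978, 0.151, 0.944, 23.534, 0.982, 0.611, 18.579, 0.961, 0.042),
    ("F14", 0.843, 8.027, 0.977, 0.156, 0.934, 27.854, 0.971, 0.627, 18.342, 0.967, 0.044),
    ("F15", 0.359, 9.091, 0.952, 0.262, 0.934, 27.854, 0.948, 0.435, 31.511, 0.896, 0.075),
    ("F16", 0.601, 8.867, 0.957, 0.227, 0.926, 26.747, 0.927, 0.506, 26.418, 0.912, 0.063),
]

# Simulation inputs (biopharmaceutical + two-compartment disposition).
_TABLE4 = MappingProxyType({
    "log_p": 2.99,
    "pka": 4.19,
    "mol_weight": 304.3,
    "solubility_mg_ml": 0.0268,
    "diffusion_cm2_s": 0.75e-5,
    "particle_density": 1.62,
    "peff_cm_s": 5.31e-4,
    "fup_pct": 1.0,
    "rbp": 0.69,
    "vc_l_kg": 0.0381,
    "k12_h": 0.3013,
    "k21_h": 0.0211,
    "cl_l_h_kg": 0.10354,
})

# Immediate-release reference PK (60 mg, two-compartment fit) and the
# simulated extended-release exposure (120 mg).
_IR_PK = MappingProxyType({
    "dose_mg": 60.0,
    "cmax_ug_ml": 4.866,
    "tmax_h": 0.4812,
    "auc_0_t": 7.364,
    "auc_0_inf": 7.498,
    "cl_l_h": 7.342,
    "vd_l_kg": 0.0381,
    "k12_h": 0.3013,
    "k21_h": 0.02116,
})

_ER_PK = MappingProxyType({
    "dose_mg": 120.0,
    "cmax_ug_ml": 1.0958,
    "tmax_h": 4.8,
    "auc_0_t": 14.448,
    "auc_0_inf": 15.459,
})


def _df(rows, columns):
    return pd.DataFrame(rows, columns=columns).set_index("run")


def _builders():
    return {
        "table3": lambda: _df(
            _TABLE3_ROWS, ["run", "X1", "X2", "X3", "lubricant_pct", "drug_pct"]
        ),
        "table6": lambda: _df(
            _TABLE6_ROWS,
            [
                "run", "weight_mg", "friability_pct", "hardness_kg_cm2",
                "thickness_mm", "diameter_mm", "content_pct",
                "lag_time_s", "float_time_h",
            ],
        ),
        "table7": lambda: _df(
            _TABLE7_ROWS,
            [
                "run", "zero_r2", "k0", "first_r2", "k1", "higuchi_r2", "kH",
                "kp_r2", "n", "kKP", "hixson_r2", "kHC",
            ],
        ),
        "table4": lambda: dict(_TABLE4),
        "ir_pk": lambda: dict(_IR_PK),
        "er_pk": lambda: dict(_ER_PK),
    }


FIXTURES = tuple(sorted(_builders()))


def load_fixture(name: str):
    """Return a packaged fixture as a fresh DataFrame or dict.

    Names: ``table3`` (compositions), ``table4`` (simulation inputs),
    ``table6`` (evaluation responses), ``table7`` (kinetic fits),
    ``ir_pk`` / ``er_pk`` (reference exposure values).
    """
    builders = _builders()
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return builders[name]()
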