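"""End-to-end demo pipeline tying the stages together.

Runs powder scoring, response-surface fitting on the packaged design
tables, desirability optimization, dissolution kinetics, and the
transit-absorption simulation, and collects everything into one
JSON-serializable report.  Deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict

import numpy as np

from . import desirability as des
from . import dissolution as diss
from . import mixture_design as mx
from . import pbpk
from . import sedem
from . import synthetic_data as synth
from .fixtures import load_fixture

log = logging.getLogger("formuqbd")

__all__ = ["run_pipeline"]


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the fixture-driven demonstration pipeline.

    ``config`` keys (all optional): ``seed`` (int), ``er_dose_mg``,
    ``ir_dose_mg``, ``release_k1_h`` (ER first-order release constant),
    ``duration_h``.
    """
    cfg = {
        "seed": 0,
        "er_dose_mg": 120.0,
        "ir_dose_mg": 60.0,
        "release_k1_h": 0.111,
        "duration_h": 36.0,
    }
    cfg.update(config or {})
    seed = int(cfg["seed"])
    report: dict = {"config": dict(cfg)}

    # --- powder scoring -----------------------------------------------
    log.info("stage sedem: scoring archetype powders (seed=%d)", seed)
    profiles = {}
    for archetype in synth.ARCHETYPES:
        rec = synth.gen_powder_record(archetype, seed=seed)
        prof = sedem.build_profile(rec)
        profiles[archetype] = {
            "IGC": prof.good_compression_index,
            "IPP": prof.parameter_profile_index,
            "IP": prof.parameter_index,
            "suitable": prof.suitable_for_direct_compression,
        }
    report["sedem"] = profiles

    # --- response-surface fits on the packaged design -----------------
    log.info("stage doe: fitting buoyancy response models")
    table3 = load_fixture("table3")
    table6 = load_fixture("table6")
    comps = table3[["X1", "X2", "X3"]].to_numpy()
    models = {}
    fitted = {}
    for response, column, order in (
        ("lag_time_s", "lag_time_s", "linear"),
        ("float_time_h", "float_time_h", "quadratic"),
    ):
        m = mx.fit_scheffe(
            comps, table6[column].to_numpy(), order=order, response_name=response
        )
        fitted[response] = m
        models[response] = json.loads(m.to_json())
    report["response_models"] = models

    # --- desirability optimization on the fitted responses ------------
    log.info("stage desirability: optimizing lag/float criteria")
    goals = [g for g in des.paper_goals() if g.response in fitted]
    comp, D, preds = des.optimize_composition(fitted, goals, seed=seed)
    report["optimization"] = {
        "composition_pct": {"X1": comp[0], "X2": comp[1], "X3": comp[2]},
        "overall_desirability": D,
        "predicted_responses": preds,
    }

    # --- dissolution kinetics on the optimum formulation --------------
    log.info("stage dissolution: kinetic fits of the optimized release")
    times = np.array([0.5, 1, 2, 4, 6, 8, 10, 12, 16, 20, 24], dtype=float)
    profile = synth.gen_dissolution(
        "first", {"k1": cfg["release_k1_h"]}, times, seed=seed, formulation="F2"
    )
    fits = diss.fit_all(profile)
    kp_n = fits["kp"].params["n"]
    report["dissolution"] = {
        "best_model": diss.best_model(fits),
        "fits": {m: {"params": f.params, "r2": f.r_squared} for m, f in fits.items()},
        "mechanism": diss.classify_mechanism(kp_n),
    }

    # --- plasma simulation and validation metrics ---------------------
    log.info("stage pbpk: simulating ER profile and comparing exposure")
    config4 = pbpk.PbpkConfig(dose_mg=cfg["er_dose_mg"])
    er_profile = pbpk.simulate(
        pbpk.FirstOrderRelease(cfg["release_k1_h"]),
        config=config4,
        duration_h=cfg["duration_h"],
    )
    er_metrics = pbpk.pk_metrics(er_profile)
    ir = load_fixture("ir_pk")
    er = load_fixture("er_pk")
    scale = cfg["er_dose_mg"] / ir["dose_mg"]
    comparison = {
        "auc_0_inf": asdict(
            pbpk.compare_profiles(
                ir["auc_0_inf"], er["auc_0_inf"], ir["dose_mg"], er["dose_mg"]
            )
        ),
        "auc_0_t": asdict(
            pbpk.compare_profiles(
                ir["auc_0_t"], er["auc_0_t"], ir["dose_mg"], er["dose_mg"]
            )
        ),
    }
    report["pbpk"] = {
        "simulated_er": {
            "cmax_ug_ml": er_metrics.cmax,
            "tmax_h": er_metrics.tmax,
            "auc_0_t": er_metrics.auc_0_t,
            "auc_0_inf": er_metrics.auc_0_inf,
        },
        "relative_bioavailability_pct": pbpk.relative_bioavailability(
            ir["auc_0_inf"] * scale, cfg["er_dose_mg"],
            er["auc_0_inf"], er["dose_mg"],
        ),
        "comparison": comparison,
    }
    return report
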