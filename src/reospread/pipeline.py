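"""End-to-end reproducible analysis pipeline.

``run_pipeline`` ties the stages together: estimate kinetic parameters
from the shipped assay fixtures, run the travelling-wave analysis and the
binding-rate optimization, simulate the 1-D invasion and the 2-D plaque
model, and validate the front decay rate on synthetic fluorescence
profiles.  Outputs are flat CSV files plus a human-readable report that
lists each headline quantity next to its published reference value with
the relative deviation.

All stochastic stages derive their seeds from one master seed recorded in
the returned :class:`RunManifest`, so a run is reproducible end to end.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .estimation import (StokesEinsteinInput, estimate_binding_rate,
                         fit_death_rate, half_life, stokes_einstein,
                         viral_replication_number)
from .front_validation import fit_front_decay, per_pixel_to_per_mm
from .io import load_binding_fixture, load_death_fixture
from .params import SV5, T3WT
from .pde import (measure_front_speed, plaque_area, simulate_model2_1d,
                  simulate_model3_2d)
from .synthdata import gen_front_profile
from .wave import minimal_wave_speed, optimal_binding_rate

__all__ = ["RunManifest", "run_pipeline", "DEFAULT_CONFIG", "load_config"]

#: Published reference values the report compares against.
REFERENCE = {
    "gamma_b_T3wt": 0.96, "gamma_b_SV5": 0.28,
    "half_life_T3wt": 0.722, "half_life_SV5": 2.476,
    "alpha": 0.057,
    "D_V_stokes_einstein": 0.02,
    "R_V_T3wt": 5.14, "R_V_SV5": 7.32,
    "c_star_T3wt": 0.04366, "c_star_SV5": 0.05941,
    "lambda_star_T3wt": 6.9, "lambda_star_SV5": 5.4,
    "c_max_T3wt": 0.04858, "gamma_b_max_T3wt": 0.29,
    "c_max_SV5": 0.06002, "gamma_b_max_SV5": 0.42,
    "front_speed_1d_T3wt": 0.04373, "front_speed_1d_SV5": 0.05990,
    "plaque_area_T3wt": 15.2053, "plaque_area_SV5": 55.4177,
    "plaque_ratio_SV5_T3wt": 3.6446,
    "lambda_front_T3wt_per_mm": 9.8, "lambda_front_SV5_per_mm": 4.9,
}

DEFAULT_CONFIG = {
    "seed": 0,
    "death_onset_h": 15.0,
    "sim1d_dx": 0.02,
    "sim1d_length_mm": 25.0,
    "sim1d_duration_h": 300.0,
    "sim2d_dx": 0.1,
    "sim2d_side_mm": 30.0,
    "sim2d_duration_h": 120.0,
    "table6_b_grid": "500,550,600,650,700,750,800,850,900,950,1000",
    "table6_gamma_lo": 0.15,
    "table6_gamma_hi": 0.5,
    "table6_plaques": False,
    "run_simulations": True,
}


def load_config(path) -> dict:
    """Parse a plain ``key = value`` config file over the defaults."""
    config = dict(DEFAULT_CONFIG)
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in config:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        default = config[key]
        if isinstance(default, bool):
            config[key] = value.lower() in ("1", "true", "yes", "on")
        elif isinstance(default, (int, float)):
            config[key] = type(default)(float(value))
        else:
            config[key] = value
    return config


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, outputs, timings."""

    config: dict
    version: str
    seed: int
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)


def _report_line(name: str, value: float, digits: int = 5) -> str:
    ref = REFERENCE.get(name)
    if ref is None:
        return f"{name:32s} {value:>12.{digits}g}"
    dev = abs(value - ref) / abs(ref) if ref else float("nan")
    return (f"{name:32s} {value:>12.{digits}g}   ref {ref:>10.6g}   "
            f"rel.dev {dev:8.2%}")


def run_pipeline(outdir, config: Optional[dict] = None,
                 log=print) -> RunManifest:
    """Run estimation, wave analysis, simulations and validation.

    Writes ``table3.csv`` (estimated parameters), ``table5.csv`` (observed
    vs speed-optimal binding), ``table6.csv`` (burst-size sweep),
    ``dispersion.csv``, ``simulation_summary.csv``, ``front_validation.csv``
    and ``report.txt`` under ``outdir``.  Returns the manifest.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(cfg), version=__version__,
                           seed=int(cfg["seed"]))
    report: list[str] = [f"reospread {__version__} pipeline report", ""]
    computed: dict[str, float] = {}

    def stage(name):
        log(f"[{name}]")
        return time.perf_counter()

    # ---- stage 1: parameter estimation -----------------------------------
    t0 = stage("estimate")
    binding = load_binding_fixture()
    death = load_death_fixture()
    rows = []
    for virus, assay in binding.items():
        est = estimate_binding_rate(assay)
        computed[f"gamma_b_{virus}"] = est.point
        computed[f"half_life_{virus}"] = half_life(est.point)
        rows.append({"parameter": "gamma_b", "virus": virus,
                     "point": est.point, "lower": est.lower,
                     "upper": est.upper, "units": "1/hour",
                     "method": est.method})
        rows.append({"parameter": "half_life", "virus": virus,
                     "point": half_life(est.point), "lower": None,
                     "upper": None, "units": "hours", "method": "ln2/gamma_b"})
    for virus, series in death.items():
        est = fit_death_rate(series, onset=float(cfg["death_onset_h"]))
        rows.append({"parameter": "alpha", "virus": virus, "point": est.point,
                     "lower": est.lower, "upper": est.upper,
                     "units": "1/hour", "method": est.method})
        computed[f"alpha_{virus}"] = est.point
    d_se = stokes_einstein(StokesEinsteinInput(
        temperature=294.15, viscosity=1e-3, particle_radius=35e-9))
    computed["D_V_stokes_einstein"] = d_se
    rows.append({"parameter": "D_V", "virus": "", "point": d_se,
                 "lower": None, "upper": None, "units": "mm^2/hour",
                 "method": "Stokes-Einstein (T=294.15 K, eta=1e-3 Pa s, "
                           "r=35 nm)"})
    for p in (T3WT, SV5):
        computed[f"R_V_{p.label}"] = viral_replication_number(p).value
        rows.append({"parameter": "R_V", "virus": p.label,
                     "point": p.R_V, "lower": None, "upper": None,
                     "units": "", "method": "b_tilde*nu"})
    pd.DataFrame(rows).to_csv(outdir / "table3.csv", index=False)
    manifest.outputs["table3"] = str(outdir / "table3.csv")
    manifest.timings_s["estimate"] = time.perf_counter() - t0

    # ---- stage 2: dispersion analysis ------------------------------------
    t0 = stage("wave")
    disp_rows = []
    for p in (T3WT, SV5):
        d = minimal_wave_speed(p)
        computed[f"c_star_{p.label}"] = d.c_star
        computed[f"lambda_star_{p.label}"] = d.lambda_star
        disp_rows.append({"virus": p.label, "gamma_b": p.gamma_b,
                          "b_tilde": p.b_tilde, "rho_star": d.rho_star,
                          "rho_v": d.rho_v, "c_star": d.c_star,
                          "lambda_star": d.lambda_star})
    pd.DataFrame(disp_rows).to_csv(outdir / "dispersion.csv", index=False)
    manifest.outputs["dispersion"] = str(outdir / "dispersion.csv")
    manifest.timings_s["wave"] = time.perf_counter() - t0

    # ---- stage 3: binding-rate optimization ------------------------------
    t0 = stage("optimize")
    t5_rows = []
    for label, p in [("T3wt", T3WT), ("Intermediate", T3WT.with_(b_tilde=623)),
                     ("SV5", SV5)]:
        d = minimal_wave_speed(p)
        t5_rows.append({"row": f"{label} Data", "gamma_b": p.gamma_b,
                        "binding_percent": 100 * (1 - np.exp(-p.gamma_b)),
                        "c_star": d.c_star, "b_tilde": p.b_tilde,
                        "ratio": None})
        opt = optimal_binding_rate(p)
        t5_rows.append({"row": f"Max {label}", "gamma_b": opt.gamma_b_max,
                        "binding_percent": opt.binding_percent_1h,
                        "c_star": opt.c_max, "b_tilde": p.b_tilde,
                        "ratio": opt.ratio})
        if label != "Intermediate":
            computed[f"c_max_{label}"] = opt.c_max
            computed[f"gamma_b_max_{label}"] = opt.gamma_b_max
    pd.DataFrame(t5_rows).to_csv(outdir / "table5.csv", index=False)
    manifest.outputs["table5"] = str(outdir / "table5.csv")

    b_grid = [float(s) for s in str(cfg["table6_b_grid"]).split(",")]
    bounds = (float(cfg["table6_gamma_lo"]), float(cfg["table6_gamma_hi"]))
    t6_rows = []
    for b in b_grid:
        opt = optimal_binding_rate(T3WT.with_(b_tilde=b), bounds)
        row = {"b_tilde": b, "gamma_b_max": opt.gamma_b_max,
               "ratio": opt.ratio, "c_max": opt.c_max,
               "binding_percent": opt.binding_percent_1h}
        if cfg["table6_plaques"]:
            f = simulate_model3_2d(opt.params,
                                   side_mm=float(cfg["sim2d_side_mm"]),
                                   duration_h=float(cfg["sim2d_duration_h"]),
                                   dx=float(cfg["sim2d_dx"]))
            row["plaque_area_mm2"] = plaque_area(f).area
        t6_rows.append(row)
    pd.DataFrame(t6_rows).to_csv(outdir / "table6.csv", index=False)
    manifest.outputs["table6"] = str(outdir / "table6.csv")
    manifest.timings_s["optimize"] = time.perf_counter() - t0

    # ---- stage 4: simulations --------------------------------------------
    if cfg["run_simulations"]:
        t0 = stage("simulate")
        sim_rows = []
        for p in (T3WT, SV5):
            f1 = simulate_model2_1d(
                p, length_mm=float(cfg["sim1d_length_mm"]),
                duration_h=float(cfg["sim1d_duration_h"]),
                dx=float(cfg["sim1d_dx"]))
            speed = measure_front_speed(f1, level=1.0)
            computed[f"front_speed_1d_{p.label}"] = speed.fitted_speed
            f2 = simulate_model3_2d(
                p, side_mm=float(cfg["sim2d_side_mm"]),
                duration_h=float(cfg["sim2d_duration_h"]),
                dx=float(cfg["sim2d_dx"]))
            area = plaque_area(f2)
            computed[f"plaque_area_{p.label}"] = area.area
            sim_rows.append({"virus": p.label,
                             "front_speed_mm_per_h": speed.fitted_speed,
                             "front_speed_r2": speed.r_squared,
                             "plaque_area_mm2": area.area,
                             "plaque_time_h": area.time})
        computed["plaque_ratio_SV5_T3wt"] = (
            computed["plaque_area_SV5"] / computed["plaque_area_T3wt"])
        pd.DataFrame(sim_rows).to_csv(outdir / "simulation_summary.csv",
                                      index=False)
        manifest.outputs["simulation_summary"] = str(
            outdir / "simulation_summary.csv")
        manifest.timings_s["simulate"] = time.perf_counter() - t0

    # ---- stage 5: front-decay validation on synthetic profiles -----------
    t0 = stage("validate")
    day_rates = {"T3wt": (0.029, 0.022, 0.014), "SV5": (0.015, 0.011, 0.007)}
    val_rows = []
    rng = np.random.default_rng(int(cfg["seed"]))
    for virus, rates in day_rates.items():
        fits = []
        for day, lam_true in enumerate(rates, start=2):
            prof = gen_front_profile(lam_true, s_px=10.0, n_px=150,
                                     noise_sd=0.02,
                                     seed=int(rng.integers(2 ** 31)), day=day)
            fit = fit_front_decay(prof)
            fits.append(fit.decay_rate)
            val_rows.append({"virus": virus, "day": day,
                             "lambda_true_per_px": lam_true,
                             "lambda_fit_per_px": fit.decay_rate,
                             "r_squared": fit.r_squared})
        lam_mm = per_pixel_to_per_mm(float(np.mean(fits)))
        computed[f"lambda_front_{virus}_per_mm"] = lam_mm
        val_rows.append({"virus": virus, "day": "mean",
                         "lambda_true_per_px": np.mean(rates),
                         "lambda_fit_per_px": np.mean(fits),
                         "r_squared": None})
    pd.DataFrame(val_rows).to_csv(outdir / "front_validation.csv", index=False)
    manifest.outputs["front_validation"] = str(outdir / "front_validation.csv")
    manifest.timings_s["validate"] = time.perf_counter() - t0

    # ---- report ----------------------------------------------------------
    for name in sorted(computed):
        report.append(_report_line(name, computed[name]))
    report.append("")
    report.append("timings (s): " + ", ".join(
        f"{k}={v:.2f}" for k, v in manifest.timings_s.items()))
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    manifest.outputs["report"] = str(outdir / "report.txt")
    log("\n".join(report))
    return manifest
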