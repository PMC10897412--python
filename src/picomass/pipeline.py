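"""End-to-end orchestration: synthesize -> fit -> derive mechanics -> report.

``run_pipeline`` reproduces the ensemble experiment in silico: it generates
the relative-mass scan across the cantilever bank, fits the readout law for
the population-average cell eigenfrequency and Q, converts the
eigenfrequency into a whole-cell spring constant, and (given a shape
factor) a Young's modulus.  The JSON report embeds the seeds and a config
hash so every number is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version

import pandas as pd

from .eigenfit import cell_stiffness, fit_readout_curve, youngs_modulus
from .synthetic_data import PopulationSpec, make_ensemble_experiment

__all__ = ["run_pipeline", "fit_ensemble_frame", "population_from_config"]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def population_from_config(config: dict) -> PopulationSpec:
    pop = config.get("population", {})
    return PopulationSpec(
        mass_mean=pop.get("mass_ng", 3.14) * 1e-12,
        mass_sd=pop.get("mass_sd_ng", 0.26) * 1e-12,
        f_cell_mean=pop.get("f_cell_khz", 14.4) * 1e3,
        f_cell_sd=pop.get("f_cell_sd_khz", 0.0) * 1e3,
        q_cell=pop.get("q_cell", 0.3),
        noise_cv=pop.get("noise_cv", 0.4),
    )


def fit_ensemble_frame(frame: pd.DataFrame, config: dict | None = None, seed: int = 0):
    """Fit the readout law to an ensemble table with ``f_cant_hz`` and ``ratio``."""
    config = config or {}
    fit_cfg = config.get("fit", {})
    return fit_readout_curve(
        frame["f_cant_hz"].to_numpy(),
        frame["ratio"].to_numpy(),
        fit_on=fit_cfg.get("fit_on", "raw"),
        n_bins=fit_cfg.get("n_bins", 7),
        n_starts=fit_cfg.get("n_starts", 5),
        n_bootstrap=fit_cfg.get("n_bootstrap", 0),
        seed=seed,
    )


def run_pipeline(config: dict | None = None, seed: int = 0) -> dict:
    """Run the full synthetic ensemble experiment and return the report dict."""
    config = config or {}
    seed = config.get("seed", seed)
    pop = population_from_config(config)
    ens_cfg = config.get("ensemble", {})
    frame = make_ensemble_experiment(
        pop=pop,
        n=ens_cfg.get("n", 178),
        f_range=(
            ens_cfg.get("f_min_khz", 3.0) * 1e3,
            ens_cfg.get("f_max_khz", 110.0) * 1e3,
        ),
        mode=ens_cfg.get("mode", "closed_form"),
        seed=seed,
    )
    result = fit_ensemble_frame(frame, config, seed=seed)

    report = result.to_dict()
    report["generating"] = {
        "f_cell_khz": pop.f_cell_mean / 1e3,
        "q_cell": pop.q_cell,
        "mass_ng": pop.mass_mean * 1e12,
        "noise_cv": pop.noise_cv,
    }
    if result.flags:
        report["k_cell_n_per_m"] = None
    else:
        report["k_cell_n_per_m"] = cell_stiffness(result.f_cell_hat, pop.mass_mean)
        shape_factor = config.get("shape_factor_m")
        if shape_factor is not None:
            report["youngs_modulus_pa"] = youngs_modulus(
                report["k_cell_n_per_m"], shape_factor
            )
    report["seed"] = seed
    report["config_hash"] = _config_hash(config)
    try:
        report["version"] = version("picomass")
    except PackageNotFoundError:  # running from a source tree
        report["version"] = "unknown"
    return report
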