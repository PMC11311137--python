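"""End-to-end orchestration: counts -> rates -> CNT fit -> report.

The pipeline reads a TOML config listing materials and their count-series
files, estimates a nucleation rate per experiment, fits the linearized CNT
model per material, and emits a provenance-carrying report (input hashes,
constants, package version, seed).  When per-material net charges are
supplied, the report also includes the gamma_net-versus-charge trend (OLS
slope and intercept), the cross-material summary the whole analysis chain
builds toward.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import tomllib
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats

from . import __version__, cnt, io as nio
from .errors import NucleokinError
from .nucleation_kinetics import estimate_J0

log = logging.getLogger("nucleokin")


class ExperimentRecord(BaseModel):
    file: str
    sha256: str
    sigma: float
    j0: float
    j0_se: float
    r_squared: float
    n_points: int


class MaterialRecord(BaseModel):
    name: str
    charge: Optional[float] = None
    experiments: list[ExperimentRecord] = Field(default_factory=list)
    ln_a: Optional[float] = None
    ln_a_se: Optional[float] = None
    b: Optional[float] = None
    b_se: Optional[float] = None
    gamma_net: Optional[float] = None
    gamma_net_se: Optional[float] = None
    r_squared: Optional[float] = None
    error: Optional[str] = None


class ChargeTrend(BaseModel):
    slope: float
    intercept: float
    r_squared: float
    n_materials: int


class AnalysisReport(BaseModel):
    """Schema of the pipeline's JSON output (shipped as report.schema.json)."""

    version: str
    seed: Optional[int] = None
    constants: dict[str, float]
    materials: list[MaterialRecord] = Field(default_factory=list)
    charge_trend: Optional[ChargeTrend] = None
    warnings: list[str] = Field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path,
                 constants: cnt.CNTConstants | None = None) -> AnalysisReport:
    """Execute the full counts -> gamma_net workflow described by a config.

    Config schema (TOML)::

        seed = 1                      # optional, recorded for provenance
        temperature_K = 295.15        # optional CNT constant overrides
        burn_in_min = 10.0
        r2_threshold = 0.95
        min_points = 4

        [[materials]]
        name = "OSC 0.23"
        charge = -0.23                # optional, enables the charge trend
        experiments = ["osc023_s47.csv", "osc023_s50.csv", ...]

    Failures are isolated per material: a material whose rate estimation or
    CNT fit fails is reported with its error string and the rest proceed.
    """
    config_path = Path(config_path)
    with config_path.open("rb") as fh:
        config = tomllib.load(fh)
    if constants is None:
        kwargs = {}
        if "temperature_K" in config:
            kwargs["temperature"] = float(config["temperature_K"])
        constants = cnt.CNTConstants(**kwargs)
    burn_in = float(config.get("burn_in_min", 10.0))
    r2_threshold = float(config.get("r2_threshold", 0.95))
    min_points = int(config.get("min_points", 4))

    report = AnalysisReport(
        version=__version__,
        seed=config.get("seed"),
        constants={
            "boltzmann_J_per_K": constants.boltzmann,
            "temperature_K": constants.temperature,
            "shape_factor": constants.shape_factor,
            "molecular_volume_cm3": constants.molecular_volume,
            "k_sp": constants.k_sp,
        },
    )
    materials = config.get("materials", [])
    if not materials:
        report.warnings.append("empty experiment list: nothing to analyse")
        log.warning("pipeline config lists no materials")
        return report

    for mat in materials:
        record = MaterialRecord(name=mat["name"], charge=mat.get("charge"))
        try:
            points = []
            for exp_path in mat.get("experiments", []):
                path = (config_path.parent / exp_path).resolve()
                series = nio.read_counts_csv(path)
                est = estimate_J0(series, burn_in_min=burn_in,
                                  min_points=min_points,
                                  r2_threshold=r2_threshold)
                record.experiments.append(ExperimentRecord(
                    file=str(exp_path),
                    sha256=_sha256(path),
                    sigma=series.sigma,
                    j0=est.j0,
                    j0_se=est.j0_se,
                    r_squared=est.r_squared,
                    n_points=est.n_points,
                ))
                if est.j0 > 0:
                    se = est.j0_se / est.j0 if est.j0_se else 0.0
                    points.append(cnt.RatePoint(sigma=series.sigma,
                                                ln_j0=math.log(est.j0),
                                                ln_j0_se=se))
                else:
                    report.warnings.append(
                        f"{mat['name']}/{exp_path}: non-positive rate excluded "
                        "from the CNT fit"
                    )
            fit = cnt.fit_cnt(points, constants)
            record.ln_a = fit.ln_a
            record.ln_a_se = _none_if_nan(fit.ln_a_se)
            record.b = fit.b
            record.b_se = _none_if_nan(fit.b_se)
            record.gamma_net = _none_if_nan(fit.gamma_net)
            record.gamma_net_se = _none_if_nan(fit.gamma_net_se)
            record.r_squared = fit.r_squared
            log.info("material %s: ln A = %.3f, B = %.1f, gamma_net = %s mJ/m^2",
                     mat["name"], fit.ln_a, fit.b,
                     "nan" if math.isnan(fit.gamma_net) else f"{fit.gamma_net:.1f}")
        except (NucleokinError, OSError, KeyError) as exc:
            record.error = f"{type(exc).__name__}: {exc}"
            report.warnings.append(f"{mat['name']}: {record.error}")
            log.warning("material %s failed: %s", mat["name"], exc)
        report.materials.append(record)

    charged = [(m.charge, m.gamma_net) for m in report.materials
               if m.charge is not None and m.gamma_net is not None]
    if len(charged) >= 2 and len({c for c, _ in charged}) >= 2:
        x = np.array([c for c, _ in charged])
        y = np.array([g for _, g in charged])
        fit = stats.linregress(x, y)
        report.charge_trend = ChargeTrend(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            n_materials=len(charged),
        )
    return report


def _none_if_nan(x: float) -> Optional[float]:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else x


def report_to_json(report: AnalysisReport) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(report.model_dump(), sort_keys=True, indent=2)


def format_report_table(report: AnalysisReport) -> str:
    """Human-readable per-material summary; gamma rounded to integer mJ/m^2."""
    lines = [f"{'material':<24}{'ln A':>9}{'B':>9}{'gamma_net':>11}{'R^2':>7}"]
    for m in report.materials:
        if m.error:
            lines.append(f"{m.name:<24}  failed: {m.error}")
            continue
        gamma = f"{round(m.gamma_net):d}" if m.gamma_net is not None else "undef"
        lines.append(
            f"{m.name:<24}{m.ln_a:>9.2f}{m.b:>9.1f}{gamma:>11}{m.r_squared:>7.3f}"
        )
    if report.charge_trend is not None:
        t = report.charge_trend
        lines.append(
            f"gamma_net vs net charge: slope = {t.slope:.1f} mJ/m^2 per e, "
            f"intercept = {t.intercept:.1f} mJ/m^2, R^2 = {t.r_squared:.3f} "
            f"(n = {t.n_materials})"
        )
    return "\n".join(lines)
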