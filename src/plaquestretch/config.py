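"""Pipeline configuration: YAML parsing, validation, defaults.

A config names either a geometry preset / inline cross-section spec or an
external labeled mesh file, plus materials, load cases and analysis
settings.  Unknown keys are rejected with a nearest-key suggestion; invalid
values are rejected with the offending field named.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .geometry import (
    CalcArc,
    CrossSectionSpec,
    LrncPool,
    annulus_spec,
    reference_stenotic_spec,
)
from .solver import SolverSettings

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    pass


_TOP_KEYS = {
    "geometry", "mesh_path", "materials", "load_cases_mmhg", "target_h_mm",
    "solver", "analysis", "output_dir", "seed",
}
_SOLVER_KEYS = {"load_steps", "newton_rtol", "newton_max_iter", "line_search",
                "n_quad"}
_ANALYSIS_KEYS = {"threshold_mm", "reference_pct", "profile_angles_deg"}
_GEOMETRY_KEYS = {
    "preset", "lumen_radius", "outer_radius", "lumen_center",
    "stenosis_eccentricity", "calc_arcs", "lrnc_pools", "jitter_deg", "seed",
}

GEOMETRY_PRESETS = {
    "reference_stenotic": reference_stenotic_spec,
    "annulus": lambda seed=0: annulus_spec(),
    "stenotic_no_calc": lambda seed=0: _no_calc(seed),
}


def _no_calc(seed=0):
    ref = reference_stenotic_spec(seed)
    return CrossSectionSpec(
        lumen_radius=ref.lumen_radius,
        outer_radius=ref.outer_radius,
        lumen_center=ref.lumen_center,
        lrnc_pools=ref.lrnc_pools,
        stenosis_eccentricity=ref.stenosis_eccentricity,
        seed=seed,
    )


@dataclass
class AnalysisSettings:
    threshold_mm: float = 1.0
    reference_pct: float = 12.5
    profile_angles_deg: tuple = (0.0, 60.0, 120.0)


@dataclass
class PipelineConfig:
    """Fully validated, fully defaulted pipeline configuration."""

    geometry: CrossSectionSpec | None
    mesh_path: str | None
    materials: str
    load_cases_mmhg: tuple
    target_h_mm: float
    solver: SolverSettings
    analysis: AnalysisSettings
    output_dir: str
    seed: int

    def config_hash(self) -> str:
        blob = json.dumps(self.echo(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def echo(self) -> dict:
        """Effective configuration as a plain JSON-ready dict."""
        d = {
            "geometry": None if self.geometry is None else asdict(self.geometry),
            "mesh_path": self.mesh_path,
            "materials": self.materials,
            "load_cases_mmhg": list(self.load_cases_mmhg),
            "target_h_mm": self.target_h_mm,
            "solver": asdict(self.solver),
            "analysis": asdict(self.analysis),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        if self.geometry is not None:
            d["geometry"]["lumen_center"] = list(self.geometry.lumen_center)
            d["geometry"]["calc_arcs"] = [asdict(a) for a in self.geometry.calc_arcs]
            d["geometry"]["lrnc_pools"] = [asdict(p) for p in self.geometry.lrnc_pools]
        if self.analysis is not None:
            d["analysis"]["profile_angles_deg"] = list(self.analysis.profile_angles_deg)
        return d


def _reject_unknown(given, allowed, where):
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suggestion = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ConfigError(f"unknown key '{key}' in {where}{suggestion}")


def _geometry_from(raw, default_seed):
    if isinstance(raw, str):
        raw = {"preset": raw}
    _reject_unknown(raw, _GEOMETRY_KEYS, "geometry")
    seed = int(raw.get("seed", default_seed))
    if "preset" in raw:
        preset = raw["preset"]
        if preset not in GEOMETRY_PRESETS:
            hint = difflib.get_close_matches(preset, GEOMETRY_PRESETS, n=1)
            suggestion = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ConfigError(f"unknown geometry preset '{preset}'{suggestion}")
        extra = set(raw) - {"preset", "seed"}
        if extra:
            raise ConfigError(
                f"geometry preset does not accept extra fields: {sorted(extra)}"
            )
        return GEOMETRY_PRESETS[preset](seed=seed)
    try:
        return CrossSectionSpec(
            lumen_radius=float(raw["lumen_radius"]),
            outer_radius=float(raw["outer_radius"]),
            lumen_center=tuple(raw.get("lumen_center", (0.0, 0.0))),
            calc_arcs=tuple(CalcArc(**a) for a in raw.get("calc_arcs", [])),
            lrnc_pools=tuple(LrncPool(**p) for p in raw.get("lrnc_pools", [])),
            stenosis_eccentricity=float(raw.get("stenosis_eccentricity", 0.0)),
            jitter_deg=float(raw.get("jitter_deg", 0.0)),
            seed=seed,
        )
    except KeyError as e:
        raise ConfigError(f"geometry: missing required field {e}") from e


def validate_config(raw) -> PipelineConfig:
    """Validate a raw config (dict or YAML text) into a PipelineConfig."""
    if isinstance(raw, (str, bytes)):
        raw = yaml.safe_load(raw)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")

    seed = int(raw.get("seed", 0))
    geometry = None
    mesh_path = raw.get("mesh_path")
    if "geometry" in raw:
        geometry = _geometry_from(raw["geometry"], seed)
    if geometry is None and mesh_path is None:
        raise ConfigError("config must provide 'geometry' or 'mesh_path'")

    loads = tuple(float(p) for p in raw.get("load_cases_mmhg", (80.0, 140.0)))
    if any(p < 0 for p in loads):
        raise ConfigError("load_cases: pressures must be non-negative (mmHg)")
    if not loads:
        raise ConfigError("load_cases: at least one pressure required")

    target_h = float(raw.get("target_h_mm", 0.3))
    if target_h <= 0:
        raise ConfigError("target_h_mm must be positive")

    solver_raw = dict(raw.get("solver", {}))
    _reject_unknown(solver_raw, _SOLVER_KEYS, "solver")
    solver = SolverSettings(**solver_raw)

    analysis_raw = dict(raw.get("analysis", {}))
    _reject_unknown(analysis_raw, _ANALYSIS_KEYS, "analysis")
    if "profile_angles_deg" in analysis_raw:
        analysis_raw["profile_angles_deg"] = tuple(
            float(a) for a in analysis_raw["profile_angles_deg"]
        )
    analysis = AnalysisSettings(**analysis_raw)
    if analysis.threshold_mm <= 0:
        raise ConfigError("analysis.threshold_mm must be positive")

    materials = raw.get("materials", "table2")

    return PipelineConfig(
        geometry=geometry,
        mesh_path=mesh_path,
        materials=str(materials),
        load_cases_mmhg=loads,
        target_h_mm=target_h,
        solver=solver,
        analysis=analysis,
        output_dir=str(raw.get("output_dir", "plaquestretch_out")),
        seed=seed,
    )


def load_config(path) -> PipelineConfig:
    return validate_config(Path(path).read_text())


def load_material_table(name_or_path):
    """Resolve a materials setting: 'table2' preset or a YAML file of constants."""
    from .labels import TissueLabel
    from .materials import MaterialTable, YeohMaterial, table2_presets

    if name_or_path == "table2":
        return table2_presets()
    raw = yaml.safe_load(Path(name_or_path).read_text())
    mats = {}
    for lab in TissueLabel:
        entry = raw[lab.name]
        mats[lab] = YeohMaterial(
            c1=float(entry["c1"]), c2=float(entry["c2"]), c3=float(entry["c3"]),
            kappa=float(entry["kappa"]) if "kappa" in entry else None,
            name=lab.name,
        )
    return MaterialTable(mats)
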