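"""End-to-end driver: generate -> mesh -> solve -> stretch -> report.

``run_pipeline`` executes the full in-silico readout for one configured
cross-section: both pressure load cases are solved, principal stretch and
distance-to-CALC fields are computed, centerline profiles and zone
statistics are written, and a deterministic JSON report plus VTU solution
files are exported.  Rerunning an identical config yields byte-identical
report JSON.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

from . import __version__
from .analysis import principal_stretch, profile_along_line, zone_statistics
from .config import PipelineConfig, load_material_table
from .geometry import distance_to_calc, generate_cross_section, mesh_geometry
from .io import read_vtu, write_report_json, write_vtu
from .solver import LoadCase, SolverError, solve_quasistatic

__all__ = ["run_pipeline"]

_CASE_NAMES = {80.0: "diastole", 140.0: "systole"}


def _log(msg):
    print(f"[plaquestretch] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the report dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    stage = "geometry"
    try:
        if config.geometry is not None:
            cross = generate_cross_section(config.geometry)
            stage = "meshing"
            mesh = mesh_geometry(cross, config.target_h_mm)
        else:
            stage = "mesh loading"
            mesh, _, _ = read_vtu(config.mesh_path)
            mesh.validate()
        timings["mesh_s"] = round(time.time() - t0, 3)
        _log(f"mesh: {mesh.n_elements} elements, {mesh.n_nodes} nodes")

        stage = "materials"
        materials = load_material_table(config.materials)
        stage = "distance field"
        dist = distance_to_calc(mesh)

        report = {
            "package_version": __version__,
            "config": config.echo(),
            "config_hash": config.config_hash(),
            "n_elements": int(mesh.n_elements),
            "n_nodes": int(mesh.n_nodes),
            "load_cases": {},
        }
        mesh_file = out / "mesh.vtu"
        write_vtu(mesh, mesh_file, cell_data={"dist_to_calc_mm": dist})

        for p in config.load_cases_mmhg:
            name = _CASE_NAMES.get(p, f"p{p:g}mmHg")
            stage = f"solve ({name})"
            ts = time.time()
            sol = solve_quasistatic(mesh, materials, LoadCase(p, name), config.solver)
            timings[f"solve_{name}_s"] = round(time.time() - ts, 3)
            stage = f"stretch analysis ({name})"
            stretch = principal_stretch(sol, mesh)
            rep = zone_statistics(
                stretch, dist, mesh,
                threshold_mm=config.analysis.threshold_mm,
                reference_pct=config.analysis.reference_pct,
            )
            write_vtu(
                mesh, out / f"solution_{name}.vtu",
                point_data={"displacement": sol.displacement_mm},
                cell_data={
                    "principal_stretch_pct": stretch.stretch_pct,
                    "dist_to_calc_mm": dist,
                },
            )
            for angle in config.analysis.profile_angles_deg:
                prof = profile_along_line(stretch, mesh, angle_deg=angle)
                prof.to_csv(
                    out / f"profile_{name}_{int(round(angle))}deg.csv", index=False
                )
            report["load_cases"][name] = rep.to_dict()
            _log(
                f"{name}: far/near MATX stretch ratio = "
                f"{rep.far_near_ratio if rep.far_near_ratio is not None else 'n/a'}"
            )
    except SolverError:
        raise
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    write_report_json(report, out / "report.json")
    manifest = {
        "package_version": __version__,
        "config_hash": report["config_hash"],
        "seed": config.seed,
        "timings_s": timings,
        "python": sys.version.split()[0],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
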