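"""Small deterministic fixture geometries, meshes and configs for testing."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .geometry import LabeledMesh, generate_cross_section, mesh_geometry
from .config import GEOMETRY_PRESETS
from .io import write_vtu
from .labels import TissueLabel

__all__ = ["unit_square_patch", "make_fixtures"]


def unit_square_patch(n: int = 2) -> LabeledMesh:
    """An n x n unit-square patch of quadratic triangles (MATX), for affine
    displacement tests; boundary tags are empty placeholders."""
    xs = np.linspace(0.0, 1.0, 2 * n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    nid = lambda i, j: i * (2 * n + 1) + j
    elements = []
    for ci in range(n):
        for cj in range(n):
            i, j = 2 * ci, 2 * cj
            # two triangles per cell, quadratic nodes on the half-grid
            elements.append(
                [nid(i, j), nid(i + 2, j), nid(i + 2, j + 2),
                 nid(i + 1, j), nid(i + 2, j + 1), nid(i + 1, j + 1)]
            )
            elements.append(
                [nid(i, j), nid(i + 2, j + 2), nid(i, j + 2),
                 nid(i + 1, j + 1), nid(i + 1, j + 2), nid(i, j + 1)]
            )
    return LabeledMesh(
        nodes=nodes,
        elements=np.asarray(elements, dtype=np.int64),
        element_labels=np.full(len(elements), int(TissueLabel.MATX), dtype=np.int64),
        boundary_edges={
            "LUMEN": np.empty((0, 3), dtype=np.int64),
            "OUTER": np.empty((0, 3), dtype=np.int64),
        },
        characteristic_h=1.0 / n,
    )


_FIXTURES = {
    "annulus": {"geometry": "annulus", "target_h_mm": 0.2},
    "reference_stenotic": {"geometry": "reference_stenotic", "target_h_mm": 0.3},
    "stenotic_no_calc": {"geometry": "stenotic_no_calc", "target_h_mm": 0.3},
}


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write fixture meshes (+ ready configs) into ``out_dir``.

    Produces the concentric MATX annulus, the reference stenotic plaque, its
    no-CALC variant and a tiny unit-square patch mesh.  Bit-identical for a
    fixed seed.  Returns {name: {"mesh": path, "config": path}}.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, cfg in _FIXTURES.items():
        spec = GEOMETRY_PRESETS[cfg["geometry"]](seed=seed)
        mesh = mesh_geometry(generate_cross_section(spec), cfg["target_h_mm"])
        mesh_path = write_vtu(mesh, out / f"{name}.vtu")
        config = {
            "geometry": {"preset": cfg["geometry"], "seed": seed},
            "target_h_mm": cfg["target_h_mm"],
            "materials": "table2",
            "load_cases_mmhg": [80.0, 140.0],
            "output_dir": str(out / f"{name}_out"),
            "seed": seed,
        }
        cfg_path = out / f"{name}.yaml"
        cfg_path.write_text(yaml.safe_dump(config, sort_keys=True))
        written[name] = {"mesh": mesh_path, "config": cfg_path}
    patch = unit_square_patch(2)
    written["patch"] = {"mesh": write_vtu(patch, out / "patch.vtu"), "config": None}
    return written
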