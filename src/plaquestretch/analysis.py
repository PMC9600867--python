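"""Principal tissue stretch: fields, centerline profiles, CALC-proximity zones.

"Principal tissue stretch" is the maximum in-plane principal stretch
lambda_1 = sqrt(max eig F^T F), with F the quadrature-point-averaged
deformation gradient of each element, reported as percent elongation
(lambda_1 - 1) x 100.  The out-of-plane stretch is identically 1 under
plane strain and is excluded so that in-plane compression remains visible
(lambda_1 < 1 is possible and meaningful).

The zone summary splits MATX elements at a distance threshold from the
nearest macro-calcification (default 1 mm) and reports the mean stretch of
each zone, the far/near ratio (the stretch-shielding readout) and the
fraction of elements above a reference stretch line (default 12.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from . import fem_core
from .geometry import LabeledMesh
from .labels import TissueLabel
from .solver import SolutionField

__all__ = [
    "StretchField",
    "StretchReport",
    "principal_stretch",
    "profile_along_line",
    "zone_statistics",
]


@dataclass
class StretchField:
    """Per-element maximum in-plane principal stretch for one load case."""

    lambda1: np.ndarray      # (n_el,)
    load_case: str

    @property
    def stretch_pct(self) -> np.ndarray:
        return (self.lambda1 - 1.0) * 100.0


def principal_stretch(solution: SolutionField, mesh: LabeledMesh) -> StretchField:
    """Per-element principal stretch from the quadrature-averaged F."""
    if not solution.converged:
        raise ValueError("refusing to post-process a non-converged solution")
    gradN, _ = fem_core.element_gradients(
        mesh.nodes, mesh.elements, solution.settings.n_quad
    )
    u_el = solution.displacement_mm[mesh.elements]
    F2 = fem_core.deformation_gradients(u_el, gradN).mean(axis=1)  # (nel, 2, 2)
    C = np.swapaxes(F2, -1, -2) @ F2
    # closed-form largest eigenvalue of symmetric 2x2
    tr = C[:, 0, 0] + C[:, 1, 1]
    disc = np.sqrt(
        np.maximum(0.0, (C[:, 0, 0] - C[:, 1, 1]) ** 2 + 4.0 * C[:, 0, 1] ** 2)
    )
    lam1 = np.sqrt(0.5 * (tr + disc))
    return StretchField(lambda1=lam1, load_case=solution.load.name)


def _lumen_polygon(mesh: LabeledMesh) -> Polygon:
    edges = mesh.boundary_edges["LUMEN"]
    # edges are CCW-ordered and contiguous by construction
    order = np.argsort(edges[:, 0], kind="stable")
    ring = []
    nxt = {int(a): (int(b), int(m)) for a, b, m in edges}
    start = int(edges[0, 0])
    cur = start
    while True:
        b, m = nxt[cur]
        ring.append(mesh.nodes[cur])
        ring.append(mesh.nodes[m])
        cur = b
        if cur == start:
            break
    return Polygon(np.asarray(ring))


def profile_along_line(
    stretch: StretchField,
    mesh: LabeledMesh,
    angle_deg: float = 0.0,
    step_mm: float | None = None,
) -> pd.DataFrame:
    """Sample stretch along a diametral line through the lumen center.

    Returns a DataFrame (position_mm, label, stretch_pct) ordered along the
    line; ``position_mm`` is signed arc position relative to the lumen
    center.  Lumen samples are labeled LUMEN with NaN stretch; samples
    outside the vessel are dropped.  Default sampling step is h/2.
    """
    if step_mm is None:
        step_mm = mesh.characteristic_h / 2.0
    c = np.asarray(mesh.lumen_center, dtype=float)
    u = np.array([np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))])
    half = 1.05 * np.max(np.linalg.norm(mesh.nodes - c, axis=1))
    s = np.arange(-half, half + step_mm / 2, step_mm)
    pts_xy = c + s[:, None] * u

    tris = [Polygon(mesh.nodes[t]) for t in mesh.corner_triangles()]
    tree = shapely.STRtree(tris)
    lumen = _lumen_polygon(mesh)
    pts = shapely.points(pts_xy)
    rows = []
    for k, pt in enumerate(pts):
        hit = tree.query(pt, predicate="intersects")
        if len(hit):
            el = int(hit.min())  # deterministic tie-break on shared edges
            rows.append(
                (float(s[k]), TissueLabel(mesh.element_labels[el]).name,
                 float(stretch.stretch_pct[el]))
            )
        elif lumen.covers(pt):
            rows.append((float(s[k]), "LUMEN", np.nan))
    df = pd.DataFrame(rows, columns=["position_mm", "label", "stretch_pct"])
    if df.empty:
        import warnings

        warnings.warn(f"profile line at {angle_deg} deg missed the wall entirely")
    return df


def _tissue_summary(pct: np.ndarray) -> dict:
    return {
        "n_elements": int(pct.size),
        "mean_pct": float(np.mean(pct)),
        "median_pct": float(np.median(pct)),
        "p5_pct": float(np.percentile(pct, 5)),
        "p95_pct": float(np.percentile(pct, 95)),
    }


@dataclass
class StretchReport:
    """Per-tissue and CALC-proximity-zone stretch summary for one load case."""

    load_case: str
    threshold_mm: float
    reference_pct: float
    tissues: dict            # label name -> summary dict
    zones: dict              # "near_calc" / "distant" -> summary + fraction
    far_near_ratio: float | None
    notes: list

    def to_dict(self, ndigits: int = 1) -> dict:
        """JSON-ready dict with percentages rounded to 0.1%."""

        def rnd(d):
            return {
                k: (round(v, ndigits) if isinstance(v, float) and k.endswith("_pct")
                    else round(v, 4) if isinstance(v, float) else v)
                for k, v in d.items()
            }

        return {
            "load_case": self.load_case,
            "threshold_mm": self.threshold_mm,
            "reference_pct": self.reference_pct,
            "tissues": {k: rnd(v) for k, v in self.tissues.items()},
            "zones": {k: rnd(v) for k, v in self.zones.items()},
            "far_near_ratio": (
                None if self.far_near_ratio is None else round(self.far_near_ratio, 4)
            ),
            "notes": list(self.notes),
        }


def zone_statistics(
    stretch: StretchField,
    distance: np.ndarray,
    mesh: LabeledMesh,
    threshold_mm: float = 1.0,
    reference_pct: float = 12.5,
) -> StretchReport:
    """Split MATX by proximity to CALC and summarize stretch per zone.

    ``near_calc`` holds MATX elements closer than ``threshold_mm`` to the
    nearest macro-calcification, ``distant`` the rest; the far/near mean
    ratio quantifies stretch shielding.  Fractions above ``reference_pct``
    are reported per zone and per tissue.
    """
    pct = stretch.stretch_pct
    labels = mesh.element_labels
    tissues = {}
    for lab in TissueLabel:
        m = labels == int(lab)
        if m.any():
            summ = _tissue_summary(pct[m])
            summ["fraction_above_reference"] = float(
                np.mean(pct[m] > reference_pct)
            )
            tissues[lab.name] = summ

    notes = []
    matx = labels == int(TissueLabel.MATX)
    near = matx & (distance < threshold_mm)
    far = matx & ~(distance < threshold_mm)
    zones = {}
    for name, mask in (("near_calc", near), ("distant", far)):
        if mask.any():
            summ = _tissue_summary(pct[mask])
            summ["fraction_above_reference"] = float(
                np.mean(pct[mask] > reference_pct)
            )
            zones[name] = summ
    if not near.any():
        notes.append(
            "no MATX within threshold of CALC (or no CALC present): "
            "single-zone result"
        )
    if not far.any() and near.any():
        notes.append("no distant MATX: wall dominated by CALC proximity")
    ratio = None
    if near.any() and far.any():
        near_mean = zones["near_calc"]["mean_pct"]
        if abs(near_mean) > 1e-12:
            ratio = zones["distant"]["mean_pct"] / near_mean
    assert (near.sum() + far.sum()) == matx.sum()
    return StretchReport(
        load_case=stretch.load_case,
        threshold_mm=float(threshold_mm),
        reference_pct=float(reference_pct),
        tissues=tissues,
        zones=zones,
        far_near_ratio=ratio,
        notes=notes,
    )
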