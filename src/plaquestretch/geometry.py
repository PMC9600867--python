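"""Parametric labeled plaque cross-sections and quadratic-triangle meshes.

A cross-section is a vessel-wall annulus between a circular lumen (radius
``Ri`` around ``lumen_center``) and a circular outer boundary (radius ``Ro``,
whose center may be offset along +x by the stenosis eccentricity, producing
an asymmetric wall).  CALC arcs and LRNC pools are annular sectors specified
in a normalized wall coordinate system:

* ``theta`` — angle (degrees) about the lumen center,
* ``f``     — radial fraction through the wall: 0 at the lumen boundary,
              1 at the outer boundary along the ray at angle ``theta``.

Because every region is a rectangle in (theta, f) space, meshing uses a
boundary-conforming structured grid: breakpoints in theta and f are snapped
to region edges, each parameter cell is split criss-cross into four
triangles (a center node keeps mirror-symmetric geometries mirror-symmetric
meshes), and mid-edge nodes are placed by the smooth (theta, f) -> (x, y)
map, yielding curved isoparametric 6-node triangles whose boundary nodes lie
exactly on the lumen/outer circles.  Everything is deterministic; the seed
only drives optional jitter of arc boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .labels import TissueLabel

__all__ = [
    "CalcArc",
    "LrncPool",
    "CrossSectionSpec",
    "CrossSection",
    "Region",
    "LabeledMesh",
    "GeometryError",
    "generate_cross_section",
    "mesh_geometry",
    "distance_to_calc",
    "reference_stenotic_spec",
    "annulus_spec",
]

#: minimum wall thickness retained on the thin side of an eccentric lumen, mm
MIN_WALL_MM = 0.5

#: angular resolution used when discretizing region outlines into polygons, deg
_POLY_DTHETA = 0.5


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class CalcArc:
    """Macro-calcification arc: an annular sector of the wall."""

    start_deg: float
    span_deg: float
    inner_frac: float
    thickness_frac: float

    @property
    def theta_range(self):
        return (self.start_deg, self.start_deg + self.span_deg)

    @property
    def f_range(self):
        return (self.inner_frac, self.inner_frac + self.thickness_frac)


@dataclass(frozen=True)
class LrncPool:
    """Lipid-rich necrotic core pool, specified by its sector center."""

    center_deg: float
    span_deg: float
    center_frac: float
    thickness_frac: float

    @property
    def theta_range(self):
        return (self.center_deg - self.span_deg / 2, self.center_deg + self.span_deg / 2)

    @property
    def f_range(self):
        return (
            self.center_frac - self.thickness_frac / 2,
            self.center_frac + self.thickness_frac / 2,
        )


@dataclass(frozen=True)
class CrossSectionSpec:
    """Parametric description of a labeled vessel cross-section (mm, deg)."""

    lumen_radius: float
    outer_radius: float
    lumen_center: tuple = (0.0, 0.0)
    calc_arcs: tuple = ()
    lrnc_pools: tuple = ()
    stenosis_eccentricity: float = 0.0
    jitter_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "calc_arcs", tuple(self.calc_arcs))
        object.__setattr__(self, "lrnc_pools", tuple(self.lrnc_pools))
        if not self.lumen_radius > 0:
            raise GeometryError("lumen_radius must be positive")
        if not self.outer_radius > self.lumen_radius + MIN_WALL_MM:
            raise GeometryError(
                f"outer_radius must exceed lumen_radius + {MIN_WALL_MM} mm minimum wall"
            )
        if not 0.0 <= self.stenosis_eccentricity <= 1.0:
            raise GeometryError("stenosis_eccentricity must be in [0, 1]")
        if self.eccentric_offset >= self.lumen_radius:
            raise GeometryError(
                "eccentric offset exceeds lumen radius; lumen center would leave "
                "the lumen (reduce stenosis_eccentricity)"
            )
        for name, rgn in self._named_inclusions():
            f0, f1 = rgn.f_range
            if not (0.0 < f0 < f1 < 1.0):
                raise GeometryError(
                    f"{name}: radial extent [{f0:.3f}, {f1:.3f}] must lie strictly "
                    "inside the wall (0, 1); regions may not touch the lumen or "
                    "outer boundary"
                )
            if not 0 < rgn.span_deg <= 360:
                raise GeometryError(f"{name}: angular span must be in (0, 360]")

    def _named_inclusions(self):
        out = [(f"CALC arc #{i}", a) for i, a in enumerate(self.calc_arcs)]
        out += [(f"LRNC pool #{i}", p) for i, p in enumerate(self.lrnc_pools)]
        return out

    @property
    def eccentric_offset(self) -> float:
        """Offset (mm) of the outer-circle center along +x from the lumen center."""
        return self.stenosis_eccentricity * (
            self.outer_radius - self.lumen_radius - MIN_WALL_MM
        )

    # --- wall parametrization -------------------------------------------------

    def outer_distance(self, theta_deg):
        """Distance from the lumen center to the outer circle along theta."""
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        d = self.eccentric_offset
        ud = d * np.cos(th)  # u . delta with delta = (d, 0)
        return ud + np.sqrt(ud * ud + self.outer_radius**2 - d * d)

    def wall_point(self, theta_deg, f):
        """Map wall coordinates (theta deg, radial fraction f) to xy in mm."""
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        f = np.asarray(f, dtype=float)
        r = self.lumen_radius + f * (self.outer_distance(theta_deg) - self.lumen_radius)
        cx, cy = self.lumen_center
        return np.stack([cx + r * np.cos(th), cy + r * np.sin(th)], axis=-1)


def reference_stenotic_spec(seed: int = 0) -> CrossSectionSpec:
    """Reference stenotic plaque preset.

    Eccentric lumen (wall 2-4 mm thick), one 120-degree CALC arc embedded
    mid-wall on the thick side and a 60-degree LRNC pool opposite.  Sized so
    that MATX exists both within 1 mm of CALC and farther than 1 mm away.
    """
    return CrossSectionSpec(
        lumen_radius=2.5,
        outer_radius=5.5,
        stenosis_eccentricity=0.4,
        calc_arcs=(CalcArc(start_deg=-60.0, span_deg=120.0, inner_frac=0.35,
                           thickness_frac=0.30),),
        lrnc_pools=(LrncPool(center_deg=180.0, span_deg=60.0, center_frac=0.5,
                             thickness_frac=0.3),),
        seed=seed,
    )


def annulus_spec(Ri: float = 3.0, Ro: float = 4.0) -> CrossSectionSpec:
    """Concentric homogeneous MATX annulus (solver-verification geometry)."""
    return CrossSectionSpec(lumen_radius=Ri, outer_radius=Ro)


# ---------------------------------------------------------------------------
# cross-section generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A labeled polygonal region of the wall."""

    label: TissueLabel
    name: str
    polygon: Polygon
    theta_range: tuple | None = None  # None for the MATX background
    f_range: tuple | None = None

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass(frozen=True)
class CrossSection:
    """Labeled planar geometry: regions tiling the wall annulus."""

    spec: CrossSectionSpec
    regions: tuple  # Region, MATX background first
    inclusions: tuple  # (label, name, (theta0, theta1), (f0, f1)) after jitter

    def label_at(self, theta_deg: float, f: float) -> TissueLabel:
        """Tissue label at wall coordinates; CALC wins ties, then LRNC."""
        hits = []
        for label, _name, (t0, t1), (f0, f1) in self.inclusions:
            if f0 <= f <= f1 and _angle_in(theta_deg, t0, t1):
                hits.append(label)
        if TissueLabel.CALC in hits:
            return TissueLabel.CALC
        if TissueLabel.LRNC in hits:
            return TissueLabel.LRNC
        return TissueLabel.MATX


def _wrap(theta):
    return theta % 360.0


def _angle_in(theta, t0, t1):
    """Is angle theta inside the arc [t0, t1] (t1 > t0, span <= 360)?"""
    if t1 - t0 >= 360.0 - 1e-12:
        return True
    return _wrap(theta - t0) <= (t1 - t0) + 1e-12


def _arcs_overlap(a0, a1, b0, b1):
    """Overlap test for two angular intervals on the circle."""
    for t in (a0, a1):
        if _angle_in(t, b0, b1):
            # touching endpoints are not overlap
            if not (abs(_wrap(t - b1)) < 1e-9 or abs(_wrap(b0 - t)) < 1e-9):
                return True
    for t in (b0, b1):
        if _angle_in(t, a0, a1):
            if not (abs(_wrap(t - a1)) < 1e-9 or abs(_wrap(a0 - t)) < 1e-9):
                return True
    # one fully inside the other
    mid_a = a0 + (a1 - a0) / 2
    mid_b = b0 + (b1 - b0) / 2
    return _angle_in(mid_a, b0, b1) or _angle_in(mid_b, a0, a1)


def _sector_polygon(spec, t0, t1, f0, f1) -> Polygon:
    n = max(2, int(np.ceil((t1 - t0) / _POLY_DTHETA)) + 1)
    th = np.linspace(t0, t1, n)
    inner = spec.wall_point(th, np.full_like(th, f0))
    outer = spec.wall_point(th[::-1], np.full_like(th, f1))
    return Polygon(np.vstack([inner, outer]))


def generate_cross_section(spec: CrossSectionSpec) -> CrossSection:
    """Build the labeled planar geometry for a cross-section spec.

    Returns closed, non-overlapping polygonal regions tiling the wall
    annulus; overlapping CALC/LRNC inclusions are rejected with a diagnostic
    naming the colliding regions.  Deterministic for a fixed spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    inclusions = []
    for name, rgn in spec._named_inclusions():
        t0, t1 = rgn.theta_range
        if spec.jitter_deg > 0:
            t0 += rng.uniform(-spec.jitter_deg, spec.jitter_deg)
            t1 += rng.uniform(-spec.jitter_deg, spec.jitter_deg)
            if t1 <= t0:
                t0, t1 = t1, t0
        label = TissueLabel.CALC if name.startswith("CALC") else TissueLabel.LRNC
        inclusions.append((label, name, (t0, t1), rgn.f_range))

    # pairwise overlap rejection (rectangles in (theta, f) with wraparound)
    for i in range(len(inclusions)):
        for j in range(i + 1, len(inclusions)):
            _, ni, (a0, a1), (fa0, fa1) = inclusions[i]
            _, nj, (b0, b1), (fb0, fb1) = inclusions[j]
            radial = fa0 < fb1 - 1e-12 and fb0 < fa1 - 1e-12
            if radial and _arcs_overlap(a0, a1, b0, b1):
                raise GeometryError(
                    f"overlapping inclusion regions: {ni} and {nj} collide in the "
                    "wall; adjust their angular or radial extents"
                )

    th_full = np.linspace(0.0, 360.0, int(360.0 / _POLY_DTHETA) + 1)
    inner_ring = spec.wall_point(th_full[:-1], np.zeros(len(th_full) - 1))
    outer_ring = spec.wall_point(th_full[:-1], np.ones(len(th_full) - 1))
    wall = Polygon(outer_ring, holes=[inner_ring[::-1]])

    regions = []
    incl_polys = []
    for label, name, (t0, t1), (f0, f1) in inclusions:
        poly = _sector_polygon(spec, t0, t1, f0, f1)
        incl_polys.append(poly)
        regions.append(Region(label, name, poly, (t0, t1), (f0, f1)))
    matx_poly = wall
    if incl_polys:
        matx_poly = wall.difference(shapely.unary_union(incl_polys))
    regions.insert(0, Region(TissueLabel.MATX, "MATX background", matx_poly))
    return CrossSection(spec=spec, regions=tuple(regions), inclusions=tuple(inclusions))


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

@dataclass
class LabeledMesh:
    """Conforming quadratic-triangle mesh with per-element tissue labels.

    ``elements`` lists 6-node triangles in VTK ordering: three corner nodes
    counter-clockwise, then the mid-edge nodes of edges (0,1), (1,2), (2,0).
    ``boundary_edges`` maps LUMEN / OUTER to (n_edge, 3) arrays of quadratic
    edges [n0, n1, mid], each loop oriented counter-clockwise about the
    lumen center.
    """

    nodes: np.ndarray          # (n_nodes, 2) mm
    elements: np.ndarray       # (n_el, 6) int
    element_labels: np.ndarray  # (n_el,) TissueLabel ints
    boundary_edges: dict       # {"LUMEN": (k,3) int, "OUTER": (k,3) int}
    characteristic_h: float
    lumen_center: tuple = (0.0, 0.0)

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elements)

    def corner_triangles(self) -> np.ndarray:
        return self.elements[:, :3]

    def element_centroids(self) -> np.ndarray:
        """Corner-average centroids (exact enough for labels/distances)."""
        return self.nodes[self.elements[:, :3]].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        """Areas of the curved isoparametric elements (3-point quadrature)."""
        from .fem_core import tri6_reference_data

        dN, w = tri6_reference_data(3)[1:3]
        X = self.nodes[self.elements]                 # (nel, 6, 2)
        Jac = np.einsum("eai,qaj->eqij", X, dN)       # (nel, nq, 2, 2)
        detJ = np.linalg.det(Jac)
        return detJ @ w

    def boundary_loop_nodes(self, tag: str) -> np.ndarray:
        """Ordered unique corner-node ids of a boundary loop."""
        edges = self.boundary_edges[tag]
        return edges[:, 0]

    def validate(self):
        """Raise if basic mesh invariants are violated."""
        if self.elements.max() >= self.n_nodes:
            raise GeometryError("element connectivity references missing nodes")
        v = self.nodes[self.elements[:, :3]]
        area2 = (v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1]) - (
            v[:, 2, 0] - v[:, 0, 0]
        ) * (v[:, 1, 1] - v[:, 0, 1])
        if np.any(area2 <= 0):
            bad = int(np.argmax(area2 <= 0))
            raise GeometryError(f"inverted element {bad} in reference configuration")
        if len(self.element_labels) != self.n_elements:
            raise GeometryError("element label count mismatch")
        for tag in ("LUMEN", "OUTER"):
            e = self.boundary_edges[tag]
            if not np.array_equal(np.sort(e[:, 0]), np.sort(e[:, 1])):
                raise GeometryError(f"{tag} boundary is not a closed loop")
        return self


def _dedupe(sorted_vals, tol):
    out = [sorted_vals[0]]
    for v in sorted_vals[1:]:
        if v - out[-1] > tol:
            out.append(v)
    return out


def _breakpoints_theta(cross: CrossSection):
    pts = {0.0}
    for _label, _n, (t0, t1), _f in cross.inclusions:
        pts.add(_wrap(t0))
        pts.add(_wrap(t1))
    bp = _dedupe(sorted(pts), tol=1e-9)
    if len(bp) > 1 and bp[0] + 360.0 - bp[-1] <= 1e-9:  # wraparound duplicate
        bp.pop()
    bp.append(bp[0] + 360.0)
    return bp


def _breakpoints_f(cross: CrossSection):
    pts = {0.0, 1.0}
    for _label, _n, _t, (f0, f1) in cross.inclusions:
        pts.add(f0)
        pts.add(f1)
    return _dedupe(sorted(pts), tol=1e-9)


def mesh_geometry(cross: CrossSection, target_h: float) -> LabeledMesh:
    """Mesh a labeled cross-section with curved quadratic triangles.

    The structured grid conforms to every region boundary, so each element
    lies wholly inside one region and is labeled by the region containing
    its parameter-space center (CALC > LRNC > MATX on exact ties).
    """
    if not target_h > 0:
        raise GeometryError("target_h must be positive")
    spec = cross.spec
    r_max = spec.lumen_radius + (spec.outer_distance(0.0) - spec.lumen_radius)
    t_max = float(np.max(spec.outer_distance(np.linspace(0, 360, 721)))) - spec.lumen_radius

    # refined breakpoint lists
    th_bp = _breakpoints_theta(cross)
    thetas = []
    for a, b in zip(th_bp[:-1], th_bp[1:]):
        n = max(1, int(np.ceil(np.deg2rad(b - a) * r_max / target_h)))
        thetas.extend(np.linspace(a, b, n + 1)[:-1])
    thetas = np.array(thetas)  # periodic: closing value omitted

    f_bp = _breakpoints_f(cross)
    fs = [0.0]
    for a, b in zip(f_bp[:-1], f_bp[1:]):
        n = max(1, int(np.ceil((b - a) * t_max / target_h)))
        fs.extend(np.linspace(a, b, n + 1)[1:])
    fs = np.array(fs)

    ntheta, nf = len(thetas), len(fs)
    # grid vertices
    TH, FF = np.meshgrid(thetas, fs, indexing="ij")  # (ntheta, nf)
    grid_xy = spec.wall_point(TH.ravel(), FF.ravel())
    vid = np.arange(ntheta * nf).reshape(ntheta, nf)

    nodes = [grid_xy]
    next_id = ntheta * nf
    elements = []
    labels = []
    edge_mid = {}

    def add_node(theta, f):
        nonlocal next_id
        nodes.append(spec.wall_point(theta, f)[None, :])
        next_id += 1
        return next_id - 1

    def midpoint(na, nb, pa, pb):
        key = (na, nb) if na < nb else (nb, na)
        nid = edge_mid.get(key)
        if nid is None:
            nid = add_node((pa[0] + pb[0]) / 2.0, (pa[1] + pb[1]) / 2.0)
            edge_mid[key] = nid
        return nid

    thetas_ext = np.append(thetas, thetas[0] + 360.0)
    lumen_edges = []
    outer_edges = []

    for i in range(ntheta):
        i2 = (i + 1) % ntheta
        t0, t1 = thetas_ext[i], thetas_ext[i + 1]
        for j in range(nf - 1):
            f0, f1 = fs[j], fs[j + 1]
            # (theta, f) -> (x, y) reverses orientation, so walk f before theta
            corner_ids = [vid[i, j], vid[i, j + 1], vid[i2, j + 1], vid[i2, j]]
            corner_par = [(t0, f0), (t0, f1), (t1, f1), (t1, f0)]
            tc, fc = (t0 + t1) / 2.0, (f0 + f1) / 2.0
            cid = add_node(tc, fc)
            label = int(cross.label_at(_wrap(tc), fc))
            for k in range(4):
                k2 = (k + 1) % 4
                a, b = corner_ids[k], corner_ids[k2]
                pa, pb = corner_par[k], corner_par[k2]
                m_ab = midpoint(a, b, pa, pb)
                m_bc = midpoint(b, cid, pb, (tc, fc))
                m_ca = midpoint(cid, a, (tc, fc), pa)
                elements.append([a, b, cid, m_ab, m_bc, m_ca])
                labels.append(label)
            if j == 0:  # lumen loop, oriented CCW (increasing theta)
                lumen_edges.append(
                    [corner_ids[0], corner_ids[3],
                     edge_mid[tuple(sorted((corner_ids[0], corner_ids[3])))]]
                )
            if j == nf - 2:
                outer_edges.append(
                    [corner_ids[1], corner_ids[2],
                     edge_mid[tuple(sorted((corner_ids[1], corner_ids[2])))]]
                )

    mesh = LabeledMesh(
        nodes=np.vstack(nodes),
        elements=np.asarray(elements, dtype=np.int64),
        element_labels=np.asarray(labels, dtype=np.int64),
        boundary_edges={
            "LUMEN": np.asarray(lumen_edges, dtype=np.int64),
            "OUTER": np.asarray(outer_edges, dtype=np.int64),
        },
        characteristic_h=float(target_h),
        lumen_center=tuple(spec.lumen_center),
    )
    return mesh.validate()


# ---------------------------------------------------------------------------
# distance to calcification
# ---------------------------------------------------------------------------

def distance_to_calc(mesh: LabeledMesh) -> np.ndarray:
    """Per-element distance (mm) from the centroid to the nearest CALC boundary.

    CALC elements have distance 0; with no CALC anywhere, every distance is
    +inf.  Exact to within one element diameter (centroid-to-polygon
    distance against the union of CALC element triangles).
    """
    dist = np.full(mesh.n_elements, np.inf)
    calc_mask = mesh.element_labels == int(TissueLabel.CALC)
    if not calc_mask.any():
        return dist
    dist[calc_mask] = 0.0
    other = ~calc_mask
    if not other.any():
        return dist
    calc_polys = [
        Polygon(mesh.nodes[tri]) for tri in mesh.corner_triangles()[calc_mask]
    ]
    tree = shapely.STRtree(calc_polys)
    centroids = mesh.element_centroids()[other]
    pts = shapely.points(centroids)
    idx, d = tree.query_nearest(pts, return_distance=True, all_matches=False)
    other_ids = np.where(other)[0]
    dist[other_ids[idx[0]]] = d
    return dist
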