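"""Synthetic cross-sections, structured quadratic meshing, distance fields."""

import numpy as np
import pytest

import plaquestretch as ps
from plaquestretch.geometry import (
    CalcArc,
    CrossSectionSpec,
    GeometryError,
    LrncPool,
    distance_to_calc,
    generate_cross_section,
    mesh_geometry,
)
from plaquestretch.labels import TissueLabel


class TestCrossSectionSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(GeometryError, match="lumen_radius"):
            CrossSectionSpec(lumen_radius=-1.0, outer_radius=4.0)
        with pytest.raises(GeometryError, match="minimum wall"):
            CrossSectionSpec(lumen_radius=3.0, outer_radius=3.2)
        with pytest.raises(GeometryError, match="radial extent"):
            CrossSectionSpec(
                lumen_radius=3.0, outer_radius=4.0,
                calc_arcs=(CalcArc(0, 90, 0.0, 0.5),),  # touches the lumen
            )
        with pytest.raises(GeometryError, match="stenosis_eccentricity"):
            CrossSectionSpec(lumen_radius=3.0, outer_radius=4.0,
                             stenosis_eccentricity=1.4)

    def test_overlapping_inclusions_rejected_with_names(self):
        spec = CrossSectionSpec(
            lumen_radius=3.0, outer_radius=5.0,
            calc_arcs=(CalcArc(0, 90, 0.3, 0.3),),
            lrnc_pools=(LrncPool(45, 60, 0.45, 0.2),),
        )
        with pytest.raises(GeometryError) as exc:
            generate_cross_section(spec)
        assert "CALC arc #0" in str(exc.value)
        assert "LRNC pool #0" in str(exc.value)


class TestGenerateCrossSection:
    def test_empty_inclusions_single_matx_annulus(self):
        cross = generate_cross_section(ps.annulus_spec(3.0, 4.0))
        assert len(cross.regions) == 1
        region = cross.regions[0]
        assert region.label is TissueLabel.MATX
        assert region.area == pytest.approx(np.pi * (16 - 9), rel=1e-4)

    def test_deterministic_for_fixed_seed(self):
        spec = ps.reference_stenotic_spec(seed=4)
        a = generate_cross_section(spec)
        b = generate_cross_section(spec)
        for ra, rb in zip(a.regions, b.regions):
            assert ra.polygon.equals_exact(rb.polygon, 0.0)
        assert a.inclusions == b.inclusions

    def test_jitter_is_seeded(self):
        base = dict(lumen_radius=3.0, outer_radius=5.0,
                    calc_arcs=(CalcArc(0, 90, 0.3, 0.3),), jitter_deg=5.0)
        a = generate_cross_section(CrossSectionSpec(**base, seed=1))
        b = generate_cross_section(CrossSectionSpec(**base, seed=1))
        c = generate_cross_section(CrossSectionSpec(**base, seed=2))
        assert a.inclusions == b.inclusions
        assert a.inclusions != c.inclusions

    def test_calc_sector_area_matches_annular_sector_formula(self):
        """90-degree arc, half wall thickness: closed-form sector area."""
        Ri, Ro, f0, ft = 3.0, 5.0, 0.25, 0.5
        spec = CrossSectionSpec(
            lumen_radius=Ri, outer_radius=Ro,
            calc_arcs=(CalcArc(10.0, 90.0, f0, ft),),
        )
        cross = generate_cross_section(spec)
        calc = [r for r in cross.regions if r.label is TissueLabel.CALC][0]
        r0 = Ri + f0 * (Ro - Ri)
        r1 = Ri + (f0 + ft) * (Ro - Ri)
        exact = 0.25 * np.pi * (r1**2 - r0**2)
        assert calc.area == pytest.approx(exact, rel=0.02)


class TestMeshGeometry:
    def test_pure_annulus_all_matx_with_closed_loops(self, annulus_cross):
        mesh = mesh_geometry(annulus_cross, 0.4)
        assert np.all(mesh.element_labels == int(TissueLabel.MATX))
        for tag in ("LUMEN", "OUTER"):
            edges = mesh.boundary_edges[tag]
            # closed loop: every start node is an end node exactly once
            assert np.array_equal(np.sort(edges[:, 0]), np.sort(edges[:, 1]))
        # lumen corner nodes lie exactly on the lumen circle
        ids = np.unique(mesh.boundary_edges["LUMEN"][:, :2])
        assert np.allclose(np.linalg.norm(mesh.nodes[ids], axis=1), 3.0, atol=1e-12)

    def test_area_conservation(self, annulus_cross):
        mesh = mesh_geometry(annulus_cross, 0.2)
        assert mesh.element_areas().sum() == pytest.approx(
            np.pi * (16 - 9), rel=0.01
        )

    def test_refinement_factor(self, annulus_cross):
        n1 = mesh_geometry(annulus_cross, 0.4).n_elements
        n2 = mesh_geometry(annulus_cross, 0.2).n_elements
        assert 3.0 <= n2 / n1 <= 5.0

    def test_calc_area_conserved_under_meshing(self, ref_cross, ref_mesh):
        calc_poly_area = sum(
            r.area for r in ref_cross.regions if r.label is TissueLabel.CALC
        )
        calc_mesh_area = ref_mesh.element_areas()[
            ref_mesh.element_labels == int(TissueLabel.CALC)
        ].sum()
        assert calc_mesh_area == pytest.approx(calc_poly_area, rel=0.05)

    def test_label_partition(self, ref_mesh):
        counts = [
            int(np.sum(ref_mesh.element_labels == int(lab))) for lab in TissueLabel
        ]
        assert sum(counts) == ref_mesh.n_elements
        assert all(c > 0 for c in counts)

    def test_meshing_deterministic(self, ref_cross):
        a = mesh_geometry(ref_cross, 0.4)
        b = mesh_geometry(ref_cross, 0.4)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.elements, b.elements)
        assert np.array_equal(a.element_labels, b.element_labels)

    def test_mirror_symmetric_geometry_gives_mirror_symmetric_mesh(
        self, symmetric_calc_mesh
    ):
        nodes = symmetric_calc_mesh.nodes
        mirrored = nodes * [1.0, -1.0]
        # every node has a mirror partner (sort on rounded keys to avoid
        # tie-break flips on ~1e-16 coordinate noise)
        key = np.round(nodes, 9)
        key_m = np.round(mirrored, 9)
        order = np.lexsort((key[:, 1], key[:, 0]))
        order_m = np.lexsort((key_m[:, 1], key_m[:, 0]))
        assert np.allclose(nodes[order], mirrored[order_m], atol=1e-9)

    def test_invalid_target_h(self, annulus_cross):
        with pytest.raises(GeometryError, match="target_h"):
            mesh_geometry(annulus_cross, -0.1)


class TestDistanceToCalc:
    def test_no_calc_all_infinite(self, annulus_mesh_coarse):
        dist = distance_to_calc(annulus_mesh_coarse)
        assert np.all(np.isinf(dist))

    def test_calc_elements_zero_and_rest_nonnegative(self, ref_mesh, ref_dist):
        calc = ref_mesh.element_labels == int(TissueLabel.CALC)
        assert np.all(ref_dist[calc] == 0.0)
        assert np.all(ref_dist[~calc] > 0.0)
        assert np.all(np.isfinite(ref_dist))

    def test_full_ring_calc_distance_matches_radial_gap(self):
        """Full-ring CALC layer: distance from inner MATX is radial, known
        in closed form (r_calc_inner - r)."""
        Ri, Ro = 3.0, 5.0
        spec = CrossSectionSpec(
            lumen_radius=Ri, outer_radius=Ro,
            calc_arcs=(CalcArc(0.0, 360.0, 0.5, 0.25),),
        )
        mesh = mesh_geometry(generate_cross_section(spec), 0.3)
        dist = distance_to_calc(mesh)
        r_calc0 = Ri + 0.5 * (Ro - Ri)
        cent = mesh.element_centroids()
        r = np.linalg.norm(cent, axis=1)
        inner = (mesh.element_labels == int(TissueLabel.MATX)) & (r < r_calc0)
        h_diam = 2 * 0.3
        assert np.all(np.abs(dist[inner] - (r_calc0 - r[inner])) < h_diam)

    def test_against_brute_force_centroid_distances(self):
        """On a small mesh, distance is bracketed by brute-force
        centroid-to-centroid distances +/- one element diameter."""
        spec = CrossSectionSpec(
            lumen_radius=3.0, outer_radius=4.5,
            calc_arcs=(CalcArc(30.0, 60.0, 0.3, 0.4),),
        )
        mesh = mesh_geometry(generate_cross_section(spec), 0.8)
        assert mesh.n_elements <= 500
        dist = distance_to_calc(mesh)
        cent = mesh.element_centroids()
        calc = mesh.element_labels == int(TissueLabel.CALC)
        brute = np.min(
            np.linalg.norm(cent[:, None, :] - cent[None, calc, :], axis=2), axis=1
        )
        diam = 2 * 0.8
        assert np.all(dist <= brute + 1e-12)          # boundary closer than centroid
        assert np.all(brute - dist <= diam)           # but not by more than a diameter
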