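"""Shared fixtures: geometries, meshes and (expensive, session-scoped) solves."""

import pytest

import plaquestretch as ps
from plaquestretch.fixtures import unit_square_patch
from plaquestretch.geometry import CalcArc
from plaquestretch.labels import TissueLabel
from plaquestretch.solver import LoadCase

REF_H = 0.3  # mm, desk-scale mesh for the reference stenotic geometry


@pytest.fixture(scope="session")
def presets():
    return ps.table2_presets()


@pytest.fixture(scope="session")
def patch_mesh():
    return unit_square_patch(2)


@pytest.fixture(scope="session")
def annulus_cross():
    return ps.generate_cross_section(ps.annulus_spec(3.0, 4.0))


@pytest.fixture(scope="session")
def annulus_mesh(annulus_cross):
    return ps.mesh_geometry(annulus_cross, 0.2)


@pytest.fixture(scope="session")
def annulus_mesh_coarse(annulus_cross):
    return ps.mesh_geometry(annulus_cross, 0.4)


@pytest.fixture(scope="session")
def annulus_sol_80(annulus_mesh, presets):
    return ps.solve_quasistatic(annulus_mesh, presets, LoadCase(80.0, "diastole"))


@pytest.fixture(scope="session")
def symmetric_calc_mesh():
    """Concentric annulus with one CALC arc mirror-symmetric about the x-axis."""
    spec = ps.CrossSectionSpec(
        lumen_radius=3.0,
        outer_radius=4.5,
        calc_arcs=(CalcArc(start_deg=-45.0, span_deg=90.0, inner_frac=0.3,
                           thickness_frac=0.4),),
    )
    return ps.mesh_geometry(ps.generate_cross_section(spec), 0.4)


@pytest.fixture(scope="session")
def ref_cross():
    return ps.generate_cross_section(ps.reference_stenotic_spec())


@pytest.fixture(scope="session")
def ref_mesh(ref_cross):
    return ps.mesh_geometry(ref_cross, REF_H)


@pytest.fixture(scope="session")
def ref_dist(ref_mesh):
    return ps.distance_to_calc(ref_mesh)


@pytest.fixture(scope="session")
def ref_sol_systole(ref_mesh, presets):
    return ps.solve_quasistatic(ref_mesh, presets, LoadCase(140.0, "systole"))


@pytest.fixture(scope="session")
def ref_sol_diastole(ref_mesh, presets):
    return ps.solve_quasistatic(ref_mesh, presets, LoadCase(80.0, "diastole"))


@pytest.fixture(scope="session")
def ref_sol_systole_calc_as_matx(ref_mesh, presets):
    """Systole with CALC given MATX properties (geometry unchanged)."""
    table = presets.substitute(TissueLabel.CALC, presets[TissueLabel.MATX])
    return ps.solve_quasistatic(ref_mesh, table, LoadCase(140.0, "systole"))
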