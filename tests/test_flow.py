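"""Brinkman flow solver on the arteriole-venule unit."""
import numpy as np
import pytest

from glymphsim.flow import (FlowBoundaryConditions, flow_summary, solve_flow)
from glymphsim.geometry import AVUnitGeometry, FacetTag, build_geometry
from glymphsim.grid import UM
from glymphsim.materials import FluidProperties, assign_materials

H = 10.0  # coarse test resolution, µm


@pytest.fixture(scope="module")
def unit():
    mesh = build_geometry(AVUnitGeometry(), H)
    mat = assign_materials(mesh)
    return mesh, mat


def test_null_forcing_gives_rest(unit):
    mesh, mat = unit
    bc = FlowBoundaryConditions(pas_inlet_velocity=0.0, pvs_outlet_velocity=0.0,
                                av_pressure_gradient=0.0)
    sol = solve_flow(mesh, mat, FluidProperties(), bc)
    assert np.abs(sol.speed()).max() < 1e-15
    assert np.abs(sol.pressure - sol.pressure[~mesh.solid].mean()).max() < 1e-9


def test_baseline_flow_field(unit):
    mesh, mat = unit
    sol = solve_flow(mesh, mat, FluidProperties(), FlowBoundaryConditions())
    # global balance and pointwise incompressibility
    assert sol.diagnostics["relative_flux_imbalance"] < 1e-6
    assert sol.diagnostics["max_div_flux_fraction"] < 1e-6
    # no-slip on the vessel walls: every face touching a lumen cell is at rest
    u, v, w = sol.face_velocity
    solid = mesh.solid
    assert np.abs(u[:-1][solid]).max() == 0
    assert np.abs(u[1:][solid]).max() == 0
    assert np.abs(w[:, :, :-1][solid]).max() == 0
    # imposed PAS inflow: boundary integral equals velocity x meshed inlet area
    tags = mesh.facet_tags["z+"]
    pas_faces = tags == int(FacetTag.PAS_INLET)
    q = sol.boundary_outflux("z+", where=pas_faces)
    area = pas_faces.sum() * mesh.grid.face_area(2) * UM ** 2
    assert -q == pytest.approx(18.7e-6 * area, rel=1e-9)
    # ... and matches the analytic annulus area to staircase accuracy
    g = mesh.geom
    ann = np.pi * (g.pas_outer_radius() ** 2 - g.arteriole_radius ** 2) * UM ** 2
    assert -q == pytest.approx(18.7e-6 * ann, rel=0.15)
    # speed in the PAS is of the order of the imposed inflow
    rep = flow_summary(sol, mesh)
    assert 0.4 * 18.7 < rep["max_speed_pas_um_s"] < 1.5 * 18.7


def test_permeability_monotonicity(unit):
    """Raising parenchymal permeability must not decrease the net
    arteriole-to-venule volumetric flux."""
    from dataclasses import replace

    from glymphsim.geometry import RegionLabel
    from glymphsim.materials import default_region_properties

    mesh, _ = unit
    fluxes = []
    for k in (1e-12, 1e-11):
        props = default_region_properties()
        props[RegionLabel.PARENCHYMA] = replace(props[RegionLabel.PARENCHYMA],
                                                permeability=k)
        mat = assign_materials(mesh, props)
        sol = solve_flow(mesh, mat, FluidProperties(), FlowBoundaryConditions())
        fluxes.append(sol.plane_flux(0.5 * mesh.geom.vessel_separation))
    assert fluxes[1] >= fluxes[0]


def test_fus_increases_intervessel_flux():
    geom = AVUnitGeometry()
    base_mesh = build_geometry(geom, H, fus_on=False)
    fus_mesh = build_geometry(geom, H, fus_on=True)
    from glymphsim.materials import FUSPerturbation

    b = solve_flow(base_mesh, assign_materials(base_mesh), FluidProperties(),
                   FlowBoundaryConditions())
    f = solve_flow(fus_mesh, assign_materials(fus_mesh, fus=FUSPerturbation()),
                   FluidProperties(), FlowBoundaryConditions())
    mid = 0.5 * geom.vessel_separation
    assert f.plane_flux(mid) > b.plane_flux(mid)


def test_mixed_bc_mode(unit):
    """Mixed mode: PAS velocity + open PVS outlet at the offset pressure.
    The perivenous outflow must be positive (out of the domain)."""
    mesh, mat = unit
    bc = FlowBoundaryConditions(bc_mode="mixed")
    sol = solve_flow(mesh, mat, FluidProperties(), bc)
    tags = mesh.facet_tags["z+"]
    q = sol.boundary_outflux("z+", where=tags == int(FacetTag.PVS_OUTLET))
    assert q > 0


def test_bad_bc_rejected():
    with pytest.raises(ValueError):
        FlowBoundaryConditions(pas_inlet_velocity=-1.0)
    with pytest.raises(ValueError):
        FlowBoundaryConditions(bc_mode="weird")
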