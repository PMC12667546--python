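"""Transport: initial conditions, stepping kernel, conservation, t95."""
import numpy as np
import pytest

from glymphsim.geometry import AVUnitGeometry, RegionLabel, build_geometry
from glymphsim.grid import UM, StructuredGrid
from glymphsim.materials import SOLUTES, assign_materials
from glymphsim.transport import (ConfigurationError, InitialDistribution,
                                 TransportOperator, init_concentration,
                                 integrate_operator)
from glymphsim.verification import _free_operator


@pytest.fixture(scope="module")
def unit():
    mesh = build_geometry(AVUnitGeometry(), 10.0)
    return mesh, assign_materials(mesh)


def test_uniform_initial_mass(unit):
    """Uniform load: M(0) = ε_parenchyma x V_parenchyma x c0."""
    mesh, mat = unit
    st = init_concentration(mesh, InitialDistribution(kind="uniform", c0=1.0))
    v_par = mesh.region_volumes()[RegionLabel.PARENCHYMA] * UM ** 3
    assert st.mass0 == pytest.approx(0.20 * v_par, rel=1e-9)
    v_analytic = mesh.analytic_region_volumes()[RegionLabel.PARENCHYMA] * UM ** 3
    assert st.mass0 == pytest.approx(0.20 * v_analytic, rel=0.02)


def test_initial_mass_ordering(unit):
    """Same c0: the uniform distribution holds strictly more mass than the
    centralized bolus (it fills the whole parenchyma)."""
    mesh, _ = unit
    uni = init_concentration(mesh, InitialDistribution(kind="uniform"))
    cen = init_concentration(mesh, InitialDistribution(kind="centralized"))
    assert uni.mass0 > cen.mass0 > 0


def test_tiny_bolus_mass_vanishes(unit):
    mesh, _ = unit
    st = init_concentration(mesh, InitialDistribution(kind="centralized",
                                                      bolus_radius=1e-6))
    assert st.mass0 == 0.0


def test_bolus_must_fit_parenchyma(unit):
    mesh, _ = unit
    with pytest.raises(ConfigurationError, match="bolus"):
        init_concentration(mesh, InitialDistribution(kind="centralized",
                                                     bolus_radius=120.0))


def test_uniform_field_in_closed_box_is_stationary():
    g = StructuredGrid.from_box(((0, 40), (0, 40), (0, 8)), (4, 4, 8))
    op = _free_operator(g, D=1e-9, noflux=True)
    c = np.ones(g.shape)
    out = op.step(c, 0.5)
    assert np.allclose(out, c, atol=1e-13)
    assert op.mass(out) == pytest.approx(op.mass(c), rel=1e-12)


def test_plug_flow_translates_centroid():
    """Pure advection: a pulse's centroid moves by U·t (mass-weighted first
    moment is exact for the conservative upwind flux)."""
    g = StructuredGrid.from_box(((0, 400), (0, 4), (0, 4)), (2, 4, 4))
    U = 10e-6  # m/s
    shape = g.shape
    face_q, face_G = [], []
    for a in range(3):
        fshape = tuple(s + (a == i) for i, s in enumerate(shape))
        A = g.face_area(a) * UM ** 2
        face_q.append(np.full(fshape, U * A if a == 0 else 0.0))
        face_G.append(np.zeros(fshape))
    vol = np.full(shape, g.cell_volume * UM ** 3)
    op = TransportOperator(g, np.zeros(shape, bool), vol.copy(), face_G, face_q,
                           side_kinds={s: "open" for s in
                                       ("x-", "x+", "y-", "y+", "z-", "z+")},
                           cell_epsD=np.zeros(shape),
                           conv_weight=np.full(shape, U) * vol, vol_weight=vol)
    x = g.centers(0)[:, None, None] * UM
    c = np.exp(-0.5 * ((x - 100e-6) / 20e-6) ** 2) * np.ones(shape)

    def centroid(f):
        m = op.storage * f
        return float((m * x).sum() / m.sum())

    x0 = centroid(c)
    t, dt = 0.0, 0.1
    while t < 5.0 - 1e-9:
        c = op.step(c, dt)
        t += dt
    assert centroid(c) - x0 == pytest.approx(U * 5.0, rel=0.02)


def test_zero_clearance_fraction_is_instant():
    g = StructuredGrid.from_box(((0, 40), (0, 40), (0, 8)), (4, 4, 8))
    op = _free_operator(g, D=1e-9, noflux=True)
    series = integrate_operator(op, np.ones(g.shape), clearance_fraction=0.0)
    assert series.t95 == 0.0
    assert series.fraction_remaining[0] == 1.0


def test_clearance_time_ordering_by_diffusivity():
    """Pure diffusion to absorbing walls: t95 ordering follows 1/D across the
    three modelled solutes (tracer fastest, amyloid-β slowest)."""
    g = StructuredGrid.from_box(((0, 100), (0, 100), (0, 4)), (5, 5, 4))
    t95 = {}
    for name, spec in SOLUTES.items():
        op = _free_operator(g, D=spec.diffusivity, absorb_xy=True, noflux=False)
        series = integrate_operator(op, np.ones(g.shape), dt0=0.01)
        t95[name] = series.t95
    assert t95["tracer"] < t95["alpha_synuclein"] < t95["amyloid_beta"]
    # and quantitatively as 1/D (identical geometry, pure diffusion)
    r = t95["amyloid_beta"] / t95["tracer"]
    assert r == pytest.approx(1e-9 / 1.8e-10, rel=0.05)


def test_scenario_mass_audit_and_positivity(coarse_suite):
    """Discrete conservation: cleared mass equals the time-integrated boundary
    outflux, and the implicit hybrid scheme never undershoots materially."""
    _, results = coarse_suite
    for res in results.values():
        s = res.series
        audit = abs((s.mass[0] - s.mass[-1]) - s.outflux_integral) / s.mass[0]
        assert audit < 0.01
        for c in s.snapshots.values():
            assert c.min() >= -1e-3
        # fraction remaining is monotone after the first step
        assert np.all(np.diff(s.fraction_remaining) <= 1e-3)


def test_dt_halving_leaves_t95_unchanged():
    """t95 from the geometric-step integrator is step-size converged: halving
    dt0 and the relative cap moves t95 by <1%."""
    from glymphsim.scenarios import ScenarioConfig, run_scenario
    from dataclasses import replace

    cfg = ScenarioConfig(condition="baseline", distribution="uniform",
                         resolution=12.0)
    a = run_scenario(cfg)
    b = run_scenario(replace(cfg, dt0=cfg.dt0 / 2, dt_rel=cfg.dt_rel / 2))
    assert b.t95 == pytest.approx(a.t95, rel=0.01)
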