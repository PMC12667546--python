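"""Materials: property maps, FUS perturbation arithmetic, face coefficients."""
import numpy as np
import pytest

from glymphsim.geometry import AVUnitGeometry, RegionLabel, build_geometry
from glymphsim.materials import (SOLUTES, FUSPerturbation, MaterialError,
                                 RegionProperties, assign_materials,
                                 default_region_properties,
                                 effective_diffusivity, face_kappa)


@pytest.fixture(scope="module")
def meshes():
    geom = AVUnitGeometry()
    return (build_geometry(geom, 8.0, fus_on=False),
            build_geometry(geom, 8.0, fus_on=True))


def test_no_fus_is_identity(meshes):
    base_mesh, _ = meshes
    props = default_region_properties()
    mat = assign_materials(base_mesh, props)
    par = base_mesh.label == int(RegionLabel.PARENCHYMA)
    assert np.all(mat.porosity[par] == props[RegionLabel.PARENCHYMA].porosity)
    assert np.all(mat.permeability[par]
                  == props[RegionLabel.PARENCHYMA].permeability)


def test_fus_scales_parenchyma_only(meshes):
    """FUS multiplies parenchymal κ by 3.0 (to 3e-12 m²) and ε by 1.67 (to
    0.334); the glia limitans and perivascular spaces are untouched."""
    _, fus_mesh = meshes
    mat = assign_materials(fus_mesh, fus=FUSPerturbation())
    par = fus_mesh.label == int(RegionLabel.PARENCHYMA)
    assert np.allclose(mat.permeability[par], 3.0e-12)
    assert np.allclose(mat.porosity[par], 0.20 * 1.67)
    pas = fus_mesh.label == int(RegionLabel.PAS)
    assert np.allclose(mat.porosity[pas], 1.0)


def test_fus_monotonicity(meshes):
    base_mesh, fus_mesh = meshes
    b = assign_materials(base_mesh)
    f = assign_materials(fus_mesh, fus=FUSPerturbation())
    # FUS never decreases porosity or permeability anywhere (labels differ
    # between the meshes only where the annuli widened, which raises both)
    for lab in RegionLabel:
        mb = base_mesh.label == int(lab)
        mf = fus_mesh.label == int(lab)
        if mb.any() and mf.any():
            assert f.porosity[mf].min() >= b.porosity[mb].min() - 1e-15
            assert f.permeability[mf].min() >= b.permeability[mb].min() * (1 - 1e-12)


def test_overscaled_porosity_rejected(meshes):
    _, fus_mesh = meshes
    with pytest.raises(MaterialError, match="porosity"):
        assign_materials(fus_mesh, fus=FUSPerturbation(porosity_factor=6.0))


def test_fus_factors_below_one_rejected():
    with pytest.raises(MaterialError):
        FUSPerturbation(permeability_factor=0.5)


@pytest.mark.parametrize("name,D,expected", [
    ("tracer", 1.0e-9, 1.0e-9 / 1.7 ** 2),
    ("amyloid_beta", 1.8e-10, 1.8e-10 / 2.89),
    ("alpha_synuclein", 7.8e-10, 7.8e-10 / 2.89),
])
def test_effective_diffusivity_tortuosity(name, D, expected):
    par = default_region_properties()[RegionLabel.PARENCHYMA]
    assert SOLUTES[name].diffusivity == D
    assert effective_diffusivity(SOLUTES[name], par) == pytest.approx(expected, rel=1e-12)


def test_effective_diffusivity_free_fluid():
    free = RegionProperties(porosity=1.0, permeability=1e-9, tortuosity=1.0)
    for s in SOLUTES.values():
        assert effective_diffusivity(s, free) == s.diffusivity


def test_face_kappa_series_resistance(meshes):
    """A face whose centre-to-centre segment crosses the glia limitans gets a
    harmonic-mean permeability dominated by the shell: below the parenchyma
    value even though neither adjacent cell is glia."""
    base_mesh, _ = meshes
    mat = assign_materials(base_mesh)
    kx = face_kappa(base_mesh, mat, 0)
    lab = base_mesh.label[:, :, 0]
    props = default_region_properties()
    k_par = props[RegionLabel.PARENCHYMA].permeability
    crossing = []
    for i in range(1, lab.shape[0]):
        for j in range(lab.shape[1]):
            pair = {lab[i - 1, j], lab[i, j]}
            if pair == {int(RegionLabel.PAS), int(RegionLabel.PARENCHYMA)}:
                crossing.append(kx[i, j, 0])
    assert crossing, "expected PAS|parenchyma faces at this resolution"
    assert max(crossing) < k_par  # glia resistance strictly binds
    # homogeneous parenchyma faces keep the cell value
    deep = kx[2, 2, 0]
    assert deep == pytest.approx(k_par, rel=1e-9)
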