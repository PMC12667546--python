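"""Transport properties of the tissue regions and the FUS BBBO perturbation.

Region properties (porosity ε, permeability κ, tortuosity λ) follow literature
values for brain tissue: parenchyma is a low-porosity porous medium, the glia
limitans a much tighter 1 µm shell, and the perivascular spaces are treated as
fluid-dominated Brinkman regions (ε = 1 with a large permeability), so a single
Brinkman/advection-diffusion equation set covers the whole domain.

FUS BBBO is parametric: it multiplies parenchymal porosity and permeability,
widens the perivascular spaces (consumed by :mod:`glymphsim.geometry`), and
adds a slow CSF inflow on the exposed outer perimeter (consumed by
:mod:`glymphsim.flow`).  Percentage values quoted for these perturbations are
interpreted multiplicatively: a "300 %" permeability increase means
``new = 3.0 x old``.

Because the glia shell is thinner than a grid cell, face-level coefficients
(flow transmissibility and diffusive conductance) are computed by sampling the
analytic region map along each cell-centre-to-cell-centre segment and taking
the harmonic (series-resistance) mean; the shell's hydraulic and diffusive
resistance is thereby retained on meshes that do not resolve it.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (LUMEN_ARTERIOLE, LUMEN_VENULE, LabeledMesh, RegionLabel,
                       classify_points)


class MaterialError(ValueError):
    """Raised when a perturbation pushes a property out of physical bounds."""


@dataclass(frozen=True)
class RegionProperties:
    """Porous-medium properties of one region."""

    porosity: float       # ε, dimensionless in (0, 1]
    permeability: float   # κ, m²
    tortuosity: float = 1.0  # λ ≥ 1; effective diffusivity is D/λ²

    def __post_init__(self):
        if not (0.0 < self.porosity <= 1.0):
            raise MaterialError(f"porosity {self.porosity} outside (0, 1]")
        if self.permeability <= 0:
            raise MaterialError("permeability must be positive")
        if self.tortuosity < 1.0:
            raise MaterialError("tortuosity must be >= 1")


@dataclass(frozen=True)
class FluidProperties:
    """CSF taken as water-like: dynamic viscosity 1 mPa·s, density 1 g/mL."""

    viscosity: float = 1.0e-3  # Pa·s
    density: float = 1000.0    # kg/m³

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise MaterialError("fluid properties must be positive")


@dataclass(frozen=True)
class FUSPerturbation:
    """Parametric FUS BBBO effect (all factors ≥ 1: FUS only relaxes tissue)."""

    porosity_factor: float = 1.67
    permeability_factor: float = 3.0
    pvs_scale_factor: float = 1.75     # consumed by geometry
    inlet_velocity: float = 0.8        # µm/s on FUS_INLET facets

    def __post_init__(self):
        for name in ("porosity_factor", "permeability_factor",
                     "pvs_scale_factor"):
            if getattr(self, name) < 1.0:
                raise MaterialError(f"{name} must be >= 1 (FUS only relaxes "
                                    "the tissue in this model)")
        if self.inlet_velocity < 0:
            raise MaterialError("inlet_velocity must be >= 0")


@dataclass(frozen=True)
class SoluteSpec:
    """A solute identified by its free diffusion coefficient."""

    name: str
    diffusivity: float  # D, m²/s (free / in-CSF value)

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise MaterialError("diffusivity must be positive")


#: Literature free-diffusion coefficients for the modelled species (m²/s).
SOLUTES: dict[str, SoluteSpec] = {
    "tracer": SoluteSpec("tracer", 1.0e-9),
    "amyloid_beta": SoluteSpec("amyloid_beta", 1.8e-10),
    "alpha_synuclein": SoluteSpec("alpha_synuclein", 7.8e-10),
}


def default_region_properties() -> dict[RegionLabel, RegionProperties]:
    """Baseline per-region properties (literature values).

    The perivascular spaces are near-free fluid: ε = 1, λ = 1 and κ = 1e-9 m²,
    which puts the Brinkman momentum balance in its viscosity-dominated
    (near-Stokes) regime there.  The glia limitans inherits the parenchymal
    tortuosity since no in-vivo diffusivity has been measured for it.
    """
    free = RegionProperties(porosity=1.0, permeability=1.0e-9, tortuosity=1.0)
    glia = RegionProperties(porosity=0.003, permeability=5.0e-14, tortuosity=1.7)
    return {
        RegionLabel.PAS: free,
        RegionLabel.PVS: free,
        RegionLabel.GLIA_ARTERIOLE: glia,
        RegionLabel.GLIA_VENULE: glia,
        RegionLabel.PARENCHYMA: RegionProperties(porosity=0.20,
                                                 permeability=1.0e-12,
                                                 tortuosity=1.7),
    }


def effective_diffusivity(solute: SoluteSpec, region: RegionProperties) -> float:
    """Tortuosity-hindered diffusivity D_eff = D/λ² (m²/s)."""
    return solute.diffusivity / region.tortuosity ** 2


def _fus_region_props(base, fus):
    """Exposed-state property table: FUS scales parenchyma ε and κ only."""
    out = dict(base)
    par = base[RegionLabel.PARENCHYMA]
    eps = par.porosity * fus.porosity_factor
    if eps > 1.0:
        raise MaterialError(
            f"FUS porosity factor {fus.porosity_factor} drives parenchyma "
            f"porosity to {eps:.3f} > 1")
    out[RegionLabel.PARENCHYMA] = replace(
        par, porosity=eps, permeability=par.permeability * fus.permeability_factor)
    return out


@dataclass
class MaterialField:
    """Per-cell ε/κ/λ on a LabeledMesh, plus the analytic point sampler used
    to build face (series-resistance) coefficients."""

    mesh: LabeledMesh
    porosity: np.ndarray
    permeability: np.ndarray
    tortuosity: np.ndarray
    base: dict[RegionLabel, RegionProperties]
    fus: FUSPerturbation | None
    mask: np.ndarray  # per-cell FUS exposure used for property scaling

    # -- point sampling -----------------------------------------------------
    def _point_tables(self):
        unexp = self.base
        exp = _fus_region_props(self.base, self.fus) if self.fus else self.base
        return unexp, exp

    def _classify(self, x, y):
        lab = classify_points(self.mesh.geom, x, y, fus_on=self.mesh.fus_on,
                              focal_plane=self.mesh.geom.focal_plane)
        # Lumen points (segments clipping a vessel corner) take the adjacent
        # perivascular-space properties; the no-slip wall is enforced by the
        # solver, not by the material map.
        lab = np.where(lab == LUMEN_ARTERIOLE, int(RegionLabel.PAS), lab)
        lab = np.where(lab == LUMEN_VENULE, int(RegionLabel.PVS), lab)
        if self.fus is not None and self.mesh.fus_on:
            fp = self.mesh.geom.focal_plane
            exp = np.ones(lab.shape, bool) if fp is None else fp.exposed(x, y)
            exp = np.broadcast_to(exp, lab.shape)
        else:
            exp = np.zeros(lab.shape, bool)
        return lab, exp

    def _sample(self, x, y, getter):
        lab, exp = self._classify(x, y)
        unexp_tab, exp_tab = self._point_tables()
        out = np.empty(lab.shape, dtype=float)
        for reg in RegionLabel:
            m = lab == int(reg)
            out[m & ~exp] = getter(unexp_tab[reg])
            out[m & exp] = getter(exp_tab[reg])
        return out

    def sample_kappa(self, x, y) -> np.ndarray:
        """Permeability κ (m²) at cross-sectional points (µm)."""
        return self._sample(x, y, lambda p: p.permeability)

    def sample_porosity(self, x, y) -> np.ndarray:
        return self._sample(x, y, lambda p: p.porosity)

    def sample_eps_deff(self, x, y, solute: SoluteSpec) -> np.ndarray:
        """ε·D_eff (m²/s) at cross-sectional points (µm) — the coefficient of
        the porous diffusive flux ε·D_eff·∇c."""
        return self._sample(
            x, y, lambda p: p.porosity * effective_diffusivity(solute, p))


def assign_materials(mesh: LabeledMesh,
                     base: dict[RegionLabel, RegionProperties] | None = None,
                     fus: FUSPerturbation | None = None,
                     mask: np.ndarray | None = None) -> MaterialField:
    """Map region labels to per-cell properties, applying FUS where exposed.

    ``mask`` defaults to the mesh's own exposure flags; it only matters when
    ``fus`` is given.  FUS multiplies parenchymal porosity and permeability on
    exposed cells; the glia limitans and perivascular spaces keep their base
    properties (the perivascular *geometry* change is handled by the mesh).
    """
    base = dict(base) if base else default_region_properties()
    missing = [r for r in RegionLabel if r not in base]
    if missing:
        raise MaterialError(f"missing base properties for regions {missing}")
    if mask is None:
        mask = mesh.exposed if fus is not None else np.zeros(mesh.grid.shape, bool)

    eps = np.zeros(mesh.grid.shape)
    kap = np.zeros(mesh.grid.shape)
    lam = np.ones(mesh.grid.shape)
    tables = (base, _fus_region_props(base, fus) if fus else base)
    for reg in RegionLabel:
        for exposed_state, tab in enumerate(tables):
            m = (mesh.label == int(reg)) & (mask == bool(exposed_state))
            p = tab[reg]
            eps[m] = p.porosity
            kap[m] = p.permeability
            lam[m] = p.tortuosity
    # Solid (lumen) cells: benign placeholders, never used by the solvers.
    eps[mesh.solid] = 1.0
    kap[mesh.solid] = base[RegionLabel.PAS].permeability
    return MaterialField(mesh=mesh, porosity=eps, permeability=kap,
                         tortuosity=lam, base=base, fus=fus, mask=mask)


# -- face coefficients ------------------------------------------------------

def _segment_samples(mesh: LabeledMesh, axis: int, n: int = 65):
    """Sample coordinates along every face-normal segment for ``axis`` faces.

    Returns (x, y) arrays of shape (n_along, n_across, n) for the in-plane
    axes, or None for z-faces (properties are z-invariant, so z-face
    coefficients equal the cell values).
    """
    g = mesh.grid
    t = (np.arange(n) + 0.5) / n
    if axis == 2:
        return None
    cx = g.centers(0)
    cy = g.centers(1)
    if axis == 0:
        # Segment endpoints along x: boundary-to-centre at the two ends,
        # centre-to-centre inside.
        x0 = np.concatenate(([g.x[0]], cx))
        x1 = np.concatenate((cx, [g.x[-1]]))
        xs = x0[:, None] + (x1 - x0)[:, None] * t[None, :]   # (nx+1, n)
        x = xs[:, None, :]
        y = cy[None, :, None]
    else:
        y0 = np.concatenate(([g.y[0]], cy))
        y1 = np.concatenate((cy, [g.y[-1]]))
        ys = y0[:, None] + (y1 - y0)[:, None] * t[None, :]   # (ny+1, n)
        x = cx[:, None, None]
        y = ys[None, :, :]
    return np.broadcast_arrays(x, y)


def face_kappa(mesh: LabeledMesh, mat: MaterialField, axis: int) -> np.ndarray:
    """Harmonic-mean permeability (m²) on every face normal to ``axis``,
    broadcast over z.  Shape matches the staggered face grid."""
    nx, ny, nz = mesh.grid.shape
    if axis == 2:
        k2d = mat.permeability[:, :, 0]
        kf = np.empty((nx, ny, nz + 1))
        kf[...] = k2d[:, :, None]
        return kf
    x, y = _segment_samples(mesh, axis)
    k = mat.sample_kappa(x, y)
    kf2d = 1.0 / np.mean(1.0 / k, axis=-1)
    return np.repeat(kf2d[:, :, None], nz, axis=2)


def face_eps_deff(mesh: LabeledMesh, mat: MaterialField, solute: SoluteSpec,
                  axis: int) -> np.ndarray:
    """Harmonic-mean ε·D_eff (m²/s) on every face normal to ``axis``."""
    nx, ny, nz = mesh.grid.shape
    if axis == 2:
        d2d = (mat.porosity * mat.tortuosity ** -2)[:, :, 0] * solute.diffusivity
        df = np.empty((nx, ny, nz + 1))
        df[...] = d2d[:, :, None]
        return df
    x, y = _segment_samples(mesh, axis)
    d = mat.sample_eps_deff(x, y, solute)
    df2d = 1.0 / np.mean(1.0 / d, axis=-1)
    return np.repeat(df2d[:, :, None], nz, axis=2)
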