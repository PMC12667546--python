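"""Geometry of the arteriole-venule unit.

The computational domain is a rectangular box of brain parenchyma traversed by
two parallel vessels (an arteriole and a venule, axes along z).  Each vessel
lumen is excluded from the domain (no-slip walls); around each lumen sit an
annular perivascular space (PAS around the arteriole, PVS around the venule)
and a thin glia-limitans shell, with parenchyma filling the rest of the box.

Focused-ultrasound blood-brain-barrier opening (FUS BBBO) widens both
perivascular annuli by a configurable factor; an optional focal plane restricts
the widening (and every other FUS effect) to one side of the unit, emulating an
arteriole-venule unit sitting at the edge of the ultrasound focus.

Geometry is represented on a structured grid: each cell carries the region
label of its centre, and sub-cell sampling supplies fluid volume fractions so
that integral quantities converge faster than the staircase boundary would
suggest.  The 1 µm glia shell is far thinner than a typical cell; it is
captured in the transport/flow coefficients by series-resistance sampling along
cell-to-cell segments (see :mod:`glymphsim.materials`), not by meshing it.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .grid import StructuredGrid


class GeometryError(ValueError):
    """Raised when geometry parameters violate the non-overlap invariants."""


class RegionLabel(IntEnum):
    """Tissue region of a (fluid) cell."""

    PAS = 1
    PVS = 2
    GLIA_ARTERIOLE = 3
    GLIA_VENULE = 4
    PARENCHYMA = 5


# Internal codes for excluded lumen cells (never exposed as RegionLabel).
LUMEN_ARTERIOLE = -1
LUMEN_VENULE = -2


class FacetTag(IntEnum):
    """Boundary facet classification."""

    OUTER_OPEN = 1
    PAS_INLET = 2
    PVS_OUTLET = 3
    FUS_INLET = 4
    VESSEL_WALL = 5


@dataclass(frozen=True)
class FocalPlane:
    """Half-space in the cross-sectional (x, y) plane.

    Points with ``(p - point) . normal >= 0`` count as FUS-exposed.
    """

    point: tuple[float, float]
    normal: tuple[float, float]

    def exposed(self, x, y):
        nx, ny = self.normal
        px, py = self.point
        return (np.asarray(x) - px) * nx + (np.asarray(y) - py) * ny >= 0.0


@dataclass(frozen=True)
class AVUnitGeometry:
    """Parametric description of the arteriole-venule unit (lengths in µm)."""

    axial_length: float = 100.0
    arteriole_diameter: float = 20.0
    venule_diameter: float = 30.0
    pas_width: float = 10.0
    pvs_width: float = 10.0
    glia_width: float = 1.0
    vessel_separation: float = 280.0
    box_margin: float = 60.0
    pvs_scale_factor: float = 1.75
    focal_plane: FocalPlane | None = None

    # -- derived quantities -------------------------------------------------
    @property
    def arteriole_radius(self) -> float:
        return 0.5 * self.arteriole_diameter

    @property
    def venule_radius(self) -> float:
        return 0.5 * self.venule_diameter

    def pas_outer_radius(self, fus_on: bool = False) -> float:
        s = self.pvs_scale_factor if fus_on else 1.0
        return self.arteriole_radius + s * self.pas_width

    def pvs_outer_radius(self, fus_on: bool = False) -> float:
        s = self.pvs_scale_factor if fus_on else 1.0
        return self.venule_radius + s * self.pvs_width

    def arteriole_shell_radius(self, fus_on: bool = False) -> float:
        return self.pas_outer_radius(fus_on) + self.glia_width

    def venule_shell_radius(self, fus_on: bool = False) -> float:
        return self.pvs_outer_radius(fus_on) + self.glia_width

    def box_bounds(self):
        """Domain box ((x0,x1),(y0,y1),(z0,z1)) in µm.

        The box is fixed by the *baseline* glia shells plus ``box_margin`` so
        that baseline and FUS runs share the same domain and grid.  The
        arteriole axis is at (0, 0), the venule axis at (vessel_separation, 0).
        """
        ra = self.arteriole_shell_radius(False)
        rv = self.venule_shell_radius(False)
        half_w = max(ra, rv) + self.box_margin
        return ((-(ra + self.box_margin), self.vessel_separation + rv + self.box_margin),
                (-half_w, half_w),
                (0.0, self.axial_length))

    # -- validation ---------------------------------------------------------
    def validate(self, fus_on: bool = False) -> None:
        for name in ("axial_length", "arteriole_diameter", "venule_diameter",
                     "pas_width", "pvs_width", "glia_width",
                     "vessel_separation", "box_margin", "pvs_scale_factor"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        clearance = (self.vessel_separation
                     - self.arteriole_shell_radius(fus_on)
                     - self.venule_shell_radius(fus_on))
        if clearance <= 0:
            raise GeometryError(
                "perivascular annuli overlap: vessel_separation "
                f"{self.vessel_separation} µm leaves clearance {clearance:.2f} µm "
                f"between glia shells (radii {self.arteriole_shell_radius(fus_on):.2f}"
                f" and {self.venule_shell_radius(fus_on):.2f} µm, fus_on={fus_on})")
        (x0, x1), (y0, y1), _ = self.box_bounds()
        for r, cx, vessel in ((self.arteriole_shell_radius(fus_on), 0.0, "arteriole"),
                              (self.venule_shell_radius(fus_on),
                               self.vessel_separation, "venule")):
            if cx - r < x0 or cx + r > x1 or -r < y0 or r > y1:
                raise GeometryError(
                    f"{vessel} glia shell (radius {r:.2f} µm) extends beyond the "
                    "domain box; increase box_margin")


def classify_points(geom: AVUnitGeometry, x, y, *, fus_on: bool = False,
                    focal_plane: FocalPlane | None = None) -> np.ndarray:
    """Region code for cross-sectional points (µm): RegionLabel or lumen code.

    Under FUS the perivascular widths are multiplied by ``pvs_scale_factor``
    wherever the point is on the exposed side of ``focal_plane`` (everywhere if
    no plane is given).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = np.broadcast_arrays(x, y)
    if fus_on:
        if focal_plane is None:
            scale = np.full(x.shape, geom.pvs_scale_factor)
        else:
            scale = np.where(focal_plane.exposed(x, y), geom.pvs_scale_factor, 1.0)
    else:
        scale = np.ones(x.shape)

    out = np.full(x.shape, int(RegionLabel.PARENCHYMA), dtype=np.int8)
    r_a = np.hypot(x, y)
    r_v = np.hypot(x - geom.vessel_separation, y)
    pas_out = geom.arteriole_radius + scale * geom.pas_width
    pvs_out = geom.venule_radius + scale * geom.pvs_width

    # venule first, arteriole second: annuli never overlap (validated), order
    # is irrelevant except for ill-posed inputs.
    out[r_v <= pvs_out + geom.glia_width] = int(RegionLabel.GLIA_VENULE)
    out[r_v <= pvs_out] = int(RegionLabel.PVS)
    out[r_v <= geom.venule_radius] = LUMEN_VENULE
    out[r_a <= pas_out + geom.glia_width] = int(RegionLabel.GLIA_ARTERIOLE)
    out[r_a <= pas_out] = int(RegionLabel.PAS)
    out[r_a <= geom.arteriole_radius] = LUMEN_ARTERIOLE
    return out


@dataclass
class LabeledMesh:
    """Structured grid plus per-cell region labels and boundary facet tags.

    ``label`` holds RegionLabel values for fluid cells and negative lumen codes
    for excluded cells; ``solid`` marks the excluded cells.  ``vol_frac`` is the
    sub-cell-sampled fluid volume fraction (zero on solid cells), used for all
    volume integrals.  ``facet_tags`` maps each box side to a 2D array of
    FacetTag codes over that side's boundary faces.
    """

    grid: StructuredGrid
    label: np.ndarray            # (nx, ny, nz) int8
    vol_frac: np.ndarray         # (nx, ny, nz) float
    exposed: np.ndarray          # (nx, ny, nz) bool — FUS exposure of each cell
    facet_tags: dict[str, np.ndarray]
    geom: AVUnitGeometry
    fus_on: bool
    resolution: float

    @property
    def solid(self) -> np.ndarray:
        return self.label < 0

    def region_volumes(self) -> dict[RegionLabel, float]:
        """Meshed volume (µm³) of each fluid region."""
        v = self.grid.cell_volume
        return {lab: float(self.vol_frac[self.label == int(lab)].sum() * v)
                for lab in RegionLabel}

    def analytic_region_volumes(self) -> dict[RegionLabel, float]:
        """Closed-form region volumes (µm³).

        With a focal plane, each vessel's annuli use the widths implied by the
        exposure of that vessel's axis; exact whenever the plane does not cut
        through an annulus (the canonical edge-of-focus scenarios place the
        plane midway between the vessels).
        """
        g, L = self.geom, self.geom.axial_length

        def ann(r0, r1):
            return np.pi * (r1 ** 2 - r0 ** 2) * L

        def exposed_at(cx):
            if not self.fus_on:
                return False
            if g.focal_plane is None:
                return True
            return bool(g.focal_plane.exposed(cx, 0.0))

        fa = exposed_at(0.0)
        fv = exposed_at(g.vessel_separation)
        pas_o = g.pas_outer_radius(fa)
        pvs_o = g.pvs_outer_radius(fv)
        (x0, x1), (y0, y1), _ = g.box_bounds()
        box = (x1 - x0) * (y1 - y0) * L
        vols = {
            RegionLabel.PAS: ann(g.arteriole_radius, pas_o),
            RegionLabel.PVS: ann(g.venule_radius, pvs_o),
            RegionLabel.GLIA_ARTERIOLE: ann(pas_o, pas_o + g.glia_width),
            RegionLabel.GLIA_VENULE: ann(pvs_o, pvs_o + g.glia_width),
        }
        lumens = np.pi * (g.arteriole_radius ** 2 + g.venule_radius ** 2) * L
        vols[RegionLabel.PARENCHYMA] = (box - lumens - sum(vols.values()))
        return vols

    def fluid_volume(self) -> float:
        """Total meshed fluid volume (µm³)."""
        return float(self.vol_frac.sum() * self.grid.cell_volume)


def build_geometry(params: AVUnitGeometry, resolution: float = 6.0,
                   fus_on: bool = False, subsamples: int = 4) -> LabeledMesh:
    """Mesh the arteriole-venule unit.

    Parameters
    ----------
    params:
        Geometry description; ``params.focal_plane`` (if set) restricts FUS
        widening to the exposed side.
    resolution:
        Target cell size in µm (scalar or per-axis triple).
    fus_on:
        Widen the perivascular annuli by ``pvs_scale_factor`` (on the exposed
        side only, when a focal plane is present).
    """
    params.validate(fus_on)
    grid = StructuredGrid.from_box(params.box_bounds(), resolution)
    nx, ny, nz = grid.shape
    xc = grid.centers(0)
    yc = grid.centers(1)

    lab2d = classify_points(params, xc[:, None], yc[None, :], fus_on=fus_on,
                            focal_plane=params.focal_plane)
    if params.focal_plane is not None and fus_on:
        exp2d = params.focal_plane.exposed(xc[:, None], yc[None, :])
        exp2d = np.broadcast_to(exp2d, lab2d.shape)
    else:
        exp2d = np.full(lab2d.shape, fus_on)

    # Fluid volume fraction by sub-cell sampling of the lumen indicator.
    hx, hy, _ = grid.spacing
    off = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    xs = (xc[:, None] + off[None, :] * hx).ravel()     # (nx*s,)
    ys = (yc[:, None] + off[None, :] * hy).ravel()
    sub = classify_points(params, xs[:, None], ys[None, :], fus_on=fus_on,
                          focal_plane=params.focal_plane)
    fluid = (sub >= 0).reshape(nx, subsamples, ny, subsamples)
    frac2d = fluid.mean(axis=(1, 3))
    frac2d[lab2d < 0] = 0.0

    label = np.repeat(lab2d[:, :, None], nz, axis=2)
    vol_frac = np.repeat(frac2d[:, :, None], nz, axis=2)
    exposed = np.repeat(exp2d[:, :, None], nz, axis=2)

    facet_tags = _tag_facets(lab2d, exp2d, fus_on, nx, ny, nz)
    res = float(np.mean(np.broadcast_to(np.asarray(resolution, float), (3,))))
    return LabeledMesh(grid=grid, label=label, vol_frac=vol_frac,
                       exposed=exposed, facet_tags=facet_tags, geom=params,
                       fus_on=fus_on, resolution=res)


def _tag_facets(lab2d, exp2d, fus_on, nx, ny, nz):
    """Boundary facet tags per box side.

    The z+ face is the pial surface: PAS cells' facets are the CSF inlet, PVS
    cells' the CSF outlet, everything else open.  The z- face is fully open
    (the vessels continue into deeper tissue).  Lateral facets are open at
    baseline; under FUS the exposed part of the lateral perimeter becomes the
    FUS fluid inlet.
    """
    tags = {}
    zp = np.full((nx, ny), int(FacetTag.OUTER_OPEN), dtype=np.int8)
    zp[lab2d == int(RegionLabel.PAS)] = int(FacetTag.PAS_INLET)
    zp[lab2d == int(RegionLabel.PVS)] = int(FacetTag.PVS_OUTLET)
    zp[lab2d < 0] = int(FacetTag.VESSEL_WALL)
    tags["z+"] = zp
    zm = np.full((nx, ny), int(FacetTag.OUTER_OPEN), dtype=np.int8)
    zm[lab2d < 0] = int(FacetTag.VESSEL_WALL)
    tags["z-"] = zm

    for side, border in (("x-", exp2d[0, :]), ("x+", exp2d[-1, :]),
                         ("y-", exp2d[:, 0]), ("y+", exp2d[:, -1])):
        n1 = border.shape[0]
        t = np.full((n1, nz), int(FacetTag.OUTER_OPEN), dtype=np.int8)
        if fus_on:
            t[border, :] = int(FacetTag.FUS_INLET)
        tags[side] = t
    return tags


def focal_mask(mesh: LabeledMesh, focal_plane: FocalPlane) -> np.ndarray:
    """Per-cell FUS-exposure flags for an explicit focal plane."""
    xc, yc, _ = mesh.grid.cell_centers()
    m = focal_plane.exposed(xc, yc)
    return np.broadcast_to(m, mesh.grid.shape).copy()
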