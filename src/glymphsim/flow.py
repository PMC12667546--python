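"""Steady incompressible Brinkman flow on the staggered (MAC) grid.

Governing equations (superficial/Darcy velocity u, pressure p):

    -∇p + (µ/ε) ∇²u - (µ/κ) u = 0,       ∇·u = 0

Inertia is neglected (Re ~ 1e-6 at glymphatic scales) and the flow is steady:
the forcing (boundary velocities, FUS inflow, pressure offsets) is constant
per condition, so one flow solve per scenario feeds the transient transport.

Discretisation: marker-and-cell staggering — velocity components live on cell
faces, pressure at cell centres.  The drag coefficient µ/κ uses the
series-resistance face permeability from :mod:`glymphsim.materials`, which is
how the unresolved 1 µm glia limitans exerts its hydraulic resistance.  The
coupled saddle-point system is solved with a sparse direct factorisation.

Boundary conditions per box side and facet:

* ``velocity`` — imposed inward normal velocity, zero tangential slip;
* ``open``    — imposed boundary pressure; the normal face velocity keeps a
  Darcy-balance momentum row, so flux enters or leaves freely;
* ``wall``    — no-slip;  ``slip`` — free-slip symmetry plane.

Vessel lumens are excluded cells; every face touching one is no-slip.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import FacetTag, LabeledMesh
from .grid import SIDES, UM, StructuredGrid
from .materials import FluidProperties, MaterialField, face_kappa

# Boundary kinds
OPEN, VELOCITY, WALL, SLIP = 0, 1, 2, 3
_KIND_NAMES = {"open": OPEN, "velocity": VELOCITY, "wall": WALL, "slip": SLIP}

MMHG_PER_M = 133.322  # Pa per mmHg


class FlowSolverError(RuntimeError):
    """Raised when the linear solve fails or leaves a large residual."""


@dataclass(frozen=True)
class FlowBoundaryConditions:
    """Boundary data for the arteriole-venule unit (velocities in µm/s).

    ``bc_mode='velocity'`` imposes both the periarterial inflow and the
    perivenous outflow as Dirichlet velocities (the arteriole-to-venule
    pressure gradient then emerges); ``bc_mode='mixed'`` keeps the PAS inflow
    but replaces the PVS outlet by an open boundary whose pressure sits
    ``av_pressure_gradient x vessel_separation`` below the outer reference,
    letting the perivenous velocity emerge.
    """

    pas_inlet_velocity: float = 18.7
    pvs_outlet_velocity: float = 3.0
    av_pressure_gradient: float = 3.0      # mmHg/m
    open_boundary_pressure: float = 0.0    # Pa
    fus_inlet_velocity: float = 0.8
    bc_mode: str = "velocity"

    def __post_init__(self):
        if min(self.pas_inlet_velocity, self.pvs_outlet_velocity,
               self.fus_inlet_velocity) < 0:
            raise ValueError("boundary velocities must be >= 0")
        if self.av_pressure_gradient < 0:
            raise ValueError("av_pressure_gradient must be >= 0")
        if self.bc_mode not in ("velocity", "mixed"):
            raise ValueError("bc_mode must be 'velocity' or 'mixed'")


@dataclass
class SideBC:
    """Per-face boundary data on one box side.

    ``kind`` holds OPEN/VELOCITY/WALL/SLIP codes; ``value`` is the boundary
    pressure (Pa) for OPEN faces and the *inward* normal velocity (m/s) for
    VELOCITY faces (negative = imposed outflow).
    """

    kind: np.ndarray
    value: np.ndarray

    @classmethod
    def uniform(cls, shape, kind: str, value: float = 0.0) -> "SideBC":
        return cls(np.full(shape, _KIND_NAMES[kind], dtype=np.int8),
                   np.full(shape, float(value)))


@dataclass
class FlowSolution:
    """Face velocities (m/s, superficial) and cell pressure (Pa)."""

    grid: StructuredGrid
    solid: np.ndarray
    face_velocity: tuple[np.ndarray, np.ndarray, np.ndarray]  # u, v, w
    pressure: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def cell_velocity(self) -> np.ndarray:
        """Cell-centred superficial velocity, shape (nx, ny, nz, 3), m/s."""
        u, v, w = self.face_velocity
        out = np.stack([0.5 * (u[:-1] + u[1:]),
                        0.5 * (v[:, :-1] + v[:, 1:]),
                        0.5 * (w[:, :, :-1] + w[:, :, 1:])], axis=-1)
        out[self.solid] = 0.0
        return out

    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.cell_velocity(), axis=-1)

    def divergence(self) -> np.ndarray:
        """Discrete divergence (1/s) per cell."""
        u, v, w = self.face_velocity
        hx, hy, hz = (s * UM for s in self.grid.spacing)
        div = (np.diff(u, axis=0) / hx + np.diff(v, axis=1) / hy
               + np.diff(w, axis=2) / hz)
        div[self.solid] = 0.0
        return div

    def boundary_outflux(self, side: str, where: np.ndarray | None = None) -> float:
        """Net outward volumetric flux (m³/s) through one box side."""
        u, v, w = self.face_velocity
        areas = [self.grid.face_area(a) * UM ** 2 for a in range(3)]
        face = {"x-": -u[0], "x+": u[-1], "y-": -v[:, 0], "y+": v[:, -1],
                "z-": -w[:, :, 0], "z+": w[:, :, -1]}[side]
        a = areas["xyz".index(side[0])]
        if where is not None:
            face = np.where(where, face, 0.0)
        return float(face.sum() * a)

    def plane_flux(self, x_plane_um: float) -> float:
        """Net volumetric flux (m³/s) in +x through the u-face plane nearest
        ``x_plane_um`` — the inter-vessel (arteriole → venule) flux when the
        plane sits between the vessels."""
        u = self.face_velocity[0]
        i = int(np.argmin(np.abs(self.grid.x - x_plane_um)))
        return float(u[i].sum() * self.grid.face_area(0) * UM ** 2)


def mesh_side_bcs(mesh: LabeledMesh, bc: FlowBoundaryConditions) -> dict[str, SideBC]:
    """Translate facet tags into per-side boundary arrays."""
    sides = {}
    p0 = bc.open_boundary_pressure
    for side in SIDES:
        tags = mesh.facet_tags[side]
        kind = np.full(tags.shape, OPEN, dtype=np.int8)
        value = np.full(tags.shape, p0, dtype=float)
        kind[tags == int(FacetTag.VESSEL_WALL)] = WALL
        m = tags == int(FacetTag.PAS_INLET)
        kind[m] = VELOCITY
        value[m] = bc.pas_inlet_velocity * UM
        m = tags == int(FacetTag.PVS_OUTLET)
        if bc.bc_mode == "velocity":
            kind[m] = VELOCITY
            value[m] = -bc.pvs_outlet_velocity * UM
        else:  # mixed: open outlet at a lowered pressure
            value[m] = p0 - (bc.av_pressure_gradient * MMHG_PER_M
                             * mesh.geom.vessel_separation * UM)
        m = tags == int(FacetTag.FUS_INLET)
        kind[m] = VELOCITY
        value[m] = bc.fus_inlet_velocity * UM
        sides[side] = SideBC(kind, value)
    return sides


def solve_flow(mesh: LabeledMesh, materials: MaterialField,
               fluid: FluidProperties, bc: FlowBoundaryConditions) -> FlowSolution:
    """Solve the Brinkman system on a labelled arteriole-venule mesh."""
    kappas = tuple(face_kappa(mesh, materials, a) for a in range(3))
    return solve_brinkman(mesh.grid, mesh.solid, materials.porosity, kappas,
                          fluid.viscosity, mesh_side_bcs(mesh, bc))


#: Faces whose permeability is below this (m²) use the pure Darcy momentum
#: balance (no viscous term).  In such regions the Brinkman screening length
#: sqrt(κ/ε) is far below the mesh size, so the viscous term only adds
#: unresolvable boundary layers — and discarding it keeps most momentum rows
#: diagonal, which the sparse factorisation exploits heavily.
VISCOUS_KAPPA_THRESHOLD = 1e-11


# ---------------------------------------------------------------------------
# generic staggered Brinkman solver
# ---------------------------------------------------------------------------

def _face_status(grid, solid, bcs, axis):
    """Classify faces of one axis: returns (status, known) arrays.

    status: 0 interior unknown, 1 known Dirichlet (value in ``known``),
    2 open-boundary unknown.
    """
    shape = list(grid.shape)
    shape[axis] += 1
    status = np.ones(shape, dtype=np.int8)  # default: known 0
    known = np.zeros(shape)
    fluid = ~solid

    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(1, None)
    sl_hi[axis] = slice(None, -1)
    # interior faces: indices 1..n-1 along axis
    inner = [slice(None)] * 3
    inner[axis] = slice(1, -1)
    both_fluid = (fluid[tuple(sl_hi)] & fluid[tuple(sl_lo)])
    status[tuple(inner)] = np.where(both_fluid, 0, 1)

    for end, side in ((0, "xyz"[axis] + "-"), (-1, "xyz"[axis] + "+")):
        sbc = bcs[side]
        cell_sl = [slice(None)] * 3
        cell_sl[axis] = 0 if end == 0 else -1
        cell_fluid = fluid[tuple(cell_sl)]
        face_sl = [slice(None)] * 3
        face_sl[axis] = end
        st = np.full(cell_fluid.shape, 1, dtype=np.int8)
        kv = np.zeros(cell_fluid.shape)
        vel = (sbc.kind == VELOCITY) & cell_fluid
        sign = 1.0 if end == 0 else -1.0  # inward -> +axis at low side
        kv[vel] = sign * sbc.value[vel]
        op = (sbc.kind == OPEN) & cell_fluid
        st[op] = 2
        status[tuple(face_sl)] = st
        known[tuple(face_sl)] = kv
    return status, known


def solve_brinkman(grid: StructuredGrid, solid: np.ndarray, eps_cell: np.ndarray,
                   kappa_faces, mu: float, bcs: dict[str, SideBC],
                   viscous_kappa_threshold: float = VISCOUS_KAPPA_THRESHOLD
                   ) -> FlowSolution:
    """Assemble and solve the staggered Brinkman saddle-point system.

    ``kappa_faces`` are per-face permeabilities (m²) for the three axes;
    ``eps_cell`` the per-cell porosity (sets the effective viscosity µ/ε).
    Lengths in ``grid`` are µm; the assembly converts to SI.
    """
    nx, ny, nz = grid.shape
    h = [s * UM for s in grid.spacing]
    fluid = ~solid

    status, known = [], []
    for a in range(3):
        st, kn = _face_status(grid, solid, bcs, a)
        status.append(st)
        known.append(kn)

    # Face typing.  Faces whose permeability exceeds the viscous threshold
    # keep full Brinkman momentum rows (velocity unknowns); all other live
    # faces are Darcy-dominated and their velocity is eliminated analytically,
    #     u_f = g (p_lo - p_hi),
    # with g the face conductance (κ/µh for interior faces, 2κ/µh for open
    # boundary faces against the prescribed boundary pressure).  This leaves a
    # Poisson-like pressure system plus a small perivascular velocity block.
    F_BRINK, F_KNOWN, F_DARCY = 0, 1, 2
    ftype, g_face = [], []
    pl_idx, ph_idx, pl_const, ph_const = [], [], [], []
    pidx = -np.ones(grid.shape, dtype=np.int64)

    fidx, n_unk = [], 0
    for a in range(3):
        st, kf = status[a], kappa_faces[a]
        ft = np.where(st == 1, F_KNOWN,
                      np.where(st == 2, F_DARCY,
                               np.where(kf > viscous_kappa_threshold,
                                        F_BRINK, F_DARCY)))
        ftype.append(ft.astype(np.int8))
        idx = -np.ones(st.shape, dtype=np.int64)
        m = ft == F_BRINK
        idx[m] = n_unk + np.arange(int(m.sum()))
        fidx.append(idx)
        n_unk += int(m.sum())
    pidx[fluid] = n_unk + np.arange(int(fluid.sum()))
    n_tot = n_unk + int(fluid.sum())

    # Darcy-face linear expressions
    for a in range(3):
        st, kf = status[a], kappa_faces[a]
        ha = h[a]
        shape = st.shape
        g = np.where(st == 2, 2.0 * kf / (mu * ha), kf / (mu * ha))
        lo_i = -np.ones(shape, dtype=np.int64)
        hi_i = -np.ones(shape, dtype=np.int64)
        lo_c = np.zeros(shape)
        hi_c = np.zeros(shape)
        sl_in = [slice(None)] * 3
        sl_in[a] = slice(1, None)
        lo_i[tuple(sl_in)] = pidx                        # low cell of face f is f-1
        sl_in2 = [slice(None)] * 3
        sl_in2[a] = slice(None, -1)
        hi_i[tuple(sl_in2)] = pidx                       # high cell of face f is f
        # boundary faces: one side is the prescribed boundary pressure
        for end, side in ((0, "xyz"[a] + "-"), (-1, "xyz"[a] + "+")):
            fsl = [slice(None)] * 3
            fsl[a] = end
            openf = st[tuple(fsl)] == 2
            if end == 0:
                lo_i[tuple(fsl)] = np.where(openf, -1, lo_i[tuple(fsl)])
                lo_c[tuple(fsl)] = np.where(openf, bcs[side].value, 0.0)
            else:
                hi_i[tuple(fsl)] = np.where(openf, -1, hi_i[tuple(fsl)])
                hi_c[tuple(fsl)] = np.where(openf, bcs[side].value, 0.0)
        g_face.append(g)
        pl_idx.append(lo_i)
        ph_idx.append(hi_i)
        pl_const.append(lo_c)
        ph_const.append(hi_c)

    rows, cols, vals = [], [], []
    rhs = np.zeros(n_tot)

    def add(r, c, v):
        r, c, v = np.broadcast_arrays(r, c, v)
        rows.append(np.asarray(r, dtype=np.int64).ravel())
        cols.append(np.asarray(c, dtype=np.int64).ravel())
        vals.append(np.asarray(v, dtype=float).ravel())

    def add_linear(row, coeff, a, fi):
        """Add ``coeff * u_face`` for a Darcy-expressed face to given rows."""
        gv = g_face[a][fi]
        for side_idx, side_const, sgn in ((pl_idx[a][fi], pl_const[a][fi], 1.0),
                                          (ph_idx[a][fi], ph_const[a][fi], -1.0)):
            m = side_idx >= 0
            if m.any():
                add(row[m], side_idx[m], sgn * coeff[m] * gv[m])
            mc = ~m
            if mc.any():
                np.add.at(rhs, row[mc], -sgn * coeff[mc] * gv[mc] * side_const[mc])

    eps_pad = np.where(fluid, eps_cell, 1.0)

    # --- Brinkman momentum rows ---
    for a in range(3):
        st, kn, idx, kf, ft = status[a], known[a], fidx[a], kappa_faces[a], ftype[a]
        ha = h[a]
        I, J, K = np.nonzero(ft == F_BRINK)
        if I.size == 0:
            continue
        r = idx[I, J, K]
        cp = [I.copy(), J.copy(), K.copy()]
        cm = [I.copy(), J.copy(), K.copy()]
        cm[a] = cm[a] - 1
        mu_e = mu / (0.5 * (eps_pad[cp[0], cp[1], cp[2]]
                            + eps_pad[cm[0], cm[1], cm[2]]))
        diag = mu / kf[I, J, K] + np.zeros(I.size)
        for d in range(3):
            c = mu_e / h[d] ** 2
            diag += 2.0 * c
            for s in (-1, 1):
                nb = [I.copy(), J.copy(), K.copy()]
                nb[d] += s
                inside = (nb[d] >= 0) & (nb[d] < st.shape[d])
                ii = np.where(inside)[0]
                if ii.size:
                    nbi = (nb[0][ii], nb[1][ii], nb[2][ii])
                    nft = ft[nbi]
                    m = nft == F_BRINK
                    add(r[ii][m], idx[nbi][m], -c[ii][m])
                    m = nft == F_KNOWN
                    np.add.at(rhs, r[ii][m], c[ii][m] * kn[nbi][m])
                    m = nft == F_DARCY
                    if m.any():
                        sub = tuple(x[m] for x in nbi)
                        add_linear(r[ii][m], -c[ii][m], a, sub)
                gi = np.where(~inside)[0]
                if gi.size:
                    side = "xyz"[d] + ("-" if s < 0 else "+")
                    sgn = _ghost_sign(bcs[side], a, d,
                                      (I[gi], J[gi], K[gi]), st.shape)
                    # ghost u_g = sgn * u_f: -c*u_g folds into the diagonal
                    np.add.at(diag, gi, -c[gi] * sgn)
        add(r, r, diag)
        # pressure gradient +(p_hi - p_lo)/ha
        add(r, pidx[cp[0], cp[1], cp[2]], np.full(I.size, 1.0 / ha))
        add(r, pidx[cm[0], cm[1], cm[2]], np.full(I.size, -1.0 / ha))

    # --- continuity rows ---
    I, J, K = np.nonzero(fluid)
    rc = pidx[I, J, K]
    for a in range(3):
        kn, idx, ft = known[a], fidx[a], ftype[a]
        ha = h[a]
        for s, sgn in ((0, -1.0), (1, 1.0)):  # low face enters -, high face +
            fc = [I.copy(), J.copy(), K.copy()]
            fc[a] = fc[a] + s
            fi = (fc[0], fc[1], fc[2])
            fts = ft[fi]
            m = fts == F_BRINK
            add(rc[m], idx[fi][m], np.full(int(m.sum()), sgn / ha))
            m = fts == F_KNOWN
            np.add.at(rhs, rc[m], -sgn / ha * kn[fi][m])
            m = fts == F_DARCY
            if m.any():
                sub = tuple(x[m] for x in fi)
                add_linear(rc[m], np.full(int(m.sum()), sgn / ha), a, sub)

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n_tot, n_tot))
    try:
        sol = spla.spsolve(A.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - solver backend failure
        raise FlowSolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise FlowSolverError("singular Brinkman system (non-finite solution)")

    p = np.zeros(grid.shape)
    p[fluid] = sol[pidx[fluid]]
    faces = []
    for a in range(3):
        fv = known[a].copy()
        m = fidx[a] >= 0
        fv[m] = sol[fidx[a][m]]
        # reconstruct eliminated Darcy-face velocities from the pressure field
        dm = ftype[a] == F_DARCY
        if dm.any():
            fi = np.nonzero(dm)
            plo = np.where(pl_idx[a][fi] >= 0, sol[np.maximum(pl_idx[a][fi], 0)],
                           pl_const[a][fi])
            phi = np.where(ph_idx[a][fi] >= 0, sol[np.maximum(ph_idx[a][fi], 0)],
                           ph_const[a][fi])
            fv[fi] = g_face[a][fi] * (plo - phi)
        faces.append(fv)

    out = FlowSolution(grid=grid, solid=solid,
                       face_velocity=tuple(faces), pressure=p)
    out.diagnostics = _flow_diagnostics(out)
    out.diagnostics["n_unknowns"] = n_tot
    out.diagnostics["n_velocity_unknowns"] = n_unk
    res = out.diagnostics["relative_flux_imbalance"]
    if res > 1e-6:
        raise FlowSolverError(
            f"boundary flux imbalance {res:.2e} exceeds 1e-6 "
            f"(diagnostics: {out.diagnostics})")
    return out


def _ghost_sign(sbc: SideBC, axis, d, face_coords, face_shape):
    """Mirror sign for a tangential ghost velocity across side ``d``.

    Wall and velocity boundaries impose zero tangential velocity (ghost -u);
    open and slip boundaries impose zero tangential shear (ghost +u).  The
    side's kind is sampled at the nearest boundary cell.
    """
    other = [dd for dd in range(3) if dd != d]
    c1 = np.clip(face_coords[other[0]], 0,
                 np.asarray(sbc.kind.shape[0]) - 1)
    c2 = np.clip(face_coords[other[1]], 0,
                 np.asarray(sbc.kind.shape[1]) - 1)
    kinds = sbc.kind[c1, c2]
    return np.where((kinds == WALL) | (kinds == VELOCITY), -1.0, 1.0)


def _flow_diagnostics(sol: FlowSolution) -> dict:
    influx = outflux = 0.0
    for side in SIDES:
        q = sol.boundary_outflux(side)
        if q >= 0:
            outflux += q
        else:
            influx -= q
    div = sol.divergence()
    scale = max(influx, outflux, 1e-30)
    vcell = sol.grid.cell_volume * UM ** 3
    return {
        "total_influx_m3s": influx,
        "total_outflux_m3s": outflux,
        "relative_flux_imbalance": abs(influx - outflux) / scale,
        "max_div_flux_fraction": float(np.abs(div).max() * vcell / scale),
    }


def flow_summary(sol: FlowSolution, mesh: LabeledMesh | None = None) -> dict:
    """Scalar report: per-region speeds (µm/s), inter-vessel flux, pressure
    drop from the arteriole side to the venule side."""
    speed = sol.speed() / UM  # µm/s
    out = {"max_speed_um_s": float(speed.max()),
           "mean_speed_um_s": float(speed[~sol.solid].mean()) if (~sol.solid).any() else 0.0}
    out.update(sol.diagnostics)
    if mesh is not None:
        from .geometry import RegionLabel
        for lab in RegionLabel:
            m = mesh.label == int(lab)
            if m.any():
                out[f"mean_speed_{lab.name.lower()}_um_s"] = float(speed[m].mean())
                out[f"max_speed_{lab.name.lower()}_um_s"] = float(speed[m].max())
        mid = 0.5 * mesh.geom.vessel_separation
        out["intervessel_flux_m3_s"] = sol.plane_flux(mid)
        pa = sol.pressure[mesh.label == int(RegionLabel.PAS)]
        pv = sol.pressure[mesh.label == int(RegionLabel.PVS)]
        if pa.size and pv.size:
            out["pressure_drop_pa"] = float(pa.mean() - pv.mean())
    return out
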