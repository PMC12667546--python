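"""Closed-form verification oracles for the flow and transport kernels.

Each oracle builds a degenerate configuration (homogeneous column, slab,
closed box, absorbing square) and runs it through the *production* solver
kernels — :func:`glymphsim.flow.solve_brinkman` and the transport stepping
kernel — comparing the result against an independent closed-form or
eigenfunction-series solution.  There is no separate reference discretisation:
what is validated is exactly the code the scenarios use.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .flow import SideBC, solve_brinkman
from .grid import UM, StructuredGrid
from .transport import TransportOperator, integrate_operator


@dataclass(frozen=True)
class OracleCase:
    """A named verification problem with its closed-form expectation."""

    name: str
    description: str
    tolerance: float           # relative tolerance on the headline quantity
    runner: Callable[[], dict]

    def run(self) -> dict:
        out = self.runner()
        out["name"] = self.name
        out["tolerance"] = self.tolerance
        out["rel_error"] = abs(out["measured"] - out["expected"]) / abs(out["expected"])
        out["passed"] = bool(out["rel_error"] <= self.tolerance)
        return out


def _uniform_face_arrays(shape, value):
    nx, ny, nz = shape
    return tuple(np.full((nx + (a == 0), ny + (a == 1), nz + (a == 2)),
                         float(value)) for a in range(3))


def darcy_column(kappa: float = 1e-12, dp: float = 1.0, length_um: float = 100.0,
                 mu: float = 1e-3, h_um: float = 5.0) -> OracleCase:
    """Pressure-driven homogeneous porous column: u = κ Δp / (µ L)."""

    def runner():
        g = StructuredGrid.from_box(((0, 20), (0, 20), (0, length_um)), h_um)
        nx, ny, nz = g.shape
        bcs = {
            "x-": SideBC.uniform((ny, nz), "slip"),
            "x+": SideBC.uniform((ny, nz), "slip"),
            "y-": SideBC.uniform((nx, nz), "slip"),
            "y+": SideBC.uniform((nx, nz), "slip"),
            "z-": SideBC.uniform((nx, ny), "open", 0.0),
            "z+": SideBC.uniform((nx, ny), "open", dp),
        }
        sol = solve_brinkman(g, np.zeros(g.shape, bool), np.full(g.shape, 0.2),
                             _uniform_face_arrays(g.shape, kappa), mu, bcs)
        measured = float(np.abs(sol.face_velocity[2]).mean())
        expected = kappa * dp / (mu * length_um * UM)
        return {"measured": measured, "expected": expected}

    return OracleCase("darcy_column",
                      "homogeneous pressure-driven column vs Darcy's law",
                      tolerance=0.01, runner=runner)


def poiseuille_slab(width_um: float = 100.0, length_um: float = 400.0,
                    kappa: float = 1e-6, mu: float = 1e-3,
                    dp: float = 1.0, n_across: int = 32) -> OracleCase:
    """High-permeability slab: centreline velocity vs plane Poiseuille."""

    def runner():
        hx = width_um / n_across
        g = StructuredGrid.from_box(((0, width_um), (0, 5), (0, length_um)),
                                    (hx, 5, 10))
        nx, ny, nz = g.shape
        bcs = {
            "x-": SideBC.uniform((ny, nz), "wall"),
            "x+": SideBC.uniform((ny, nz), "wall"),
            "y-": SideBC.uniform((nx, nz), "slip"),
            "y+": SideBC.uniform((nx, nz), "slip"),
            "z-": SideBC.uniform((nx, ny), "open", 0.0),
            "z+": SideBC.uniform((nx, ny), "open", dp),
        }
        sol = solve_brinkman(g, np.zeros(g.shape, bool), np.ones(g.shape),
                             _uniform_face_arrays(g.shape, kappa), mu, bcs)
        w = sol.face_velocity[2]
        profile = np.abs(w[:, 0, nz // 2])
        half = 0.5 * width_um * UM
        grad = dp / (length_um * UM)
        expected = half ** 2 * grad / (2 * mu)
        return {"measured": float(profile.max()), "expected": expected,
                "wall_velocity": float(min(profile[0], profile[-1]))}

    return OracleCase("poiseuille_slab",
                      "Brinkman free-fluid limit vs plane Poiseuille",
                      tolerance=0.05, runner=runner)


def gaussian_diffusion(D: float = 1e-9, sigma0_um: float = 20.0,
                       t_end: float = 1.0, h_um: float = 2.0) -> OracleCase:
    """Closed 1D column: Gaussian variance must grow as σ² + 2 D t."""

    def runner():
        g = StructuredGrid.from_box(((-200, 200), (0, 4), (0, 4)), (h_um, 4, 4))
        op = _free_operator(g, D, noflux=True)
        x = g.centers(0)[:, None, None] * UM
        c0 = np.exp(-0.5 * (x / (sigma0_um * UM)) ** 2) * np.ones(g.shape)
        m0 = op.mass(c0)

        def variance(c):
            m = op.storage * c
            mu_x = (m * x).sum() / m.sum()
            return float((m * (x - mu_x) ** 2).sum() / m.sum())

        v0 = variance(c0)
        c = c0
        t = 0.0
        while t < t_end - 1e-12:
            c = op.step(c, 0.05)
            t += 0.05
        return {"measured": variance(c), "expected": v0 + 2 * D * t_end,
                "mass_drift": abs(op.mass(c) - m0) / m0}

    return OracleCase("gaussian_diffusion",
                      "variance growth of a diffusing Gaussian, closed box",
                      tolerance=0.02, runner=runner)


def absorbing_disc_clearance(D: float = 1e-9, box_um: float = 200.0,
                             disc_radius_um: float = 50.0,
                             h_um: float = 2.5, n_modes: int = 60) -> OracleCase:
    """t95 of pure diffusion from a centred disc in an absorbing square vs the
    separation-of-variables eigenfunction series."""

    def runner():
        g = StructuredGrid.from_box(((0, box_um), (0, box_um), (0, 4)),
                                    (h_um, h_um, 4))
        op = _free_operator(g, D, noflux=False, absorb_xy=True)
        xc = g.centers(0)[:, None, None]
        yc = g.centers(1)[None, :, None]
        r2 = (xc - box_um / 2) ** 2 + (yc - box_um / 2) ** 2
        c0 = np.where(r2 <= disc_radius_um ** 2, 1.0, 0.0) * np.ones(g.shape)
        series = integrate_operator(op, c0, clearance_fraction=0.95,
                                    dt0=0.002, dt_rel=0.02)
        expected = _series_t95(D, box_um * UM, disc_radius_um * UM, n_modes)
        return {"measured": series.t95, "expected": expected,
                "steps": series.meta["steps"]}

    return OracleCase("absorbing_disc_clearance",
                      "95%-clearance time of a disc in an absorbing square vs "
                      "eigenfunction series",
                      tolerance=0.05, runner=runner)


def _free_operator(grid, D, noflux=True, absorb_xy=False):
    """Transport operator for free fluid (ε=1) with zero flow."""
    shape = grid.shape
    h = [s * UM for s in grid.spacing]
    face_G, face_q = [], []
    for a in range(3):
        A = grid.face_area(a) * UM ** 2
        fshape = tuple(s + (a == i) for i, s in zip(range(3), shape))
        face_G.append(np.full(fshape, D * A / h[a]))
        face_q.append(np.zeros(fshape))
    if absorb_xy:
        kinds = {s: "absorb" for s in ("x-", "x+", "y-", "y+")}
        kinds.update({"z-": "noflux", "z+": "noflux"})
    else:
        kinds = {s: "noflux" for s in ("x-", "x+", "y-", "y+", "z-", "z+")}
    vol = np.full(shape, grid.cell_volume * UM ** 3)
    return TransportOperator(grid, np.zeros(shape, bool), vol.copy(),
                             face_G, face_q, side_kinds=kinds,
                             cell_epsD=np.full(shape, D),
                             conv_weight=np.zeros(shape), vol_weight=vol)


def _series_t95(D, L, a, n_modes):
    """Eigenfunction-series mass fraction for a centred disc of radius ``a``
    in an absorbing square of side ``L``; returns the 95%-clearance time.

    Coefficients are computed by dense 2D quadrature of the disc indicator
    against the sine modes — independent of the finite-volume discretisation.
    """
    nq = 800
    x = (np.arange(nq) + 0.5) / nq * L
    disc = ((x[:, None] - L / 2) ** 2 + (x[None, :] - L / 2) ** 2) <= a ** 2
    m = np.arange(1, n_modes + 1)
    S = np.sin(np.pi * np.outer(m, x) / L) * (L / nq)   # (n_modes, nq)
    # A_mn (up to the 4/L² normalisation), and line integrals of each mode
    A = S @ disc @ S.T * (4 / L ** 2)
    line = (L / np.pi) * (1 - np.cos(np.pi * m)) / m
    lam = D * (np.pi / L) ** 2 * (m[:, None] ** 2 + m[None, :] ** 2)
    w = A * np.outer(line, line)
    M0 = w.sum()

    def frac(t):
        return (w * np.exp(-lam * t)).sum() / M0

    lo, hi = 0.0, 1.0
    while frac(hi) > 0.05:
        hi *= 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) > 0.05:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


ALL_ORACLES = (darcy_column, poiseuille_slab, gaussian_diffusion,
               absorbing_disc_clearance)


def run_all() -> list[dict]:
    """Run every oracle; returns one report dict per case."""
    return [factory().run() for factory in ALL_ORACLES]
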