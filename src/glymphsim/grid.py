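"""Structured Cartesian grid used by every solver stage.

All coordinates are in micrometres (the package's internal length unit);
solvers convert to SI at assembly time.  The grid is uniform per axis, which
keeps the staggered finite-volume stencils simple and symmetric.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UM = 1e-6  # metres per micrometre

# Side keys, in the order (axis, low/high).
SIDES = ("x-", "x+", "y-", "y+", "z-", "z+")


@dataclass(frozen=True)
class StructuredGrid:
    """Uniform box grid: cell (i, j, k) spans [x[i], x[i+1]] x ... in µm."""

    x: np.ndarray  # edge coordinates, shape (nx+1,)
    y: np.ndarray
    z: np.ndarray

    @classmethod
    def from_box(cls, bounds, h) -> "StructuredGrid":
        """Build a grid over ``bounds = ((x0,x1),(y0,y1),(z0,z1))`` (µm) with
        target cell size ``h`` (µm, scalar or per-axis triple)."""
        hs = np.broadcast_to(np.asarray(h, dtype=float), (3,))
        edges = []
        for (lo, hi), hv in zip(bounds, hs):
            n = max(1, int(round((hi - lo) / hv)))
            edges.append(np.linspace(lo, hi, n + 1))
        return cls(*edges)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.x) - 1, len(self.y) - 1, len(self.z) - 1)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (float(self.x[1] - self.x[0]),
                float(self.y[1] - self.y[0]),
                float(self.z[1] - self.z[0]))

    @property
    def cell_volume(self) -> float:
        """Volume of one cell in µm³."""
        hx, hy, hz = self.spacing
        return hx * hy * hz

    def centers(self, axis: int) -> np.ndarray:
        e = (self.x, self.y, self.z)[axis]
        return 0.5 * (e[:-1] + e[1:])

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable center coordinate arrays (xc[:,None,None], ...)."""
        xc = self.centers(0)[:, None, None]
        yc = self.centers(1)[None, :, None]
        zc = self.centers(2)[None, None, :]
        return xc, yc, zc

    def refined(self, factor: float = 1.25) -> "StructuredGrid":
        """Grid with ~``factor`` more cells per axis over the same box."""
        edges = []
        for e in (self.x, self.y, self.z):
            n = max(1, int(round((len(e) - 1) * factor)))
            edges.append(np.linspace(e[0], e[-1], n + 1))
        return StructuredGrid(*edges)

    def face_area(self, axis: int) -> float:
        """Area (µm²) of a face normal to ``axis``."""
        hx, hy, hz = self.spacing
        return (hy * hz, hx * hz, hx * hy)[axis]
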