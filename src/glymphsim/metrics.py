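"""Clearance metrics: flux decomposition, Péclet numbers, FUS comparisons.

The global Péclet number is defined as the ratio of the volume-integrated
convective flux magnitude ∫|u c| dV to the volume-integrated diffusive flux
magnitude ∫|ε D_eff ∇c| dV — a whole-domain measure of how much of the
instantaneous solute motion is carried by the flow versus by concentration
gradients.  Scalar summaries use the time average of Pe(t) over the clearance
interval [0, t95]; terminal and peak values are also reported since a single
printed Péclet number can reasonably mean any of the three.

Percent changes follow the (new - old)/old × 100 convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowSolution
from .geometry import RegionLabel
from .materials import MaterialField, SoluteSpec
from .transport import TransportOperator, TransportSeries


class MetricsError(ValueError):
    pass


@dataclass
class FluxDecomposition:
    """Volume-integrated |convective| and |diffusive| flux records."""

    times: np.ndarray
    conv: np.ndarray   # ∫|u c| dV over the integration region, mol·m/s
    diff: np.ndarray   # ∫|ε D_eff ∇c| dV, mol·m/s
    region: str = "domain"

    def __post_init__(self):
        if np.any(self.conv < 0) or np.any(self.diff < 0):
            raise MetricsError("flux magnitudes must be non-negative")

    @property
    def peak_conv(self) -> float:
        return float(self.conv.max())

    @property
    def peak_conv_time(self) -> float:
        return float(self.times[int(np.argmax(self.conv))])

    @property
    def peak_diff(self) -> float:
        return float(self.diff.max())

    @property
    def peak_diff_time(self) -> float:
        return float(self.times[int(np.argmax(self.diff))])

    def cumulative(self) -> tuple[float, float]:
        """Time integrals (∫Φ dt) of both flux records."""
        return (float(np.trapezoid(self.conv, self.times)),
                float(np.trapezoid(self.diff, self.times)))

    @classmethod
    def from_series(cls, series: TransportSeries) -> "FluxDecomposition":
        return cls(times=series.times.copy(), conv=series.conv_flux.copy(),
                   diff=series.diff_flux.copy())


@dataclass
class PecletReport:
    """Pe(t) record plus the scalar summaries."""

    times: np.ndarray
    pe: np.ndarray
    pe_mean: float      # time average over [0, t95] (or full record)
    pe_terminal: float
    pe_peak: float


@dataclass
class ComparisonResult:
    """Paired baseline-vs-FUS metrics for one scenario family."""

    label: str
    t95_base: float
    t95_fus: float
    time_ratio: float
    time_reduction_pct: float
    pe_base: float
    pe_fus: float
    peclet_ratio: float
    peclet_increase_pct: float
    conv_peak_fold: float
    diff_peak_fold: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time_ratio <= 0 or self.peclet_ratio <= 0:
            raise MetricsError("comparison ratios must be positive")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "label", "t95_base", "t95_fus", "time_ratio",
            "time_reduction_pct", "pe_base", "pe_fus", "peclet_ratio",
            "peclet_increase_pct", "conv_peak_fold", "diff_peak_fold")}
        d.update(self.extras)
        return d


def _region_mask(mesh, region):
    if region is None or region == "domain":
        return ~mesh.solid
    if isinstance(region, RegionLabel):
        return mesh.label == int(region)
    if isinstance(region, str):
        return mesh.label == int(RegionLabel[region.upper()])
    return np.asarray(region, bool)


def decompose_fluxes(states, flow: FlowSolution, materials: MaterialField,
                     solute: SoluteSpec, region=None) -> FluxDecomposition:
    """Flux integrals over ``region`` for a sequence of (t, c) states.

    ``states`` may be an iterable of (time, concentration-field) pairs or a
    TransportSeries (whose stored snapshots are then used).
    """
    mesh = materials.mesh
    if isinstance(states, TransportSeries):
        if region is None:
            return FluxDecomposition.from_series(states)
        states = sorted(states.snapshots.items())
    op = TransportOperator.from_fields(mesh, materials, flow, solute)
    mask = _region_mask(mesh, region)
    w = np.where(mask, 1.0, 0.0)
    times, conv, diff = [], [], []
    for t, c in states:
        if c.shape != mesh.grid.shape:
            raise MetricsError("state field does not match the mesh")
        conv.append(float((op.conv_weight * w * c).sum()))
        diff.append(float((op.cell_epsD * op.gradient_magnitude(c)
                           * op.vol_weight * w).sum()))
        times.append(float(t))
    name = ("domain" if region is None else
            region.name.lower() if isinstance(region, RegionLabel) else str(region))
    return FluxDecomposition(times=np.asarray(times), conv=np.asarray(conv),
                             diff=np.asarray(diff), region=name)


def peclet(flux: FluxDecomposition, t95: float | None = None) -> PecletReport:
    """Péclet record Pe(t) = Φ_conv/Φ_diff with undefined points masked."""
    ok = flux.diff > 0
    if not ok.any():
        raise MetricsError("diffusive flux is zero over the whole record; "
                           "Péclet number undefined")
    pe = np.where(ok, flux.conv / np.where(ok, flux.diff, 1.0), np.nan)
    t_end = t95 if t95 is not None else flux.times[-1]
    sel = (flux.times <= t_end) & ok
    if sel.sum() >= 2:
        tt, pp = flux.times[sel], pe[sel]
        pe_mean = float(np.trapezoid(pp, tt) / (tt[-1] - tt[0]))
    else:
        pe_mean = float(pe[ok][-1])
    return PecletReport(times=flux.times.copy(), pe=pe, pe_mean=pe_mean,
                        pe_terminal=float(pe[ok][-1]),
                        pe_peak=float(np.nanmax(pe)))


def spatial_peclet(c: np.ndarray, flow: FlowSolution,
                   materials: MaterialField, solute: SoluteSpec) -> np.ndarray:
    """Pointwise |u c| / |ε D_eff ∇c| field; NaN where the denominator is 0."""
    mesh = materials.mesh
    op = TransportOperator.from_fields(mesh, materials, flow, solute)
    num = flow.speed() * c
    den = op.cell_epsD * op.gradient_magnitude(c)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    out[mesh.solid] = np.nan
    return out


def compare(base, fus) -> ComparisonResult:
    """Baseline-vs-FUS comparison of two ScenarioResults.

    The runs must describe the same solute and initial distribution and differ
    only in the FUS condition.
    """
    for attr in ("solute", "distribution"):
        if getattr(base.config, attr) != getattr(fus.config, attr):
            raise MetricsError(
                f"scenario mismatch: {attr} differs "
                f"({getattr(base.config, attr)} vs {getattr(fus.config, attr)})")
    ratio = fus.t95 / base.t95
    pe_b, pe_f = base.peclet.pe_mean, fus.peclet.pe_mean
    return ComparisonResult(
        label=f"{base.config.solute}:{base.config.distribution}",
        t95_base=base.t95, t95_fus=fus.t95, time_ratio=ratio,
        time_reduction_pct=(1.0 - ratio) * 100.0,
        pe_base=pe_b, pe_fus=pe_f, peclet_ratio=pe_f / pe_b,
        peclet_increase_pct=(pe_f - pe_b) / pe_b * 100.0,
        conv_peak_fold=fus.fluxes.peak_conv / base.fluxes.peak_conv,
        diff_peak_fold=fus.fluxes.peak_diff / base.fluxes.peak_diff,
        extras={"pe_terminal_base": base.peclet.pe_terminal,
                "pe_terminal_fus": fus.peclet.pe_terminal,
                "pe_peak_base": base.peclet.pe_peak,
                "pe_peak_fus": fus.peclet.pe_peak})
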