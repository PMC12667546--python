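"""Scenario registry and orchestration.

A scenario is one full pipeline run: geometry → materials → flow → transport
→ metrics, for one condition (baseline, full-focus FUS, or an edge-of-focus
partial FUS restricted to the arteriole or venule side) and one solute /
initial-distribution choice.  The paper-suite driver runs the six canonical
paired comparisons; the sweep driver perturbs one physical parameter across a
multiplier ladder and reports the paired metrics per value.

Everything is deterministic: identical configurations produce identical
outputs bit for bit.
"""
from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import io as gio
from .flow import FlowBoundaryConditions, flow_summary, solve_flow
from .geometry import AVUnitGeometry, FocalPlane, RegionLabel, build_geometry
from .materials import (SOLUTES, FluidProperties, FUSPerturbation,
                        RegionProperties, SoluteSpec, assign_materials,
                        default_region_properties)
from .metrics import (ComparisonResult, FluxDecomposition, PecletReport,
                      compare, peclet)
from .transport import ConfigurationError, InitialDistribution, run_transport

CONDITIONS = ("baseline", "fus_full", "fus_pas_only", "fus_pvs_only")

#: Default mesh size (µm). Chosen as the coarsest resolution whose suite
#: ratios are mesh-converged to within a few percent; see docs/methods.md.
DEFAULT_RESOLUTION = 6.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one run."""

    condition: str = "baseline"
    solute: str = "tracer"
    distribution: str = "centralized"   # "centralized" | "uniform"
    label: str = ""
    resolution: float = DEFAULT_RESOLUTION
    geometry: AVUnitGeometry = field(default_factory=AVUnitGeometry)
    fus: FUSPerturbation = field(default_factory=FUSPerturbation)
    flow_bc: FlowBoundaryConditions = field(default_factory=FlowBoundaryConditions)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    region_properties: tuple = ()       # ((RegionLabel, RegionProperties), ...)
    bolus_radius: float = 40.0
    c0: float = 1.0
    clearance_fraction: float = 0.95
    snapshot_times: tuple = (1.0, 10.0, 30.0)
    dt0: float = 0.02
    dt_rel: float = 0.03
    output_dir: str | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if isinstance(self.solute, str) and self.solute not in SOLUTES:
            raise ConfigurationError(
                f"solute {self.solute!r} not in registry {sorted(SOLUTES)}")

    @property
    def fus_on(self) -> bool:
        return self.condition != "baseline"

    def solute_spec(self) -> SoluteSpec:
        return self.solute if isinstance(self.solute, SoluteSpec) else SOLUTES[self.solute]

    def base_properties(self) -> dict:
        props = default_region_properties()
        props.update(dict(self.region_properties))
        return props

    def effective_geometry(self) -> AVUnitGeometry:
        """Geometry with the FUS scale factor and (for partial conditions)
        the mid-vessel focal plane applied."""
        geom = replace(self.geometry, pvs_scale_factor=self.fus.pvs_scale_factor)
        if self.condition in ("fus_pas_only", "fus_pvs_only"):
            mid = 0.5 * geom.vessel_separation
            normal = (-1.0, 0.0) if self.condition == "fus_pas_only" else (1.0, 0.0)
            geom = replace(geom, focal_plane=FocalPlane((mid, 0.0), normal))
        return geom

    def digest(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScenarioResult:
    """One run's outputs and provenance."""

    config: ScenarioConfig
    t95: float
    series: object                 # TransportSeries
    fluxes: FluxDecomposition
    peclet: PecletReport
    flow_report: dict
    provenance: dict

    def __post_init__(self):
        if not self.t95 > 0:
            raise ConfigurationError("t95 must be positive")


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sensitivity sweep of the paired baseline/FUS comparison.

    ``parameter`` is one of 'pas_width' (scales both perivascular widths),
    'parenchyma_permeability', or 'parenchyma_porosity'.
    """

    parameter: str
    multipliers: tuple
    base: ScenarioConfig = field(default_factory=lambda: ScenarioConfig(
        condition="baseline", distribution="uniform"))

    def __post_init__(self):
        if self.parameter not in ("pas_width", "parenchyma_permeability",
                                  "parenchyma_porosity"):
            raise ConfigurationError(f"unknown sweep parameter {self.parameter!r}")
        if any(m <= 0 for m in self.multipliers):
            raise ConfigurationError("sweep multipliers must be positive")


def prepare_condition(cfg: ScenarioConfig):
    """Geometry + materials + flow for one condition (solute independent)."""
    geom = cfg.effective_geometry()
    mesh = build_geometry(geom, cfg.resolution, fus_on=cfg.fus_on)
    mat = assign_materials(mesh, cfg.base_properties(),
                           cfg.fus if cfg.fus_on else None)
    bc = replace(cfg.flow_bc, fus_inlet_velocity=cfg.fus.inlet_velocity)
    flow = solve_flow(mesh, mat, cfg.fluid, bc)
    return mesh, mat, flow


def run_scenario(cfg: ScenarioConfig, _prepared=None) -> ScenarioResult:
    """Execute the full pipeline for one configuration."""
    t_start = time.perf_counter()
    mesh, mat, flow = _prepared if _prepared is not None else prepare_condition(cfg)
    dist = InitialDistribution(kind=cfg.distribution,
                               bolus_radius=cfg.bolus_radius, c0=cfg.c0)
    series = run_transport(flow, mat, cfg.solute_spec(), dist,
                           clearance_fraction=cfg.clearance_fraction,
                           snapshot_times=cfg.snapshot_times,
                           dt0=cfg.dt0, dt_rel=cfg.dt_rel)
    fluxes = FluxDecomposition.from_series(series)
    pec = peclet(fluxes, t95=series.t95)
    freport = flow_summary(flow, mesh)
    prov = {
        "config_digest": cfg.digest(),
        "package_version": _version(),
        "mesh_cells": int(np.prod(mesh.grid.shape)),
        "fluid_cells": int((~mesh.solid).sum()),
        "transport_steps": series.meta.get("steps"),
        "mass_audit_residual": _mass_audit(series),
        "wall_time_s": round(time.perf_counter() - t_start, 3),
    }
    result = ScenarioResult(config=cfg, t95=series.t95, series=series,
                            fluxes=fluxes, peclet=pec, flow_report=freport,
                            provenance=prov)
    if cfg.output_dir:
        _write_outputs(result, mesh, flow)
    return result


def _version():
    from . import __version__

    return __version__


def _mass_audit(series) -> float:
    """|cleared mass − integrated boundary outflux| / initial mass."""
    cleared = series.mass[0] - series.mass[-1]
    return abs(cleared - series.outflux_integral) / series.mass[0]


def _write_outputs(result: ScenarioResult, mesh, flow):
    out = result.config.output_dir
    label = result.config.label or result.config.digest()
    base = os.path.join(out, label)
    os.makedirs(base, exist_ok=True)
    gio.export_series_csv(result.series, os.path.join(base, "series.csv"))
    gio.export_mesh(mesh, os.path.join(base, "mesh.vtu"))
    gio.export_flow(mesh, flow, os.path.join(base, "flow.vtu"))
    for t, c in result.series.snapshots.items():
        gio.export_concentration(mesh, c, os.path.join(base, f"conc_t{t:g}.vtu"))
    # spatial Péclet field at the mid snapshot (t = 10 s by default)
    from .metrics import spatial_peclet

    snaps = result.series.snapshots
    t_ref = min(snaps, key=lambda t: abs(t - 10.0))
    mat = assign_materials(mesh, result.config.base_properties(),
                           result.config.fus if result.config.fus_on else None)
    pe_field = spatial_peclet(snaps[t_ref], flow, mat, result.config.solute_spec())
    gio.export_concentration(mesh, np.nan_to_num(pe_field, nan=-1.0),
                             os.path.join(base, f"peclet_t{t_ref:g}.vtu"),
                             name="peclet")
    with open(os.path.join(base, "manifest.json"), "w") as fh:
        json.dump({"t95_s": result.t95, "provenance": result.provenance,
                   "flow": {k: v for k, v in result.flow_report.items()},
                   "pe_mean": result.peclet.pe_mean}, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# the six canonical paired comparisons
# ---------------------------------------------------------------------------

PAPER_ROWS = (
    ("centralized_tracer", "tracer", "centralized", "fus_full"),
    ("distributed_tracer", "tracer", "uniform", "fus_full"),
    ("amyloid_beta", "amyloid_beta", "uniform", "fus_full"),
    ("alpha_synuclein", "alpha_synuclein", "uniform", "fus_full"),
    ("pas_fus", "tracer", "centralized", "fus_pas_only"),
    ("pvs_fus", "tracer", "centralized", "fus_pvs_only"),
)


def run_paper_suite(resolution: float = DEFAULT_RESOLUTION,
                    output_dir: str | None = None, rows=PAPER_ROWS,
                    **config_overrides):
    """Run the canonical paired comparisons and return the consolidated table.

    Returns (DataFrame with one ComparisonResult row per scenario family,
    dict of all underlying ScenarioResults).  Flow solutions are shared
    across rows with the same condition; baseline runs are shared across
    comparisons with the same solute/distribution.
    """
    import pandas as pd

    prepared: dict[str, tuple] = {}
    results: dict[tuple, ScenarioResult] = {}

    def get(condition, solute, distribution):
        key = (condition, solute, distribution)
        if key not in results:
            cfg = ScenarioConfig(condition=condition, solute=solute,
                                 distribution=distribution,
                                 resolution=resolution,
                                 label=f"{condition}_{solute}_{distribution}",
                                 output_dir=output_dir, **config_overrides)
            if condition not in prepared:
                prepared[condition] = prepare_condition(cfg)
            results[key] = run_scenario(cfg, _prepared=prepared[condition])
        return results[key]

    records = []
    for label, solute, distribution, condition in rows:
        base = get("baseline", solute, distribution)
        fus = get(condition, solute, distribution)
        comp = compare(base, fus)
        rec = comp.to_dict()
        rec["label"] = label
        rec["condition"] = condition
        records.append(rec)
    table = pd.DataFrame.from_records(records)
    if output_dir:
        os.makedirs(output_dir, exist_ok=True)
        table.to_csv(os.path.join(output_dir, "paper_suite.csv"), index=False)
    return table, results


def run_sweep(spec: SweepSpec, resolution: float = DEFAULT_RESOLUTION):
    """Paired baseline/FUS comparison at each multiplier of one parameter."""
    import pandas as pd

    records = []
    for mult in spec.multipliers:
        base_cfg = replace(spec.base, resolution=resolution)
        if spec.parameter == "pas_width":
            g = base_cfg.geometry
            geom = replace(g, pas_width=g.pas_width * mult,
                           pvs_width=g.pvs_width * mult)
            base_cfg = replace(base_cfg, geometry=geom)
        else:
            props = dict(base_cfg.region_properties) or {}
            defaults = default_region_properties()
            par = props.get(RegionLabel.PARENCHYMA, defaults[RegionLabel.PARENCHYMA])
            if spec.parameter == "parenchyma_permeability":
                par = replace(par, permeability=par.permeability * mult)
            else:
                par = replace(par, porosity=par.porosity * mult)
            props[RegionLabel.PARENCHYMA] = par
            base_cfg = replace(base_cfg, region_properties=tuple(props.items()))
        fus_cfg = replace(base_cfg, condition="fus_full")
        b = run_scenario(base_cfg)
        f = run_scenario(fus_cfg)
        rec = compare(b, f).to_dict()
        rec.update({"parameter": spec.parameter, "multiplier": mult})
        records.append(rec)
    return pd.DataFrame.from_records(records)
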