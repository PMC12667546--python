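"""Scenario orchestration: registry, determinism, directional physics."""
import numpy as np
import pytest

from glymphsim.scenarios import (ScenarioConfig, SweepSpec, run_scenario,
                                 run_sweep)
from glymphsim.transport import ConfigurationError


def test_unknown_condition_rejected():
    with pytest.raises(ConfigurationError):
        ScenarioConfig(condition="sideways")
    with pytest.raises(ConfigurationError):
        ScenarioConfig(solute="unobtainium")


def test_suite_registry(coarse_suite):
    table, results = coarse_suite
    assert len(table) == 6
    assert set(table["label"]) == {"centralized_tracer", "distributed_tracer",
                                   "amyloid_beta", "alpha_synuclein",
                                   "pas_fus", "pvs_fus"}
    for res in results.values():
        assert res.t95 > 0
        assert res.provenance["config_digest"]


def test_fus_accelerates_all_families(coarse_suite):
    table, _ = coarse_suite
    assert (table["time_ratio"] < 1.0).all()
    assert (table["pe_fus"] > table["pe_base"]).all()


def test_baseline_t95_ordered_by_diffusivity(coarse_suite):
    """With identical flow, the least-diffusive solute takes longest to clear
    at baseline (amyloid-β slowest, tracer fastest)."""
    table, _ = coarse_suite
    row = table.set_index("label")
    assert (row.loc["amyloid_beta", "t95_base"]
            > row.loc["alpha_synuclein", "t95_base"]
            > row.loc["distributed_tracer", "t95_base"])


def test_amyloid_largest_peclet_increase(coarse_suite):
    """FUS shifts the convective/diffusive balance most for the solute that
    diffuses least."""
    table, _ = coarse_suite
    row = table.set_index("label")
    solutes = ["distributed_tracer", "alpha_synuclein", "amyloid_beta"]
    inc = row.loc[solutes, "peclet_increase_pct"]
    assert inc["amyloid_beta"] == inc.max()


def test_partial_focus_bracketed(coarse_suite):
    """A half-exposed unit clears faster than baseline but slower than a
    fully exposed one, for either exposed side."""
    table, _ = coarse_suite
    row = table.set_index("label")
    t_full = row.loc["centralized_tracer", "t95_fus"]
    t_base = row.loc["centralized_tracer", "t95_base"]
    for fam in ("pas_fus", "pvs_fus"):
        assert t_full < row.loc[fam, "t95_fus"] < t_base


def test_determinism():
    cfg = ScenarioConfig(condition="baseline", distribution="uniform",
                         resolution=14.0)
    a = run_scenario(cfg)
    b = run_scenario(cfg)
    assert a.t95 == b.t95
    assert np.array_equal(a.series.mass, b.series.mass)
    assert a.provenance["config_digest"] == b.provenance["config_digest"]


def test_outputs_written(tmp_path):
    from dataclasses import replace

    cfg = ScenarioConfig(condition="baseline", distribution="uniform",
                         resolution=14.0, label="smoke",
                         output_dir=str(tmp_path))
    run_scenario(cfg)
    base = tmp_path / "smoke"
    for name in ("series.csv", "mesh.vtu", "flow.vtu", "manifest.json"):
        assert (base / name).exists()
    # VTU is well-formed XML
    import xml.etree.ElementTree as ET

    root = ET.parse(base / "flow.vtu").getroot()
    assert root.tag == "VTKFile"


def test_sweep_mechanics():
    """The sweep driver produces one paired comparison per multiplier, and
    cutting parenchymal permeability tenfold slows clearance in both
    conditions."""
    spec = SweepSpec(parameter="parenchyma_permeability", multipliers=(0.1, 1.0))
    t = run_sweep(spec, resolution=12.0).set_index("multiplier")
    assert len(t) == 2
    assert (t["t95_base"] > 0).all() and (t["t95_fus"] > 0).all()
    assert t.loc[0.1, "t95_base"] > t.loc[1.0, "t95_base"]
    assert t.loc[0.1, "t95_fus"] > t.loc[1.0, "t95_fus"]


def test_config_yaml_roundtrip(tmp_path):
    from glymphsim.cli import _load_config

    cfgfile = tmp_path / "run.yaml"
    cfgfile.write_text(
        "condition: fus_full\nsolute: amyloid_beta\ndistribution: uniform\n"
        "resolution: 12.0\ngeometry:\n  pas_width: 12.0\n"
        "fus:\n  permeability_factor: 2.5\n")
    cfg = _load_config(str(cfgfile))
    assert cfg.condition == "fus_full"
    assert cfg.geometry.pas_width == 12.0
    assert cfg.fus.permeability_factor == 2.5
    bad = tmp_path / "bad.yaml"
    bad.write_text("conditon: typo\n")
    with pytest.raises(ConfigurationError, match="unknown config keys"):
        _load_config(str(bad))
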