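"""Shared fixtures.

Scenario-level fixtures run at a coarse test resolution so the whole suite
stays within a desktop-scale budget; the acceptance fixtures run the paired
headline comparisons at the package's default resolution.  Everything is
session-scoped: the expensive pipelines execute once per session.
"""
from __future__ import annotations

import numpy as np
import pytest

from glymphsim.scenarios import run_paper_suite
from glymphsim.verification import run_all

#: Coarse mesh size (µm) for directional / property tests.
COARSE = 10.0


@pytest.fixture(scope="session")
def oracle_reports():
    return {r["name"]: r for r in run_all()}


@pytest.fixture(scope="session")
def coarse_suite():
    """All six canonical paired comparisons at coarse resolution."""
    table, results = run_paper_suite(resolution=COARSE)
    return table, results


@pytest.fixture(scope="session")
def default_pairs():
    """The four solute/distribution families at default resolution (the
    quantitative headline comparisons)."""
    rows = (
        ("centralized_tracer", "tracer", "centralized", "fus_full"),
        ("distributed_tracer", "tracer", "uniform", "fus_full"),
        ("amyloid_beta", "amyloid_beta", "uniform", "fus_full"),
        ("alpha_synuclein", "alpha_synuclein", "uniform", "fus_full"),
    )
    table, results = run_paper_suite(rows=rows)
    return {r["label"]: r for r in table.to_dict("records")}, results
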