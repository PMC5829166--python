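"""Shared fixtures: tiny genomes and session-scoped simulated panels.

The heavier simulated panels are session-scoped so the end-to-end recovery
tests and the acceptance suite share one simulation per configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

import hydenseq as hq


@pytest.fixture()
def tiny_genome() -> hq.Genome:
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    return hq.Genome(lengths={"chrT": 1000}, sequence={"chrT": seq})


@pytest.fixture()
def small_sim_config() -> hq.SimConfig:
    """Fast simulator settings for unit-level checks."""
    return hq.SimConfig(
        seed=11,
        chromosome_length=60_000,
        n_origins_per_chromosome=2,
        n_cells=30,
        depth=60_000,
        n_sbfi_sites_per_chromosome=20,
    )


@pytest.fixture(scope="session")
def panel_1e6() -> hq.PanelSim:
    """Study-condition panel: 4 origins x 200 kb, 1e6 ends per library."""
    return hq.simulate_panel(hq.SimConfig(seed=7, depth=1_000_000, n_cells=200))


@pytest.fixture(scope="session")
def results_1e6(panel_1e6: hq.PanelSim) -> hq.PanelResults:
    return hq.analyze_panel(
        panel_1e6.tracks(), panel_1e6.sheet(), panel_1e6.genome, panel_1e6.origins
    )
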