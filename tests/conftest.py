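"""Shared fixtures: small synthetic studies reused across test modules."""

from dataclasses import replace

import pytest

from barcodeauth.distances import distance_matrix
from barcodeauth.simulate import (
    SimulationConfig,
    make_market_study,
    simulate_alignment,
)


@pytest.fixture(scope="session")
def panel_study():
    """(Alignment, GroupMap) for the default reference panel, seed 3."""
    return simulate_alignment(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def panel_dm(panel_study):
    aln, _ = panel_study
    return distance_matrix(aln)


@pytest.fixture(scope="session")
def flat_study():
    """Panel alignment with all branch lengths zero: every sequence identical."""
    cfg = SimulationConfig(seed=5)
    flat = replace(
        cfg, groups=tuple(replace(g, stem=0.0, tip_spread=0.0) for g in cfg.groups)
    )
    return simulate_alignment(flat)


@pytest.fixture(scope="session")
def market_study():
    """Full synthetic market study (22 samples, 7 authentic), seed 11."""
    return make_market_study(SimulationConfig(seed=11))
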