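"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from admixrisk.simulate import (
    PopulationProfile,
    SimulationConfig,
    simulate_study,
)

CHOCO_ALPHA = (15 * 0.76, 15 * 0.13, 15 * 0.11)
ANTIOQUIA_ALPHA = (15 * 0.07, 15 * 0.75, 15 * 0.18)


@pytest.fixture(scope="session")
def effect_study():
    """Two-cohort study with a +0.15 risk shift toward African-like ancestry."""
    cfg = SimulationConfig(
        n_snps=1200,
        n_risk_snps=165,
        risk_shift_delta=0.15,
        shift_target_ancestry=0,
        missing_rate=0.01,
        seed=20_250,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Two cohorts with identical ancestry profiles and no risk shift."""
    cfg = SimulationConfig(
        n_snps=1200,
        n_risk_snps=165,
        risk_shift_delta=0.0,
        missing_rate=0.01,
        seed=20_251,
        pop_profiles=(
            PopulationProfile("cohort_a", 94, CHOCO_ALPHA),
            PopulationProfile("cohort_b", 94, CHOCO_ALPHA),
        ),
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12_345)
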