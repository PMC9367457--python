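import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from npcpipe.synthetic import (
    PlantedEffect,
    SimulationConfig,
    simulate_cancer_gene_sources,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-effect cohort shared by read-only tests."""
    config = SimulationConfig(
        n_cases=119,
        n_controls=1337,
        n_validation_cases=156,
        n_validation_controls=600,
        n_panel=800,
        n_variants=80,
        n_genes=16,
        planted_effects=[PlantedEffect("GENE0001", 20.0, n_variants=1, maf=0.01)],
        seed=42,
    )
    sim = simulate_cohort(config)
    sources = simulate_cancer_gene_sources(
        sorted({v.gene for v in sim.variants}), ["GENE0001"], seed=43
    )
    return config, sim, sources


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
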