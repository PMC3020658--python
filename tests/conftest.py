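import pytest

from pancore.pipeline import run_pipeline
from pancore.simulate import SimulationConfig, simulate_pangenome


@pytest.fixture(scope="session")
def small_world():
    """Three genera of three isolates, small proteins, low divergence:
    the whole alignment pipeline runs in a few seconds with exact planted
    structure recoverable."""
    config = SimulationConfig(
        n_genera=3, isolates_per_genus=3, species_per_genus=2,
        n_core_families=30, n_unique_families=8, n_dispensable_families=12,
        singlets_per_isolate=3, protein_length=100,
        within_genus_divergence=0.05, between_genus_divergence=0.15,
        seed=11,
    )
    pset, marker, truth = simulate_pangenome(config)
    result = run_pipeline(pset, M=0.01)
    return pset, marker, truth, result


@pytest.fixture(scope="session")
def recovery():
    """Parameter-recovery run at the default family structure."""
    from pancore.experiments import recovery_experiment

    return recovery_experiment(1)
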