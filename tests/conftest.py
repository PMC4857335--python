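import pytest

from stromatsp import SimulationParams, generate_codeset, simulate_cohort


@pytest.fixture(scope="session")
def codeset():
    return generate_codeset(102, 5)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort (12 genes, 2 housekeeping, 5+5 lanes) for I/O tests."""
    cs = generate_codeset(12, 2)
    params = SimulationParams(n_group_a=5, n_group_b=5, seed=42,
                              dropout_prob=0.05)
    cm, truth = simulate_cohort(cs, params)
    return cm, truth


@pytest.fixture(scope="session")
def default_cohort(codeset):
    """Full-size cohort at generator defaults (20 GP3 + 21 GP4 lanes)."""
    cm, truth = simulate_cohort(codeset, SimulationParams(seed=7))
    return cm, truth
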