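import pytest
from hypothesis import HealthCheck, settings

from cgikit import SimulationConfig, simulate_genome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The standard 2 Mb planted-island genome (100 islands, 0.002/0.08)."""
    config = SimulationConfig(seed=1)
    chrom, truth = simulate_genome(config)
    return config, chrom, truth


@pytest.fixture(scope="session")
def small_sim():
    """A 300 kb genome with 15 planted islands, for faster checks."""
    config = SimulationConfig(seed=7, genome_length=300_000, n_islands=15)
    chrom, truth = simulate_genome(config)
    return config, chrom, truth


def overlaps_any(start, end, intervals):
    """>= 1 bp overlap of [start, end) with any (start, end) pair."""
    return any(s < end and e > start for s, e in intervals)
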