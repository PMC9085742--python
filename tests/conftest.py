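import pytest

from mprakit.config import SimulationConfig
from mprakit import simulate as msim


SMALL_KWARGS = dict(
    seed=1,
    n_de_novo=60,
    n_inherited=40,
    n_tss=10,
    n_planted_overlaps=3,
    contig_lengths={"chr1": 300_000, "chr2": 300_000},
)


@pytest.fixture
def small_config():
    return SimulationConfig(**SMALL_KWARGS)


@pytest.fixture(scope="session")
def small_scenario():
    """100-variant scenario shared by fast unit tests (treat as read-only)."""
    return msim.simulate_scenario(SimulationConfig(**SMALL_KWARGS))


@pytest.fixture(scope="session")
def power_scenario():
    """Default operating point: depth 500, |log2FC| 1, dispersion 0.05, 3+3."""
    cfg = SimulationConfig(
        seed=11, n_de_novo=700, n_inherited=500, n_tss=20,
        n_pdna_reps=3, n_cdna_reps=3, n_planted_overlaps=8,
    )
    return cfg, msim.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def null_scenario():
    """10,000 elements, nothing planted: type-I error / independence checks."""
    cfg = SimulationConfig(
        seed=7, n_de_novo=1500, n_inherited=1000, n_tss=20,
        frac_active_ref=0.0, frac_effect_variants=0.0, n_planted_overlaps=0,
    )
    return cfg, msim.simulate_scenario(cfg)
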