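import pytest

from clonediv import SimulationConfig, generate_truth, render_dataset


@pytest.fixture(scope="session")
def default_truth():
    return generate_truth(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_bundle(default_truth):
    return render_dataset(default_truth)


def small_config(seed: int, **overrides) -> SimulationConfig:
    """Down-scaled genome for loops where only the SNV/CNA layers matter;
    branch SNV counts and all statistical couplings stay at their defaults."""
    params = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length_bp=8_000_000,
        n_genes=800,
        n_cgi=150,
        n_cpg_sites=8_000,
        n_repeats=60,
        n_planted_dmgb=40,
        n_planted_dmp=25,
        n_extra_deg=40,
    )
    params.update(overrides)
    return SimulationConfig(**params)
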