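import numpy as np
import pytest

from asescale import (
    FrequencyModel,
    SimulationConfig,
    apply_variant_filters,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def ushaped_dataset():
    """Small low-MAF-enriched dataset: 50 individuals x ~200 sequence-like SNPs.

    Filtered only for monomorphism so that rare variants stay in, which is
    exactly where the two codings disagree.
    """
    config = SimulationConfig(
        n_individuals=50,
        n_snps=200,
        h2=0.5,
        gamma_true=-1.0,
        frequency_model=FrequencyModel("ushaped"),
        mean_weight=10.0,
        weight_model="poisson-like",
        seed=7,
    )
    data = simulate_dataset(config)
    filtered, _ = apply_variant_filters(
        data.genotypes, min_minor_copies=1, require_all_genotypes=False
    )
    return data, filtered


@pytest.fixture(scope="session")
def uniform_dataset():
    """Array-like dataset with common variants and equal weights."""
    config = SimulationConfig(
        n_individuals=500,
        n_snps=300,
        h2=0.5,
        gamma_true=0.0,
        frequency_model=FrequencyModel("uniform"),
        mean_weight=1.0,
        seed=11,
    )
    data = simulate_dataset(config)
    filtered, _ = apply_variant_filters(
        data.genotypes, min_minor_copies=2, require_all_genotypes=False
    )
    return data, filtered


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
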