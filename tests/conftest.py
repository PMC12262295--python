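import numpy as np
import pytest

from bindxpress.synthetic import SyntheticConfig, generate_bundle


def tiny_config(seed: int = 11, **overrides) -> SyntheticConfig:
    """A small, fast bundle configuration for unit tests."""
    base = dict(
        seed=seed,
        n_chroms=2,
        chrom_length=120_000,
        n_genes=48,
        n_true_targets=10,
        n_decoy_bound=8,
        n_tissues=3,
        n_background_peaks_per_set=10,
        n_spcg=12,
        noise_lfc_sd=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition bundle shared across read-only tests."""
    return generate_bundle(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_bundle(tiny_config())


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
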