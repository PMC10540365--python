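import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adqtl.relatedness import build_grms
from adqtl.simulate import simulate_genotypes, simulate_trait

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def medium_genotypes():
    """Shared 300 x 600 HWE genotype matrix (5 chromosomes)."""
    return simulate_genotypes(300, 600, seed=11)


@pytest.fixture(scope="session")
def medium_grms(medium_genotypes):
    return build_grms(medium_genotypes)


@pytest.fixture(scope="session")
def medium_trait(medium_genotypes, medium_grms):
    """Trait with one additive and one dominance QTL on the shared matrix."""
    y, truth = simulate_trait(
        medium_genotypes,
        [("snp00050", 0.5, 0.0), ("snp00400", 0.0, 0.6)],
        sigma_a2=0.25,
        sigma_d2=0.12,
        grms=medium_grms,
        seed=12,
    )
    return y, truth
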