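import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ampliopt.mock import theoretical_composition
from ampliopt.refs import (
    default_primer_pairs,
    extract_amplicon,
    mock1_members,
    mock2_members,
    synthetic_reference_set,
)
from ampliopt.simulate import ERROR_FREE_QUALITY, SimConfig, simulate_pairs


@pytest.fixture(scope="session")
def primer_pairs():
    return default_primer_pairs()


@pytest.fixture(scope="session")
def mock1_comp():
    return theoretical_composition(mock1_members())


@pytest.fixture(scope="session")
def mock2_comp():
    return theoretical_composition(mock2_members())


@pytest.fixture(scope="session")
def refs_mock1(mock1_comp):
    return synthetic_reference_set(list(mock1_comp.abundances))


@pytest.fixture(scope="session")
def v34_amplicons(refs_mock1, primer_pairs, mock1_comp):
    pair = primer_pairs["V3-V4"]
    return {t: extract_amplicon(refs_mock1[t], pair) for t in mock1_comp.abundances}


@pytest.fixture(scope="session")
def perfect_reads_v34(mock1_comp, primer_pairs, v34_amplicons):
    """5,000 error-free, chimera-free 300 bp pairs from mock1 over V3-V4."""
    cfg = SimConfig(
        seed=11,
        n_pairs=5000,
        read_len=300,
        pair=primer_pairs["V3-V4"],
        composition=mock1_comp,
        chimera_rate=0.0,
        fwd_quality=ERROR_FREE_QUALITY,
        rev_quality=ERROR_FREE_QUALITY,
    )
    return simulate_pairs(cfg, v34_amplicons)


@pytest.fixture(scope="session")
def noisy_reads_v34(mock1_comp, primer_pairs, v34_amplicons):
    """5,000 default-quality pairs with 5% chimeras (the realistic regime)."""
    cfg = SimConfig(
        seed=12,
        n_pairs=5000,
        read_len=300,
        pair=primer_pairs["V3-V4"],
        composition=mock1_comp,
        chimera_rate=0.05,
    )
    return simulate_pairs(cfg, v34_amplicons)
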