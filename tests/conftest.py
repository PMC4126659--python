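import numpy as np
import pytest

from krillselect import build_virtual_population, reference


@pytest.fixture(scope="session")
def small_population():
    """~200 individuals spanning 12-64 mm, enough for coarse selection curves."""
    return build_virtual_population(
        np.arange(12.0, 64.1, 2.0),
        8,
        reference.KRILL_LENGTH_REGRESSIONS,
        reference.KRILL_COEFF_MODELS,
        seed=202,
    )


@pytest.fixture(scope="session")
def deterministic_population():
    """Noise-free population: penetration outcomes are knife-edge in length."""
    zero = {k: 0.0 for k in reference.KRILL_RESIDUAL_SDS}
    return build_virtual_population(
        np.arange(12.0, 64.1, 0.5),
        1,
        reference.KRILL_LENGTH_REGRESSIONS,
        reference.KRILL_COEFF_MODELS,
        residual_sds=zero,
        seed=0,
    )
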