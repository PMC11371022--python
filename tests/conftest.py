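"""Shared fixtures: the canonical network and its fitted exposure surface.

The exposure surface costs one stiff integration per grid point, so it is
built once per session on a moderate grid (4 doses x 11 log-spaced dose
rates spanning conventional through FLASH delivery).
"""

import numpy as np
import pytest

from flashsr.radiolysis_kinetics import (
    default_network,
    exposure_surface,
    fit_surrogate,
)

CANONICAL_DOSES = np.array([5.0, 10.0, 20.0, 30.0])
CANONICAL_RATES = np.geomspace(1e-2, 1e7, 11)


@pytest.fixture(scope="session")
def canonical_network():
    return default_network()


@pytest.fixture(scope="session")
def canonical_surface(canonical_network):
    return exposure_surface(canonical_network, CANONICAL_DOSES, CANONICAL_RATES)


@pytest.fixture(scope="session")
def canonical_surrogate(canonical_surface):
    return fit_surrogate(canonical_surface, poly_degree=3)
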