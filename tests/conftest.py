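"""Shared fixtures: small random configurations and descriptor sets."""

import numpy as np
import pytest

from cgmatch.core import Configuration
from cgmatch.descriptors import SymmetryFunctionSpec

R_CUT = 2.5


def random_configuration(rng, n=None, periodic=False, spread=4.0, min_dist=0.3):
    """Non-degenerate random cluster (or periodic box) of up to 6 sites."""
    if n is None:
        n = int(rng.integers(2, 7))
    while True:
        pos = rng.uniform(0.0, spread, (n, 3))
        box = np.full(3, max(spread, 2 * R_CUT) + 0.5) if periodic else None
        d = pos[:, None, :] - pos[None, :, :]
        if box is not None:
            d -= box * np.round(d / box)
        r = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(r, np.inf)
        if r.min() > min_dist:
            return Configuration(pos, box)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def mixed_specs():
    """A small representative set of radial and angular descriptors."""
    return [
        SymmetryFunctionSpec.radial(3.429, 0.5, R_CUT),
        SymmetryFunctionSpec.radial(0.001, 1.2, R_CUT),
        SymmetryFunctionSpec.radial(15.0, 0.0, R_CUT),
        SymmetryFunctionSpec.angular(0.1, 4.0, 1, R_CUT),
        SymmetryFunctionSpec.angular(1.0, 2.0, -1, R_CUT),
        SymmetryFunctionSpec.angular(0.01, 1.0, 1, R_CUT),
    ]
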