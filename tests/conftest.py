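"""Shared fixtures: small synthetic scenes reused across test modules.

Expensive scenes are session-scoped; every generator call is seeded so the
whole suite is deterministic.
"""

import numpy as np
import pytest

from biofilmkit import synthgen


@pytest.fixture(scope="session")
def small_motility_video():
    """50-cell H₂-preset video (5 s, 20 fps) plus its ground truth."""
    return synthgen.simulate_motility_video("h2_motility", n_cells=50, seed=3)


@pytest.fixture(scope="session")
def small_detachment_series():
    """Three-cycle H₂ detachment series at 2 frames per phase."""
    return synthgen.simulate_detachment_series("h2_three_cycle",
                                               frames_per_phase=2, seed=7)


@pytest.fixture(scope="session")
def small_zstack():
    """Two-ellipsoid Z-stack with ground truth."""
    specs = [
        {"center": (60, 60, 21), "semi_axes": (20, 15, 5)},
        {"center": (100, 30, 10), "semi_axes": (10, 8, 4)},
    ]
    return synthgen.simulate_biofilm_zstack(specs, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
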