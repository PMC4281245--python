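"""Shared fixtures.

The full separation x fixation sweep is the most expensive computation the
suite needs; it is run once per session and shared by the experiment-level
and acceptance tests.
"""

import pytest

import scfield as sf


@pytest.fixture(scope="session")
def default_sweep():
    """The default sweep: 15-150 deg x {weak, strong} fixation."""
    return sf.run_sweep(sf.SweepSpec())


@pytest.fixture(scope="session")
def small_geometry():
    """A coarse field for fast dynamical property tests.

    The recurrent term is a mean-field average, so the dynamics are
    grid-resolution independent; 200 nodes keep property tests cheap.
    """
    return sf.FieldGeometry(n_nodes=200, extent_mm=5.0)
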