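"""Shared fixtures.

The expensive stochastic protocols (20-replicate runs of the default 2D
condition) are session-scoped so that the baseline, amplitude and
cross-engine equivalence checks all reuse the same simulations.
"""

from __future__ import annotations

import numpy as np
import pytest

from astroca import core, protocols


@pytest.fixture(scope="session")
def table1_kinetics():
    return core.table1_kinetics()


@pytest.fixture(scope="session")
def table1_space():
    return core.table1_space()


@pytest.fixture(scope="session")
def fig2_ssa(table1_kinetics, table1_space):
    """20 replicate SSA runs of the default well-mixed condition."""
    return protocols.replicate_run("ssa", table1_kinetics, table1_space,
                                   T=10_000.0, n=20, base_seed=1000)


@pytest.fixture(scope="session")
def fig2_particle(table1_kinetics, table1_space):
    """20 replicate particle runs, D = inf, eta = 1, R_gamma = 200."""
    return protocols.replicate_run("particle2d", table1_kinetics,
                                   table1_space, T=10_000.0, n=20,
                                   base_seed=2000)
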