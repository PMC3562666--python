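"""Shared fixtures: reduced-size configurations and cached simulation runs.

Full-resolution 48-hour runs are expensive, so they are session-scoped and
shared by the acceptance tests; unit and property tests use coarse grids
(60 + 24 cells), which retain every mechanism of the model at a fraction
of the cost.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from liposim import default_config, simulate
from liposim.config import NumericsParams

settings.register_profile("ci", derandomize=True, max_examples=25)
settings.load_profile("ci")

COARSE = dict(n_tumour=60, n_normal=24)


def coarse_numerics(**kw) -> NumericsParams:
    base = dict(COARSE, dt=10.0, t_end=172800.0, output_every=60.0)
    base.update(kw)
    return NumericsParams(**base)


def with_numerics(cfg, **kw):
    return dataclasses.replace(cfg, numerics=coarse_numerics(**kw))


@pytest.fixture(scope="session")
def liposome_coarse():
    """48-h liposome-mode run on the coarse grid."""
    return simulate(with_numerics(default_config("liposome")))


@pytest.fixture(scope="session")
def infusion_coarse():
    """48-h infusion-mode run on the coarse grid."""
    return simulate(with_numerics(default_config("infusion")))


@pytest.fixture(scope="session")
def infusion_default():
    """48-h infusion-mode run at the default (250 + 100 cell) resolution."""
    return simulate(default_config("infusion"))


@pytest.fixture(scope="session")
def liposome_default():
    """48-h liposome-mode run at the default resolution."""
    return simulate(default_config("liposome"))


@pytest.fixture(scope="session")
def zero_flow():
    """Factory for a quiescent flow field (no filtration, drainage or flow)."""
    from liposim.flow import FlowField

    def make(grid):
        n = grid.n_cells
        return FlowField(grid=grid, p_i=np.zeros(n), v_face=np.zeros(n + 1),
                         fv=np.zeros(n), fly=np.zeros(n))

    return make
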