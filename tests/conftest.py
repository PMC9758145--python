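"""Shared fixtures: phantoms, dose engines, and the seed-stability study."""

from __future__ import annotations

import numpy as np
import pytest

import protonarc as pa
from protonarc.phantom import (PhantomSpec, cylinder, expand_ring,
                               healthy_region, make_phantom, skin_shell,
                               sphere)


@pytest.fixture(scope="session")
def reference():
    return pa.reference_phantom()


@pytest.fixture(scope="session")
def reference_engine(reference):
    return pa.DoseEngine(reference)


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Water cylinder with a centred (on the x = 0 plane) cylindrical target,
    mirror-symmetric under patient left-right reflection."""
    spec = PhantomSpec(grid_shape=(64, 64, 1), voxel_size=(2.0, 2.0, 2.0),
                       body=cylinder((0, 0, 0), 60.0),
                       target=cylinder((0, -20, 0), 10.0))
    ph = make_phantom(spec)
    ph.structures["ring10mm"] = expand_ring(ph, "target", 10.0)
    ph.structures["skin"] = skin_shell(ph, 5.0)
    ph.structures["brain"] = healthy_region(ph)
    return ph


@pytest.fixture()
def water_slab():
    """Deep uniform water box for depth-dose checks (anterior beam at 0 deg
    travels along -y through water)."""
    from protonarc.phantom import Primitive
    spec = PhantomSpec(grid_shape=(11, 128, 1), voxel_size=(2.0, 2.0, 2.0),
                       body=Primitive("box", (0.0, 0.0, 0.0),
                                      (11.0, 128.0, 1.0)),
                       target=sphere((0.0, -60.0, 0.0), 8.0))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def stability_study(reference):
    """Ten full genetic optimizations with distinct seeds on the reference
    phantom — the convergence-stability experiment reused by several tests."""
    cfg = pa.RunConfig(seed=1)
    return pa.run_stability_study(cfg, n_seeds=10, phantom=reference)
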