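"""Shared fixtures: phantoms and their derived objects are expensive, so the
standard two-fragment cup phantom (seed 1) and its template/region/reduction
are built once per session."""

import numpy as np
import pytest

from fract3d.geometry import Plane
from fract3d.metrics import SphericalCupRegion
from fract3d.phantom import PhantomSpec, make_phantom
from fract3d.reduction import build_mirror_template, reduce_fragments


@pytest.fixture(scope="session")
def cup_phantom():
    """Two-fragment fractured cup with known displacements (seed 1)."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def template(cup_phantom):
    """Mirror of the intact contralateral side, overlaying the fractured side."""
    return build_mirror_template(
        cup_phantom.intact, Plane(point=[0.0, 0.0, 0.0], normal=[1.0, 0.0, 0.0])
    )


@pytest.fixture(scope="session")
def region(template):
    return SphericalCupRegion.fit(template)


@pytest.fixture(scope="session")
def reduction(cup_phantom, template):
    return reduce_fragments(cup_phantom.pre, template)


@pytest.fixture(scope="session")
def reduced_fragments(cup_phantom, reduction):
    from fract3d.io import FragmentSet

    meshes = []
    for fid, m in cup_phantom.pre:
        rm = m.copy()
        rm.apply_transform(reduction.transforms[fid].to_matrix())
        rm.metadata["fragment_id"] = fid
        meshes.append(rm)
    return FragmentSet(meshes=meshes,
                       fragment_ids=list(cup_phantom.pre.fragment_ids))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
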