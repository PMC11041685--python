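import numpy as np
import pytest

from fractasm.geometry import GeometryParams, build_hexamer, build_sierpinski


@pytest.fixture(scope="session")
def params():
    return GeometryParams()


@pytest.fixture(scope="session")
def hexamer(params):
    return build_hexamer(params)


@pytest.fixture(scope="session")
def level1(params):
    return build_sierpinski(1, params)


@pytest.fixture(scope="session")
def level2(params):
    return build_sierpinski(2, params)


def rotate_assembly(assembly, angle_deg, about=None):
    """Return a deep-rotated copy of an assembly (about the z axis)."""
    import copy
    import math

    a = copy.deepcopy(assembly)
    th = math.radians(angle_deg)
    R = np.array(
        [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
    )
    pts = assembly.monomer_positions()[:, :2]
    ctr = pts.mean(axis=0) if about is None else np.asarray(about, dtype=float)
    for m in a.monomers:
        m.position[:2] = R @ (m.position[:2] - ctr) + ctr
    for h in a.hexamers:
        h.center[:2] = R @ (h.center[:2] - ctr) + ctr
    for d in a.dimers:
        d.corner_direction = R @ d.corner_direction
    return a
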