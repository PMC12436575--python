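"""Shared fixtures: small analytic meshes and one mid-size porous pipeline."""

import numpy as np
import pytest

from osteogrow import (PoreSpec, RemodelingParams, build_adjacency,
                       extract_anchor_submesh, generate_porous_domain,
                       mesh_domain, rect_mesh, run_ingrowth)
from osteogrow.porous_geometry import ANCHOR, VOID, FEMesh


@pytest.fixture(scope="session")
def unit_square():
    return rect_mesh(1.0, 1.0, 0.25)


@pytest.fixture(scope="session")
def small_porous():
    """Mid-size porous quarter domain + mesh (anchor r=2 mm, 300 um pores)."""
    spec = PoreSpec(300.0, 100.0, 0.60, rng_seed=11)
    dom = generate_porous_domain(spec, anchor_radius=2.0, slice_thickness=2.0,
                                 bone_layer=0.5)
    mesh = mesh_domain(dom, 0.1)
    return dom, mesh


@pytest.fixture(scope="session")
def small_ingrowth(small_porous):
    """A 15-iteration relaxed-gate ingrowth run on the small porous anchor."""
    _, mesh = small_porous
    sub = extract_anchor_submesh(mesh)
    params = RemodelingParams(max_iterations=15)
    hist = run_ingrowth(sub, 22.0, params)
    return sub, params, hist


@pytest.fixture()
def fan_mesh():
    """Six triangles around a central one: element 3 edge-shares 1, 2 and 5.

    The central triangle (id 3) has its three edges shared with triangles
    1, 2 and 5; triangles 0 and 4 hang off the outer edges of 1 and 2.
    """
    s3 = np.sqrt(3) / 2
    nodes = np.array([
        [0.0, 0.0],    # A
        [1.0, 0.0],    # B
        [0.5, s3],     # C
        [0.5, -s3],    # D
        [1.5, s3],     # E
        [-0.5, s3],    # F
        [-0.5, -s3],   # G
        [2.0, 0.0],    # H
    ])
    elems = np.array([
        [0, 3, 6],  # 0: attached to 1
        [0, 1, 3],  # 1: shares AB with 3
        [1, 2, 4],  # 2: shares BC with 3
        [0, 1, 2],  # 3: central
        [1, 4, 7],  # 4: attached to 2
        [2, 0, 5],  # 5: shares CA with 3
    ])
    mesh = FEMesh(nodes=nodes, elems=elems,
                  region=np.full(6, VOID, dtype=np.int8),
                  thickness=1.0, element_size=1.0)
    build_adjacency(mesh)
    return mesh
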