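"""Shared fixtures: canonical disk geometry, electrodes, patterns, and a
small reconstruction setup reused across the inverse-solver tests."""

import numpy as np
import pytest

from lungeit import (ConductivityField, FEMForwardProblem, adjacent_pattern,
                     build_disk_mesh, build_pixel_grid, place_electrodes)


def circle_boundary(n=256, radius=1.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return radius * np.column_stack([np.cos(th), np.sin(th)])


@pytest.fixture(scope="session")
def circle():
    return circle_boundary()


@pytest.fixture(scope="session")
def disk_mesh_2k():
    return build_disk_mesh(1.0, 2000)


@pytest.fixture(scope="session")
def disk_mesh_fine():
    return build_disk_mesh(1.0, 9000)


@pytest.fixture(scope="session")
def electrodes16(circle):
    return place_electrodes(circle, 16, 0.0, width=0.0)


@pytest.fixture(scope="session")
def electrodes16_snapped(disk_mesh_fine, electrodes16):
    """Electrode positions snapped to the fine disk mesh's boundary nodes
    (the FEM attaches point electrodes to nodes; analytic oracles must use
    the same points)."""
    from lungeit.mesh import ElectrodeSet

    loop = disk_mesh_fine.boundary_loop()
    bn = disk_mesh_fine.nodes[loop]
    pos = np.array([bn[np.argmin(np.linalg.norm(bn - p, axis=1))]
                    for p in electrodes16.positions])
    ang = np.arctan2(pos[:, 1], pos[:, 0])
    ang = np.unwrap(ang - ang[0]) + ang[0]
    return ElectrodeSet(ang, pos, width=0.0)


@pytest.fixture(scope="session")
def pattern16():
    return adjacent_pattern(16)


@pytest.fixture(scope="session")
def disk_problem_fine(disk_mesh_fine, electrodes16_snapped, pattern16):
    return FEMForwardProblem(disk_mesh_fine, electrodes16_snapped, pattern16,
                             model="shunt")


@pytest.fixture(scope="session")
def disk_grid_300(circle):
    return build_pixel_grid(circle, 300)


@pytest.fixture(scope="session")
def homogeneous_field_2k(disk_mesh_2k):
    return ConductivityField(np.ones(disk_mesh_2k.n_elements))
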