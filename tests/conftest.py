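"""Shared fixtures: small meshes and the recovery benchmark runs.

The two full inverse-crime recovery runs (default and alternative
initialization) are expensive, so they are session-scoped and shared
between the tests that score them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecginverse.benchmarks import make_benchmark_case, run_recovery
from ecginverse.mesh import (
    ENDO,
    EPI,
    GeometryConfig,
    SurfaceMesh,
    make_synthetic_geometry,
)


@pytest.fixture
def tetra_mesh() -> SurfaceMesh:
    """Surface of a tetrahedron: 4 vertices, 4 triangles, all EPI."""
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    tris = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(verts, tris, np.zeros(4, dtype=int))


def grid_mesh(nx: int = 5, ny: int = 5) -> SurfaceMesh:
    """Planar unit-grid mesh, each cell split into two triangles."""
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            tris.append((a, b, a + 1))
            tris.append((b, b + 1, a + 1))
    return SurfaceMesh(verts, np.array(tris), np.zeros(nx * ny, dtype=int))


@pytest.fixture
def planar_grid() -> SurfaceMesh:
    return grid_mesh(5, 5)


@pytest.fixture(scope="session")
def small_geometry():
    """30-vertex epi-only ventricle with 16 electrodes."""
    return make_synthetic_geometry(
        GeometryConfig(target_vertices=30, n_electrodes=16, seed=7)
    )


@pytest.fixture(scope="session")
def two_shell_geometry():
    """Epi+endo ventricle (wall thickness 8 mm) with 32 electrodes."""
    return make_synthetic_geometry(
        GeometryConfig(wall_thickness=8.0, target_vertices=60,
                       n_electrodes=32, seed=3)
    )


@pytest.fixture(scope="session")
def benchmark_case():
    return make_benchmark_case(seed=0)


@pytest.fixture(scope="session")
def benchmark_recovery(benchmark_case):
    """Default-initialization recovery on the noiseless benchmark case."""
    return run_recovery(benchmark_case, tau0=60.0, max_iterations=300)


@pytest.fixture(scope="session")
def benchmark_recovery_alt_init(benchmark_case):
    """Same case solved from the alternative activation initialization."""
    return run_recovery(benchmark_case, tau0=75.0, max_iterations=300)
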