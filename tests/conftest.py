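"""Shared fixtures: synthetic roots and reconstructed models.

Expensive artifacts (meshes, full reconstructions) are session-scoped
so the suite builds each one once.
"""

import numpy as np
import pytest

import rootqsm as rq


@pytest.fixture(scope="session")
def root_spec():
    return rq.default_spec(seed=0)


@pytest.fixture(scope="session")
def root_mesh(root_spec):
    mesh, truth = rq.generate_mesh(root_spec)
    return mesh, truth


@pytest.fixture(scope="session")
def root_cloud(root_mesh):
    mesh, _ = root_mesh
    return rq.mesh_to_pointcloud(mesh, 1.0)


@pytest.fixture(scope="session")
def root_qsm(root_cloud):
    return rq.reconstruct(root_cloud, seed=10)


@pytest.fixture(scope="session")
def cube_stl(tmp_path_factory):
    """Unit cube written as both ASCII and binary STL."""
    import trimesh

    d = tmp_path_factory.mktemp("stl")
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    ascii_path = d / "cube_ascii.stl"
    bin_path = d / "cube_bin.stl"
    box.export(str(ascii_path), file_type="stl_ascii")
    box.export(str(bin_path), file_type="stl")
    return ascii_path, bin_path


def cylinder_surface_points(radius=1.0, length=5.0, n_theta=20, n_z=10,
                            noise=0.0, seed=0):
    """Grid-sampled points on a z-aligned cylinder surface, ends included."""
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    z = np.linspace(0, length, n_z)
    T, Z = np.meshgrid(theta, z)
    pts = np.c_[radius * np.cos(T).ravel(), radius * np.sin(T).ravel(), Z.ravel()]
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts
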