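import numpy as np
import pytest

from omtcube.density import DensityField, normalize_intensity, density_phase1
from omtcube.mesh import build_tet_mesh, normalize_complex
from omtcube.phantom import PhantomSpec, generate_phantom
from omtcube.pipeline import PipelineConfig, run_phase2
from omtcube.surface import cube_boundary_aomt
from omtcube.volume import volume_omt

# grid / cube sizes used by the shared heavy fixtures; chosen so the whole
# suite runs in minutes on one CPU while the meshes stay large enough for
# the measure-preservation statistics to be meaningful
PHANTOM_SHAPE = (64, 64, 44)
CUBE_SIZE = 64
REF_RESOLUTION = 17


@pytest.fixture(scope="session")
def phantom_subject():
    return generate_phantom(PhantomSpec(seed=1, grid_shape=PHANTOM_SHAPE))


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig(gamma=1.0, cube_size=CUBE_SIZE, ref_resolution=REF_RESOLUTION)


@pytest.fixture(scope="session")
def phase2_result(phantom_subject, pipeline_config):
    """Full Phase II on the phantom (GT WT region fallback, training mode)."""
    return run_phase2(phantom_subject, None, pipeline_config, mode="train")


@pytest.fixture(scope="session")
def uniform_map_products(phantom_subject):
    """V-OMT of the phantom with uniform density (no refinement)."""
    mesh = build_tet_mesh(phantom_subject.brain_mask)
    rho = DensityField.uniform(mesh)
    mesh_n, _ = normalize_complex(mesh, rho.vertex_values)
    gstar = cube_boundary_aomt(mesh_n, rho, ref_resolution=REF_RESOLUTION)
    fmap, report = volume_omt(mesh_n, rho, gstar, p=11)
    return {"mesh": mesh_n, "rho": rho, "gstar": gstar, "fmap": fmap, "report": report}


@pytest.fixture(scope="session")
def phantom_mesh_density(phantom_subject):
    """Phase I density (gamma = 1) on the unrefined phantom mesh."""
    mesh = build_tet_mesh(phantom_subject.brain_mask)
    cehe = normalize_intensity(
        phantom_subject.modalities["flair"], phantom_subject.brain_mask
    )
    rho = density_phase1(cehe, mesh, 1.0)
    return mesh, rho, cehe


@pytest.fixture(scope="session")
def cube_selfmap():
    """V-OMT of a uniform-density voxel cube onto the target cube (p = 11)."""
    mesh = build_tet_mesh(np.ones((12, 12, 12), dtype=bool))
    rho = DensityField.uniform(mesh)
    mesh_n, _ = normalize_complex(mesh, rho.vertex_values)
    gstar = cube_boundary_aomt(mesh_n, rho)
    fmap, report = volume_omt(mesh_n, rho, gstar, p=11)
    return {"mesh": mesh_n, "rho": rho, "fmap": fmap, "report": report}


def random_blob_mask(rng, shape, n_seeds=3):
    """Random union of balls that all contain the domain center, hence
    star-shaped and genus zero (up to voxelization repair)."""
    m = np.zeros(shape, dtype=bool)
    center = np.asarray(shape) / 2
    g = np.indices(shape) + 0.5
    for _ in range(n_seeds):
        r = rng.uniform(2.0, min(shape) / 2.5)
        c = center + rng.uniform(-0.6, 0.6, 3) * r
        d2 = sum((g[i] - c[i]) ** 2 for i in range(3))
        m |= d2 < r**2
    return m
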