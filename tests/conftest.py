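import numpy as np
import pytest
import trimesh

from koashape.geometry import SurfaceMesh
from koashape.synthetic_knee import (CohortConfig, SeverityEffects,
                                     build_templates, sample_cohort, voxelize)


def as_surface(tm: trimesh.Trimesh) -> SurfaceMesh:
    return SurfaceMesh(np.asarray(tm.vertices, float),
                       np.asarray(tm.faces, np.int64))


@pytest.fixture(scope="session")
def templates():
    return build_templates()


@pytest.fixture(scope="session")
def sphere_r10():
    """Fine icosphere of radius 10 mm (analytic volume/area oracles)."""
    return as_surface(trimesh.creation.icosphere(subdivisions=4, radius=10.0))


@pytest.fixture(scope="session")
def cube_10mm():
    return as_surface(trimesh.creation.box(extents=(10.0, 10.0, 10.0)))


@pytest.fixture(scope="session")
def sphere_volume(sphere_r10):
    """Voxelized r=10 mm sphere at 0.5 mm isotropic spacing."""
    return voxelize({"FC": sphere_r10}, (0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def small_cohort():
    """20-knee cohort with default severity effects, 1 mm spacing."""
    cfg = CohortConfig(n_knees=20, seed=42, voxel_spacing_mm=(1.0, 1.0, 1.0))
    records, meshes = sample_cohort(cfg)
    return cfg, records, meshes


@pytest.fixture(scope="session")
def rigid_only_cfg():
    """Config with no shape modes and no severity effects (pure templates)."""
    return CohortConfig(n_knees=4, seed=1, n_shape_modes=0, mode_sd_mm=(),
                        severity_effects=SeverityEffects.none(),
                        grade_noise_sd=0.0)
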