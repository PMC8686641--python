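import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import palate_relief as pr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


UNIFORM_T = 2.0


@pytest.fixture
def flat_config():
    """Flat bilayer slab: dome_height 0, uniform 2 mm mucosa."""
    return pr.PalateConfig(
        arch_length=20.0,
        arch_half_width=10.0,
        dome_height=0.0,
        plate_thickness=1.5,
        thickness_bounds=tuple((UNIFORM_T, UNIFORM_T) for _ in range(pr.N_SEGMENTS)),
        mesh_edge=2.0,
        seed=0,
    )


@pytest.fixture
def flat_geometry(flat_config):
    tm = pr.sample_thickness_map(flat_config)
    return pr.build_geometry(flat_config, tm)


@pytest.fixture
def flat_mesh(flat_geometry):
    return pr.mesh_layered(flat_geometry, 2.0)


@pytest.fixture
def small_bilayer():
    """Small domed bilayer with varying thickness, cheap to solve."""
    cfg = pr.PalateConfig(
        arch_length=16.0, arch_half_width=8.0, dome_height=4.0, mesh_edge=2.0, seed=3
    )
    tm = pr.sample_thickness_map(cfg)
    return pr.mesh_layered(pr.build_geometry(cfg, tm), 2.0)


@pytest.fixture(scope="session")
def default_report():
    """The shipped default seven-scenario study, run once per session."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # expected gap-closure warnings
        return pr.run_study(pr.StudyConfig())


def random_stress_field(mesh: pr.TetMesh, seed: int, scale: float = 0.2) -> pr.StressField:
    """Synthetic uniaxial-like stress field with the given von Mises scale."""
    rng = np.random.default_rng(seed)
    vm = scale * rng.random(mesh.n_tets)
    tensor = np.zeros((mesh.n_tets, 6))
    tensor[:, 2] = -vm  # uniaxial compression has von Mises = |sigma_zz|
    return pr.StressField(tensor=tensor, vm=pr.von_mises(tensor))
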