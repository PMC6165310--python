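import numpy as np
import pytest

from symaxis import (
    EllipsoidSpec,
    PointCloud,
    RunConfig,
    run_simulation_experiment,
    sample_partial_view,
    summarize_errors,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def sphere_cloud(rng):
    """~400 points uniform on a sphere of radius 2 about (1, -2, 30),
    with exact outward normals, camera at the origin."""
    u = rng.standard_normal((400, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    center = np.array([1.0, -2.0, 30.0])
    return PointCloud(center + 2.0 * u, u.copy()), center, 2.0


@pytest.fixture
def planar_cloud(rng):
    """100 points on z = 0 with the camera above at (0, 0, 10)."""
    xy = rng.uniform(-1, 1, size=(100, 2))
    pts = np.column_stack([xy, np.zeros(100)])
    return PointCloud(pts, viewpoint=(0.0, 0.0, 10.0))


@pytest.fixture
def spheroid_view():
    """One benchmark-style partial spheroid cloud (analytic normals)."""
    spec = EllipsoidSpec(center=(3.0, 5.0, 40.0), n_points=1500, seed=5)
    return sample_partial_view(spec), spec


@pytest.fixture(scope="session")
def sim_study():
    """The depth-sweep error study shared by the acceptance tests: 50
    repetitions over all 45 depths at the default operating point (u = 6,
    tau = 3*pi, 2000 pre-cull samples). Takes a few minutes; per-depth
    means over fewer repetitions are dominated by the heavy tail of
    single-run errors."""
    cfg = RunConfig(seed=0)
    records = run_simulation_experiment(50, cfg)
    return records, summarize_errors(records)
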