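import numpy as np
import pytest

from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import v2qstripes as v2


@pytest.fixture(scope="session")
def small_patch():
    """16 x 8 mm flat patch at 0.8 mm spacing (231 vertices, two stripe cycles)."""
    return v2.generate_patch(16.0, 8.0, 0.8)


@pytest.fixture(scope="session")
def small_dist(small_patch):
    return small_patch.pairwise_dist()


@pytest.fixture(scope="session")
def small_surrogate_gen(small_dist):
    return v2.SurrogateGenerator(small_dist)


@pytest.fixture(scope="session")
def default_patch():
    """The default cohort geometry: 32 x 16 mm at 0.4 mm (3321 vertices)."""
    return v2.generate_patch(32.0, 16.0, 0.4)


def make_uv_sphere(radius=10.0, n_lat=40, n_lon=80):
    """Closed UV sphere with outward-wound faces; returns (points, faces, interior).

    ``interior`` indexes vertices away from the poles where the discrete
    curvature estimate is well conditioned.
    """
    th = np.linspace(0, np.pi, n_lat)[1:-1]
    ph = np.linspace(0, 2 * np.pi, n_lon, endpoint=False)
    t, p = np.meshgrid(th, ph, indexing="ij")
    pts = np.stack(
        [
            radius * np.sin(t) * np.cos(p),
            radius * np.sin(t) * np.sin(p),
            radius * np.cos(t),
        ],
        axis=-1,
    ).reshape(-1, 3)
    pts = np.vstack([pts, [0, 0, radius], [0, 0, -radius]])
    npole, spole = len(pts) - 2, len(pts) - 1
    idx = np.arange((n_lat - 2) * n_lon).reshape(n_lat - 2, n_lon)
    faces = []
    for i in range(n_lat - 3):
        for j in range(n_lon):
            a, b = idx[i, j], idx[i, (j + 1) % n_lon]
            c, d = idx[i + 1, j], idx[i + 1, (j + 1) % n_lon]
            faces += [[a, c, b], [b, c, d]]
    for j in range(n_lon):
        faces.append([npole, idx[0, j], idx[0, (j + 1) % n_lon]])
        faces.append([spole, idx[-1, (j + 1) % n_lon], idx[-1, j]])
    interior = idx[8 : n_lat - 10].ravel()
    return pts, np.asarray(faces), interior
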