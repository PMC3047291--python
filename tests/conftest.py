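import numpy as np
import pytest

import guidefit as gf


@pytest.fixture(scope="session")
def small_spec():
    """A reduced arch phantom for unit tests: small, fast, still curved."""
    return gf.PhantomSpec(
        arch_radius=12.0,
        tube_radius=4.0,
        arc_span=120.0,
        bump_count=3,
        bump_amplitude=0.4,
        optical_sample_count=3000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_arch(small_spec):
    return gf.make_arch_mesh(small_spec)


@pytest.fixture(scope="session")
def default_arch():
    """The study-conditions arch at default size (shared across tests)."""
    return gf.make_arch_mesh(gf.PhantomSpec())


@pytest.fixture(scope="session")
def sphere4():
    return gf.make_sphere_mesh(1.0, 4)


@pytest.fixture(scope="session")
def blurred_sphere_volume():
    """Voxelized sphere of analytic radius 8 mm (fg 1000 / bg 0), blurred with
    a 0.6 mm PSF at 0.3 mm spacing — the standard threshold-recovery fixture."""
    mesh = gf.make_sphere_mesh(8.0, 4)
    vol = gf.voxelize_mesh(mesh, 0.3, padding=3.0, fg=1000.0, bg=0.0)
    return gf.simulate_ct(vol, psf_sigma=0.6, noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng, max_angle_deg=180.0, max_translation=10.0):
    axis = rng.normal(size=3)
    angle = rng.uniform(0.0, max_angle_deg)
    t = rng.normal(size=3)
    norm = np.linalg.norm(t)
    if norm > 0:
        t = t * (rng.uniform(0, max_translation) / norm)
    return gf.RigidTransform.from_axis_angle(axis, angle, t)
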