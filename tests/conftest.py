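import pytest
from hypothesis import HealthCheck, settings

from muoct.phantom import OpticsConfig, PhantomConfig, simulate_sequence

settings.register_profile(
    "muoct",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("muoct")


@pytest.fixture(scope="session")
def small_optics() -> OpticsConfig:
    """A 100 x 30 um field at the instrument's native sampling."""
    return OpticsConfig(frame_rate=40.0, n_lines=100, field_x=100.0, field_z=30.0, dz=0.5)


@pytest.fixture(scope="session")
def std_phantom(small_optics):
    """A realistic 4 s phantom: beating cilia, advected inclusions, speckle."""
    cfg = PhantomConfig(
        optics=small_optics,
        duration=4.0,
        beat_frequency=10.0,
        mucus_velocity=24.22,
        seed=11,
    )
    seq, truth = simulate_sequence(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def quiet_phantom(small_optics):
    """A short noise-free static phantom (layers only: no cilia, no flow)."""
    cfg = PhantomConfig(
        optics=small_optics,
        duration=0.5,
        asl_depth=9.0,
        pcl_depth=7.0,
        cilia_spacing=None,
        n_inclusions=0,
        mucus_velocity=0.0,
        speckle_contrast=0.0,
        noise_floor=0.0,
        seed=3,
    )
    seq, truth = simulate_sequence(cfg)
    return cfg, seq, truth
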