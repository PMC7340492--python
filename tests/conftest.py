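import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phenotrial import GroundTruth, SceneSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """Reduced-resolution scene so rendering stays fast in the suite."""
    return SceneSpec(rgb_shape=(60, 88), ms_shape=(40, 58))


@pytest.fixture
def noise_free_scene():
    return SceneSpec(
        rgb_shape=(60, 88), ms_shape=(40, 58),
        pixel_noise_sd=0.0, rgb_noise_sd=0.0, thermal_noise_sd=0.0,
    )


def make_gt(plot_id="P001", tillage="CP", canopy=0.5, senescent=0.0, residue=0.0,
            brightness=1.0, yield_mean=2.5, temperature=25.0):
    return GroundTruth(
        plot_id=plot_id, tillage=tillage, canopy_fraction=canopy,
        senescent_fraction=senescent, residue_fraction=residue,
        soil_brightness=brightness, true_yield_mean=yield_mean,
        canopy_temperature=temperature,
    )


@pytest.fixture
def gt_factory():
    return make_gt
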