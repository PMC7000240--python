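import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fastflim.decay import DecayModel
from fastflim.pileup import DetectionConfig
from fastflim.stream import ImagingLayout
from fastflim.synth import make_scene


@pytest.fixture
def paper_model() -> DecayModel:
    """Instrument defaults: 3 ns dye, 80 MHz laser, 128 bins, 1±0.1 ns IRF."""
    return DecayModel(tau=3.0, T=12.5, k=128, p_pulse=0.01, irf_center=1.0, irf_sigma=0.1)


@pytest.fixture
def open_config() -> DetectionConfig:
    """A detection chain that never drops photons."""
    return DetectionConfig(td=0.0, mode="multi_hit", max_hits=10**9, window_pulses=1)


@pytest.fixture
def small_layout() -> ImagingLayout:
    return ImagingLayout(n_pixels=8, duty_cycle=0.65, T=12.5, k_bins=64)


@pytest.fixture
def two_region_scene():
    """Left half tau = 2 ns, right half tau = 3 ns, uniform brightness."""
    return make_scene(
        {
            "shape": [8, 8],
            "channels": 1,
            "background": {"intensity": 30.0, "tau": 2.0},
            "regions": [
                {"kind": "rect", "y0": 0, "y1": 8, "x0": 4, "x1": 8, "intensity": 30.0, "tau": 3.0}
            ],
        }
    )
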