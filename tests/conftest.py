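import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xdip import BeamParameters, single_panel_detector
from xdip.geometry import dual_demo, octal_demo

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beam():
    return BeamParameters(5.52)


@pytest.fixture(scope="session")
def octal256():
    """Gapless 256 x 256 detector at the wide-angle geometry (1.6 m)."""
    return single_panel_detector("octal", (256, 256), camera_length=1.6)


@pytest.fixture(scope="session")
def dual512():
    """Gapless 512 x 512 detector at the small-angle geometry (3.2 m)."""
    return single_panel_detector("dual", (512, 512), camera_length=3.2)


@pytest.fixture(scope="session")
def demo_detectors():
    """Panelled desk-scale tandem pair (gaps, aperture, beamstop)."""
    return octal_demo(), dual_demo()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def best_overlap(mask: np.ndarray, template: np.ndarray) -> float:
    """Overlap |A ∩ B| / max(|A|, |B|) maximized over translation and
    point reflection of the template (FFT cross-correlation)."""
    from scipy.signal import fftconvolve

    best = 0.0
    a = mask.astype(float)
    for cand in (template, template[::-1, ::-1]):
        xc = fftconvolve(a, cand[::-1, ::-1].astype(float), mode="full")
        best = max(best, float(xc.max()) / max(mask.sum(), cand.sum()))
    return best
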