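import numpy as np
import pytest

from libsquant import PhantomSpec, generate_cube, p_line, ti_line


@pytest.fixture(scope="session")
def small_phantom():
    """A 64×64 phantom cube at 1 μg g⁻¹ with its ground truth."""
    spec = PhantomSpec(concentration=1.0, seed=3)
    cube, truth = generate_cube(spec)
    return spec, cube, truth


@pytest.fixture
def flat_axis():
    """Wavelength axis around the Ti line at the instrumental sampling."""
    return 320.0 + 0.15 * np.arange(50)  # 320.0–327.35 nm


def gaussian_peak(wl, center, fwhm, amplitude):
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((wl - center) / s) ** 2)


@pytest.fixture
def ti():
    return ti_line()


@pytest.fixture
def phos():
    return p_line()
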