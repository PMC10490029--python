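import numpy as np
import pytest
from PIL import Image

from nitracolor import LinearCalibration, STANDARD_CONCENTRATIONS
from nitracolor.synthetic import ImageFixtureSpec, render_cuvette_image


@pytest.fixture(scope="session")
def printed_model() -> LinearCalibration:
    """The published device law: NO3⁻ = 24.82 − 0.26 · V (percent scale)."""
    return LinearCalibration.from_coefficients(24.82, -0.26, valid_range=(0.0, 10.0))


@pytest.fixture
def save_image(tmp_path):
    """Write a pixel array (or PixelGrid) to a PNG and return the path."""

    def _save(pixels, name="img.png"):
        arr = getattr(pixels, "pixels", pixels)
        path = tmp_path / name
        Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)
        return path

    return _save


@pytest.fixture
def standard_images(tmp_path, printed_model):
    """Noise-free synthetic cuvette PNGs for the 12-standard dilution series."""
    paths = []
    for c in STANDARD_CONCENTRATIONS:
        img = render_cuvette_image(
            ImageFixtureSpec(c, printed_model, noise_sd=0.0, size=96, seed=1)
        )
        p = tmp_path / f"std_{c:g}.png"
        Image.fromarray(img.pixels).save(p)
        paths.append((c, p))
    return paths
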