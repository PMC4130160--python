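import numpy as np
import pytest

from cryopolish import ImageGrid2D, PolishConfig, make_reference


@pytest.fixture(scope="session")
def reference64():
    """A band-limited random reference image, box 64 at 2.5 A/px."""
    return make_reference(64, 2.5, seed=42)


@pytest.fixture()
def config():
    return PolishConfig(pixel_size=2.5, running_avg_width=1, max_shift=8.0)


@pytest.fixture()
def gaussian_blob():
    """Centred analytic Gaussian blob; its translate is known in closed form."""

    def build(cx=32.0, cy=32.0, sigma=3.0, side=64):
        y, x = np.mgrid[0:side, 0:side]
        return ImageGrid2D(
            np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2)), 2.5
        )

    return build
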