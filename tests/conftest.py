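import numpy as np
import pytest
from scipy import ndimage

from wsicoloc.registration import RegistrationConfig
from wsicoloc.synthetic import generate_tissue_slide


def smooth_random_image(shape=(128, 128), seed=7, sigma=2.5):
    """Smooth random test image, full 0-255 range."""
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.uniform(0, 255, shape), sigma)
    return (img - img.min()) / (img.max() - img.min()) * 255.0


@pytest.fixture(scope="session")
def smooth_image():
    return smooth_random_image()


@pytest.fixture(scope="session")
def tissue_slide():
    """Small H&E-like slide shared across tests (read-only)."""
    return generate_tissue_slide(512, 512, 40, seed=3)


@pytest.fixture(scope="session")
def light_config():
    """Reduced-budget registration settings for fast unit tests."""
    return RegistrationConfig(
        n_resolutions=2, iterations=150, n_samples=1024,
        polish_iterations=60, polish_samples=2048, seed=0,
    )


def dense_mi_oracle(fixed, moving, n_bins=32):
    """Independent dense joint-histogram Mattes MI (nats).

    Explicit per-pixel accumulation: zero-order kernel on fixed
    intensities, cubic B-spline kernel on moving intensities, two guard
    bins per side; every pixel is a sample.
    """
    fixed = np.asarray(fixed, float).ravel()
    moving = np.asarray(moving, float).ravel()
    pad = 2
    fl, fh = fixed.min(), fixed.max()
    ml, mh = moving.min(), moving.max()
    uf = (fixed - fl) / (fh - fl) * (n_bins - 1 - 2 * pad) + pad
    um = (moving - ml) / (mh - ml) * (n_bins - 1 - 2 * pad) + pad

    def b3(x):
        ax = abs(x)
        if ax < 1:
            return (4 - 6 * ax * ax + 3 * ax**3) / 6.0
        if ax < 2:
            return (2 - ax) ** 3 / 6.0
        return 0.0

    H = np.zeros((n_bins, n_bins))
    for f, m in zip(uf, um):
        fb = int(round(f))
        mf = int(np.floor(m))
        for off in (-1, 0, 1, 2):
            H[fb, mf + off] += b3(m - (mf + off))
    H /= H.sum()
    pf = H.sum(axis=1)
    pm = H.sum(axis=0)
    mi = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            if H[i, j] > 0:
                mi += H[i, j] * np.log(H[i, j] / (pf[i] * pm[j]))
    return mi
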