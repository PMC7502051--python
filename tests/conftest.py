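"""Shared fixtures: phantoms and template banks, generated once per session."""

import numpy as np
import pytest

from aortaqc import RunConfig, generate_phantom
from aortaqc.phantom import PhantomSpec, build_template_bank


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def clean_spec():
    """Zero-noise phantom spec with every structure at its default."""
    return PhantomSpec(noise_sigma_hu=0.0)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    """(volume, ground truth) of the default zero-noise phantom."""
    return generate_phantom(clean_spec)


@pytest.fixture(scope="session")
def clean_bank(clean_phantom, clean_spec):
    volume, _ = clean_phantom
    return build_template_bank(volume, clean_spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(noise_sigma_hu=10.0, seed=11)
    return generate_phantom(spec), spec


def pearson_window_scan(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Independent sliding-window NCC oracle: direct Pearson correlation of
    the template against every full-overlap window (no FFT, no integral
    images)."""
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(image, template.shape)
    zt = template - template.mean()
    nt = np.sqrt((zt**2).sum())
    n = template.size
    s1 = np.einsum("ijkl->ij", windows)
    s2 = np.einsum("ijkl,ijkl->ij", windows, windows)
    num = np.einsum("ijkl,kl->ij", windows, zt)  # zt is zero-mean
    var = np.maximum(s2 - s1 * s1 / n, 0.0)
    denom = nt * np.sqrt(var)
    out = np.zeros_like(num)
    good = denom > 1e-9 * max(1.0, float(np.abs(image).max()) ** 2 * n)
    out[good] = num[good] / denom[good]
    return np.clip(out, -1.0, 1.0)
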