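import numpy as np
import pytest

from sinumorph.volume_io import BinaryVolume, GrayVolume


def digital_ball(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    g = np.mgrid[:n, :n, :n]
    c = n // 2
    return ((g - c) ** 2).sum(axis=0) <= radius**2


def solid_torus(R: int = 18, r: int = 7, n: int = 64) -> np.ndarray:
    g = np.mgrid[:n, :n, :n].astype(float)
    c = n / 2 - 0.5
    rho = np.sqrt((g[0] - c) ** 2 + (g[1] - c) ** 2)
    return (rho - R) ** 2 + (g[2] - c) ** 2 <= r**2


def hollow_shell(r_out: int = 25, r_in: int = 15, n: int = 64) -> np.ndarray:
    g = np.mgrid[:n, :n, :n].astype(float)
    c = n / 2 - 0.5
    d2 = ((g - c) ** 2).sum(axis=0)
    return (d2 <= r_out**2) & (d2 >= r_in**2)


def tube_z(n: int, cx: float, cy: float, radius: float) -> np.ndarray:
    """Solid tube along z crossing the whole (n, n, n) volume."""
    g = np.mgrid[:n, :n]
    disc = (g[0] - cx) ** 2 + (g[1] - cy) ** 2 <= radius**2
    return np.repeat(disc[:, :, None], n, axis=2)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def small_gray(rng):
    data = rng.integers(0, 256, size=(24, 24, 24)).astype(np.uint8)
    return GrayVolume(data, 0.5)


def as_bin(mask: np.ndarray, spacing: float = 1.0) -> BinaryVolume:
    return BinaryVolume(mask, spacing)
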