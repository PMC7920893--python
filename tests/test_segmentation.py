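import numpy as np
import pytest

from conftest import as_bin, hollow_shell
from sinumorph.segmentation import (
    SegmentationError,
    SegmentationParams,
    binarize,
    fill_enclosed_holes,
    median_denoise,
    otsu_threshold,
    remove_small_noise,
    segment_vessels,
)
from sinumorph.volume_io import GrayVolume


def brute_median(data, size):
    h = size // 2
    padded = np.pad(data, h, mode="reflect")
    out = np.empty_like(data)
    for idx in np.ndindex(data.shape):
        win = padded[tuple(slice(i, i + size) for i in idx)]
        out[idx] = np.median(win)
    return out


class TestMedianDenoise:
    def test_constant_volume_unchanged(self):
        vol = GrayVolume(np.full((10, 10, 10), 37, np.uint8), 0.5)
        out = median_denoise(vol, 7)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_matches_brute_force_with_impulse_and_plateau(self, rng):
        data = np.full((11, 11, 11), 10, np.uint8)
        data[5, 5, 5] = 250          # isolated impulse
        data[1:9, 1:9, 1:9] = 10
        data[2:7, 2:7, 2:7] = 80     # plateau
        out = median_denoise(GrayVolume(data, 1.0), 3)
        np.testing.assert_array_equal(out.data, brute_median(data, 3))
        assert out.data[5, 5, 5] != 250  # impulse removed

    def test_even_size_rejected(self, small_gray):
        with pytest.raises(ValueError):
            median_denoise(small_gray, 4)


class TestOtsu:
    def test_bimodal_separates_classes(self):
        data = np.zeros((10, 10, 10), np.uint8)
        data[5:] = 200
        data[:5] = 10
        t = otsu_threshold(GrayVolume(data, 1.0))
        assert 10 < t <= 200

    def test_constant_volume_errors(self):
        with pytest.raises(SegmentationError):
            otsu_threshold(GrayVolume(np.full((5, 5, 5), 7, np.uint8), 1.0))

    def test_matches_exhaustive_search_16_bins(self, rng):
        """The chosen split maximizes between-class variance on every
        random <=16-bin histogram (exhaustive oracle, lowest bin on ties)."""
        for _ in range(60):
            nbins = int(rng.integers(2, 17))
            hist = rng.integers(0, 40, size=nbins)
            hist[0] = max(hist[0], 1)      # occupy the extreme bins so the
            hist[-1] = max(hist[-1], 1)    # observed range spans all bins
            values = np.repeat(np.arange(nbins), hist).astype(np.float64)
            vol = GrayVolume(values.reshape(-1, 1, 1), 1.0)
            t = otsu_threshold(vol, nbins=nbins)

            def var_b(k):
                w0, w1 = hist[: k + 1].sum(), hist[k + 1:].sum()
                if w0 == 0 or w1 == 0:
                    return -np.inf
                c = np.arange(nbins)
                mu0 = (hist[: k + 1] * c[: k + 1]).sum() / w0
                mu1 = (hist[k + 1:] * c[k + 1:]).sum() / w1
                return w0 * w1 * (mu0 - mu1) ** 2

            scores = [var_b(k) for k in range(nbins - 1)]
            best = int(np.argmax(scores))  # argmax takes the lowest on ties
            edges = np.linspace(0, nbins - 1, nbins + 1)
            assert t == pytest.approx(edges[best + 1])

    def test_agrees_with_skimage_on_smooth_data(self, rng):
        from skimage.filters import threshold_otsu

        data = np.concatenate([
            rng.normal(50, 10, 4000), rng.normal(180, 15, 2000)
        ]).clip(0, 255)
        vol = GrayVolume(data.reshape(20, 20, 15), 1.0)
        t = otsu_threshold(vol)
        t_sk = threshold_otsu(vol.data, nbins=256)
        assert abs(t - t_sk) <= (data.max() - data.min()) / 256 + 1e-9


class TestBinarize:
    def test_all_true_with_min_threshold(self, small_gray):
        out = binarize(small_gray, float(small_gray.data.min()))
        assert out.mask.all()

    def test_band_selects_middle_level(self):
        data = np.zeros((6, 6, 6), np.uint8)
        data[2] = 100
        data[4] = 200
        out = binarize(GrayVolume(data, 1.0), 50, 150)
        np.testing.assert_array_equal(out.mask, data == 100)

    def test_inverted_bounds_rejected(self, small_gray):
        with pytest.raises(ValueError):
            binarize(small_gray, 100, 50)


class TestFillEnclosedHoles:
    def test_hollow_shell_becomes_solid(self):
        shell = hollow_shell(12, 7, n=32)
        out = fill_enclosed_holes(as_bin(shell))
        g = np.mgrid[:32, :32, :32].astype(float)
        c = 32 / 2 - 0.5
        ball = ((g - c) ** 2).sum(axis=0) <= 12**2
        np.testing.assert_array_equal(out.mask, ball)

    def test_through_tunnel_untouched(self):
        slab = np.zeros((20, 20, 20), bool)
        slab[:, :, 5:15] = True
        slab[9:11, 9:11, :] = False  # tunnel with mouths at the boundary
        out = fill_enclosed_holes(as_bin(slab))
        np.testing.assert_array_equal(out.mask, slab)

    def test_no_enclosed_background_after_filling(self, rng):
        from scipy import ndimage as ndi

        mask = rng.random((24, 24, 24)) < 0.45
        out = fill_enclosed_holes(as_bin(mask))
        labels, n = ndi.label(~out.mask, structure=ndi.generate_binary_structure(3, 1))
        for lab in range(1, n + 1):
            comp = labels == lab
            touches = (
                comp[0].any() or comp[-1].any() or comp[:, 0].any()
                or comp[:, -1].any() or comp[:, :, 0].any() or comp[:, :, -1].any()
            )
            assert touches, "enclosed background component survived filling"

    def test_extensive_and_idempotent(self, rng):
        mask = as_bin(rng.random((16, 16, 16)) < 0.4)
        once = fill_enclosed_holes(mask)
        assert (once.mask >= mask.mask).all()
        twice = fill_enclosed_holes(once)
        np.testing.assert_array_equal(twice.mask, once.mask)


class TestRemoveSmallNoise:
    def test_small_cluster_removed_large_cube_kept(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:4, 2:4, 2:4] = True       # 2x2x2 cluster
        mask[6:16, 6:16, 6:16] = True    # 10^3 cube
        out = remove_small_noise(as_bin(mask), 3)
        assert not out.mask[2:4, 2:4, 2:4].any()
        assert out.mask[6:16, 6:16, 6:16].all()

    def test_anti_extensive_and_idempotent(self, rng):
        mask = as_bin(rng.random((16, 16, 16)) < 0.5)
        once = remove_small_noise(mask, 3)
        assert (once.mask <= mask.mask).all()
        twice = remove_small_noise(once, 3)
        np.testing.assert_array_equal(twice.mask, once.mask)


def test_pipeline_determinism(rng):
    data = rng.integers(0, 256, size=(24, 24, 24)).astype(np.uint8)
    v1 = GrayVolume(data.copy(), 0.5)
    v2 = GrayVolume(data.copy(), 0.5)
    m1, i1 = segment_vessels(v1)
    m2, i2 = segment_vessels(v2)
    np.testing.assert_array_equal(m1.mask, m2.mask)
    assert i1 == i2


def test_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(median_size=4)
    with pytest.raises(ValueError):
        SegmentationParams(noise_opening_size=0)
    with pytest.raises(ValueError):
        SegmentationParams(threshold_override=(10, 5))
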