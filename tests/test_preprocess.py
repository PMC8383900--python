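"""Preprocessing chain: channel split, ROI, denoise, normalize, CLAHE."""

import numpy as np
import pytest
from skimage import color

import fundtess as ft
from fundtess.errors import InvalidConfig, NoROIFound
from fundtess.preprocess import _lowpass_transfer


def _highband_energy(img: ft.FundusImage, cutoff: float) -> float:
    total = 0.0
    h, w = img.shape
    fy = np.abs(np.fft.fftfreq(h)) / 0.5
    fx = np.abs(np.fft.fftfreq(w)) / 0.5
    band = np.maximum(fy[:, None], fx[None, :]) > cutoff
    for c in range(3):
        spec = np.fft.fft2(img.pixels[:, :, c].astype(float))
        total += float((np.abs(spec[band]) ** 2).sum())
    return total


def test_split_restack_identity(synth_case):
    scene, _ = synth_case()
    r, g, b = ft.split_channels(scene.image)
    again = ft.restack_channels(r, g, b)
    assert np.array_equal(again.pixels, scene.image.pixels)


def test_split_pure_red():
    px = np.zeros((64, 64, 3), dtype=np.uint8)
    px[..., 0] = 255
    r, g, b = ft.split_channels(ft.FundusImage(px))
    assert (r == 255).all() and (g == 0).all() and (b == 0).all()


def test_fundus_disc_is_red_dominant(synth_case):
    scene, _ = synth_case()
    r, _, b = ft.split_channels(scene.image)
    disc = scene.roi_truth.pixels
    assert r[disc].mean() > b[disc].mean()


def test_roi_area_matches_disc_geometry(synth_case):
    scene, pre = synth_case(rho=0.2, seed=5)
    expected = np.pi * scene.radius_px**2
    assert abs(pre.roi.area_px - expected) / expected < 0.02


def test_roi_all_black_raises():
    img = ft.FundusImage(np.zeros((96, 96, 3), dtype=np.uint8))
    with pytest.raises(NoROIFound):
        ft.establish_roi(img)


def test_roi_corner_blob_rejected(synth_case):
    scene, _ = synth_case(rho=0.1, seed=9)
    px = scene.image.pixels.copy()
    px[:18, :18] = 255  # bright corner distractor
    roi = ft.establish_roi(ft.FundusImage(px))
    center = scene.roi_truth.pixels
    inter = (roi.pixels & center).sum()
    union = (roi.pixels | center).sum()
    assert inter / union > 0.9
    assert not roi.pixels[:10, :10].any()


def test_roi_determinism(synth_case):
    scene, _ = synth_case()
    a = ft.establish_roi(scene.image)
    b = ft.establish_roi(scene.image)
    assert np.array_equal(a.pixels, b.pixels)


def test_roi_recovery_across_radii_and_seeds():
    """Jaccard vs the true disc stays >= 0.95 over 20 seeded renderings."""
    rng = np.random.default_rng(42)
    for i in range(20):
        radius = float(rng.uniform(0.30, 0.45))
        p = ft.SynthImageParams(size=128, disc_radius_frac=radius,
                                rho_target=float(rng.uniform(0.0, 0.35)),
                                seed=int(rng.integers(0, 2**31 - 1)))
        scene = ft.generate_image(p)
        roi = ft.establish_roi(ft.denoise(scene.image))
        inter = (roi.pixels & scene.roi_truth.pixels).sum()
        union = (roi.pixels | scene.roi_truth.pixels).sum()
        assert inter / union >= 0.95, f"case {i}: jaccard {inter / union:.3f}"


def test_denoise_constant_image_unchanged():
    img = ft.FundusImage(np.full((64, 64, 3), 77, dtype=np.uint8))
    out = ft.denoise(img)
    assert np.array_equal(out.pixels, img.pixels)


def test_denoise_unit_cutoff_is_passthrough(synth_case):
    scene, _ = synth_case()
    out = ft.denoise(scene.image, ft.PreprocessConfig(lowpass_cutoff=1.0))
    assert np.abs(out.pixels.astype(int) - scene.image.pixels.astype(int)).max() <= 1


def test_denoise_cutoff_validation():
    with pytest.raises(InvalidConfig):
        ft.PreprocessConfig(lowpass_cutoff=0.0)
    with pytest.raises(InvalidConfig):
        ft.PreprocessConfig(lowpass_cutoff=1.5)


def test_denoise_contracts_high_band_energy():
    """High-band spectral energy strictly drops on noisy seeded images."""
    cfg = ft.PreprocessConfig(lowpass_cutoff=0.35)
    rng = np.random.default_rng(7)
    for _ in range(10):
        p = ft.SynthImageParams(size=96, rho_target=float(rng.uniform(0, 0.3)),
                                noise_sigma=10.0,
                                seed=int(rng.integers(0, 2**31 - 1)))
        scene = ft.generate_image(p)
        before = _highband_energy(scene.image, cfg.lowpass_cutoff)
        after = _highband_energy(ft.denoise(scene.image, cfg), cfg.lowpass_cutoff)
        assert after < before


def test_normalize_hits_target_lightness(synth_case):
    scene, _ = synth_case()
    cfg = ft.PreprocessConfig(target_L=60.0)
    out = ft.normalize(scene.image, cfg)
    mean_l = color.rgb2lab(out.pixels)[:, :, 0].mean()
    assert abs(mean_l - 60.0) <= 0.5


def test_normalize_idempotent(synth_case):
    scene, _ = synth_case()
    once = ft.normalize(scene.image)
    twice = ft.normalize(once)
    assert np.abs(twice.pixels.astype(int) - once.pixels.astype(int)).max() <= 1


def test_normalize_equalizes_brightness_variants():
    """Renderings at 0.7x and 1.3x gain agree in mean L after calibration."""
    levels = []
    for gain in (0.7, 1.3):
        p = ft.SynthImageParams(size=128, rho_target=0.2, brightness_gain=gain,
                                seed=3)
        scene = ft.generate_image(p)
        out = ft.normalize(scene.image)
        levels.append(color.rgb2lab(out.pixels)[:, :, 0].mean())
    assert abs(levels[0] - levels[1]) < 1.0


def test_enhance_constant_roi_unchanged():
    px = np.full((64, 64, 3), 120, dtype=np.uint8)
    roi = ft.BinaryMask(np.ones((64, 64), dtype=bool), kind="roi")
    out = ft.enhance(ft.FundusImage(px), roi)
    assert np.array_equal(out.pixels, px)


def test_enhance_preserves_pixels_outside_roi(synth_case):
    scene, pre = synth_case()
    out = ft.enhance(scene.image, pre.roi)
    outside = ~pre.roi.pixels
    assert np.array_equal(out.pixels[outside], scene.image.pixels[outside])


def test_enhance_does_not_lose_entropy():
    """CLAHE on a low-contrast rendering keeps or raises L-histogram entropy."""
    p = ft.SynthImageParams(size=128, rho_target=0.2, brightness_gain=0.6,
                            noise_sigma=3.0, seed=5)
    scene = ft.generate_image(p)
    roi = ft.establish_roi(scene.image)

    def entropy(img):
        lum = color.rgb2lab(img.pixels)[:, :, 0][roi.pixels]
        hist, _ = np.histogram(lum, bins=64, range=(0, 100), density=True)
        hist = hist[hist > 0]
        return float(-(hist * np.log2(hist)).sum())

    assert entropy(ft.enhance(scene.image, roi)) >= entropy(scene.image) - 1e-9


def test_preprocess_is_the_composition(synth_case):
    scene, pre = synth_case(rho=0.15, seed=21)
    den = ft.denoise(scene.image)
    roi = ft.establish_roi(den)
    norm = ft.normalize(den, roi=roi)
    enh = ft.enhance(norm, roi)
    assert np.array_equal(pre.roi.pixels, roi.pixels)
    assert np.array_equal(pre.enhanced.pixels, enh.pixels)
    assert pre.enhanced.shape == scene.image.shape


def test_transfer_function_bounds():
    tf = _lowpass_transfer(64, 64, 0.5)
    assert tf.max() <= 1.0 and tf.min() >= 0.0 and tf[0, 0] == 1.0
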