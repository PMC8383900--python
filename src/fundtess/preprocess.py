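"""Fundus photograph preprocessing: ROI, denoising, normalization, CLAHE.

The imaged fundus field on a 45-degree photograph is a bright near-circular
disc on a dark camera background. Preprocessing (a) locates that field as
the region of interest (ROI) from the red channel, where the background is
darkest, (b) suppresses acquisition noise with a frequency-domain low-pass,
(c) calibrates mean lightness in CIELAB so images are comparable, and
(d) enhances local contrast inside the ROI with contrast-limited adaptive
histogram equalization (CLAHE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage import color, exposure, measure
from skimage.filters import threshold_otsu

from .errors import EmptyROI, InvalidConfig, NoROIFound
from .image import BinaryMask, FundusImage


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Attributes
    ----------
    lowpass_cutoff
        Low-pass cutoff as a fraction of the Nyquist frequency, in (0, 1].
        1.0 keeps every representable frequency (pass-through).
    target_L
        Mean-lightness target on the CIELAB 0-100 L scale.
    clahe_clip
        CLAHE contrast-limit parameter (histogram clip); larger means
        stronger enhancement.
    clahe_tiles
        Side of the CLAHE tile grid (``clahe_tiles x clahe_tiles`` blocks).
    roi_min_area_fraction
        Minimum candidate area as a fraction of the frame.
    roi_circularity_min
        Minimum circularity ``4*pi*A / P**2`` of the candidate.
    """

    lowpass_cutoff: float = 0.35
    target_L: float = 60.0
    clahe_clip: float = 2.0
    clahe_tiles: int = 4
    roi_min_area_fraction: float = 0.15
    roi_circularity_min: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.lowpass_cutoff <= 1.0):
            raise InvalidConfig(f"lowpass_cutoff {self.lowpass_cutoff} outside (0, 1]")
        if not (0.0 < self.target_L < 100.0):
            raise InvalidConfig(f"target_L {self.target_L} outside (0, 100)")
        if self.clahe_clip <= 0:
            raise InvalidConfig("clahe_clip must be positive")
        if int(self.clahe_tiles) < 1:
            raise InvalidConfig("clahe_tiles must be a positive integer")
        for name in ("roi_min_area_fraction", "roi_circularity_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidConfig(f"{name} {v} outside (0, 1)")


def split_channels(img: FundusImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Separate the red, green and blue channels as 2-D uint8 arrays."""
    px = img.pixels
    return px[:, :, 0].copy(), px[:, :, 1].copy(), px[:, :, 2].copy()


def restack_channels(red: np.ndarray, green: np.ndarray, blue: np.ndarray) -> FundusImage:
    """Inverse of :func:`split_channels`."""
    return FundusImage(np.stack([red, green, blue], axis=-1).astype(np.uint8))


def establish_roi(img: FundusImage, cfg: PreprocessConfig | None = None) -> BinaryMask:
    """Locate the imaged fundus field on the dark camera background.

    The red channel is thresholded (Otsu, keeping the bright side);
    candidate components are hole-filled and screened by mean intensity
    (at least the global red mean), area fraction, circularity and
    centroid position (central third of the frame). The largest surviving
    component is the ROI.

    Raises
    ------
    NoROIFound
        If no candidate survives every screen.
    """
    cfg = cfg or PreprocessConfig()
    red = img.pixels[:, :, 0].astype(np.float64)
    h, w = red.shape
    try:
        t = threshold_otsu(red)
    except ValueError:  # single-valued image
        raise NoROIFound("image has no intensity variation") from None
    bright = red > t
    if not bright.any():
        raise NoROIFound("no bright region above threshold")
    # bridge the dark retinal-vessel tree so the field stays one component
    close_r = max(2, int(round(0.025 * min(h, w))))
    selem = np.ones((2 * close_r + 1, 2 * close_r + 1), dtype=bool)
    bright = ndimage.binary_closing(bright, structure=selem)
    labels = measure.label(bright, connectivity=2)
    global_mean = red.mean()
    best: np.ndarray | None = None
    best_area = 0
    for region in measure.regionprops(labels):
        comp = ndimage.binary_fill_holes(labels == region.label)
        area = int(comp.sum())
        if area < cfg.roi_min_area_fraction * h * w:
            continue
        if red[comp].mean() < global_mean:
            continue
        filled = measure.regionprops(comp.astype(np.uint8))[0]
        perim = filled.perimeter
        if perim <= 0:
            continue
        circularity = 4.0 * np.pi * area / perim**2
        if circularity < cfg.roi_circularity_min:
            continue
        cy, cx = filled.centroid
        if not (h / 3 <= cy <= 2 * h / 3 and w / 3 <= cx <= 2 * w / 3):
            continue
        if area > best_area:
            best, best_area = comp, area
    if best is None:
        raise NoROIFound("no candidate survived area/intensity/shape/location screens")
    return BinaryMask(best, kind="roi")


def _lowpass_transfer(h: int, w: int, cutoff: float) -> np.ndarray:
    """Transfer function: flat passband up to ``cutoff`` x Nyquist, Gaussian roll-off.

    Frequencies are measured per axis and combined with the Chebyshev norm,
    so ``cutoff=1.0`` is an exact pass-through for any representable signal.
    """
    fy = np.abs(np.fft.fftfreq(h)) / 0.5  # fraction of Nyquist
    fx = np.abs(np.fft.fftfreq(w)) / 0.5
    fn = np.maximum(fy[:, None], fx[None, :])
    rolloff = 0.1
    excess = np.maximum(fn - cutoff, 0.0)
    return np.exp(-0.5 * (excess / rolloff) ** 2)


def denoise(img: FundusImage, cfg: PreprocessConfig | None = None) -> FundusImage:
    """Frequency-domain low-pass denoising, per channel.

    Each channel is transformed with the FFT, multiplied by a flat-passband
    transfer function with a Gaussian roll-off above ``lowpass_cutoff`` x
    Nyquist, transformed back and re-quantized to [0, 255]. Spectral energy
    above the cutoff is strictly reduced for any input with content there.
    """
    cfg = cfg or PreprocessConfig()
    h, w = img.shape
    transfer = _lowpass_transfer(h, w, cfg.lowpass_cutoff)
    out = np.empty_like(img.pixels)
    for c in range(3):
        chan = img.pixels[:, :, c].astype(np.float64)
        filtered = np.fft.ifft2(np.fft.fft2(chan) * transfer).real
        out[:, :, c] = np.clip(np.rint(filtered), 0, 255).astype(np.uint8)
    return FundusImage(out)


def normalize(img: FundusImage, cfg: PreprocessConfig | None = None,
              roi: BinaryMask | None = None) -> FundusImage:
    """Calibrate mean lightness to ``target_L`` in CIELAB.

    The image is converted to LAB, the L channel is shifted so its mean
    (over the ROI if given, else the full frame) equals ``target_L``, and
    the result is converted back to RGB. A and B are untouched before the
    return conversion.
    """
    cfg = cfg or PreprocessConfig()
    sel = roi.pixels if roi is not None else np.ones(img.shape, dtype=bool)
    if not sel.any():
        raise EmptyROI("normalization ROI is empty")
    # saturated pixels clip against the sRGB gamut on the way back, which
    # drags the realized mean below the applied shift; iterate to the target
    out = img.pixels
    for _ in range(6):
        lab = color.rgb2lab(out)
        shift = cfg.target_L - lab[:, :, 0][sel].mean()
        if abs(shift) <= 0.25:
            break
        lab[:, :, 0] = np.clip(lab[:, :, 0] + shift, 0.0, 100.0)
        out = np.clip(np.rint(color.lab2rgb(lab) * 255.0), 0, 255).astype(np.uint8)
    return FundusImage(out)


def enhance(img: FundusImage, roi: BinaryMask,
            cfg: PreprocessConfig | None = None) -> FundusImage:
    """CLAHE on the L channel inside the ROI; pixels outside are untouched.

    The L channel is equalized on a ``clahe_tiles x clahe_tiles`` grid with
    clip parameter ``clahe_clip``; the enhanced L is recombined with the
    original A/B channels and written back only where the ROI is true.
    """
    cfg = cfg or PreprocessConfig()
    if img.shape != roi.shape:
        raise EmptyROI(f"roi shape {roi.shape} does not match image {img.shape}")
    if not roi.pixels.any():
        raise EmptyROI("enhancement ROI is empty")
    lab = color.rgb2lab(img.pixels)
    L = lab[:, :, 0]
    inside = L[roi.pixels]
    if inside.max() - inside.min() < 1e-9:
        return FundusImage(img.pixels.copy())  # degenerate histogram: identity
    h, w = img.shape
    kernel = (max(1, int(np.ceil(h / cfg.clahe_tiles))),
              max(1, int(np.ceil(w / cfg.clahe_tiles))))
    # skimage expects [0, 1]; the clip parameter counts multiples of the
    # uniform histogram bin height, mapped onto skimage's fractional scale
    L_eq = exposure.equalize_adapthist(
        L / 100.0, kernel_size=kernel, clip_limit=cfg.clahe_clip / 256.0
    ) * 100.0
    lab_out = lab.copy()
    lab_out[:, :, 0] = np.where(roi.pixels, L_eq, L)
    rgb = np.clip(np.rint(color.lab2rgb(lab_out) * 255.0), 0, 255).astype(np.uint8)
    out = img.pixels.copy()
    out[roi.pixels] = rgb[roi.pixels]
    return FundusImage(out)


class PreprocessResult(NamedTuple):
    enhanced: FundusImage
    roi: BinaryMask
    params: dict


def preprocess(img: FundusImage, cfg: PreprocessConfig | None = None) -> PreprocessResult:
    """Full chain: denoise -> ROI -> lightness normalization -> CLAHE.

    The ROI is established on the denoised image; normalization and
    enhancement operate inside it. Output dimensions equal input
    dimensions.
    """
    cfg = cfg or PreprocessConfig()
    den = denoise(img, cfg)
    roi = establish_roi(den, cfg)
    norm = normalize(den, cfg, roi=roi)
    enh = enhance(norm, roi, cfg)
    params = {
        "lowpass_cutoff": cfg.lowpass_cutoff,
        "target_L": cfg.target_L,
        "clahe_clip": cfg.clahe_clip,
        "clahe_tiles": cfg.clahe_tiles,
        "roi_min_area_fraction": cfg.roi_min_area_fraction,
        "roi_circularity_min": cfg.roi_circularity_min,
        "roi_area_px": roi.area_px,
    }
    return PreprocessResult(enhanced=enh, roi=roi, params=params)
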