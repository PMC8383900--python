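"""Automatic exposed-choroid labeling by channel subtraction.

Exposed choroid is red-dominant relative to the overlying retina, so the
signed difference of two color channels (red minus green by default)
separates it from retinal tissue. The difference image is thresholded
inside the ROI, cleaned morphologically, and small speckles are removed.
This is the coarse automatic half of semi-automatic labeling; manually
corrected masks are simply read back from disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .errors import EmptyROI, InvalidConfig
from .image import BinaryMask, FundusImage

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class AutolabelConfig:
    """Parameters of the channel-subtraction labeler.

    ``subtraction_pair`` is an ordered (first, second) channel pair; the
    difference image is first minus second. ``threshold_method`` is
    ``"otsu"`` (floored at ``noise_floor``, see :func:`auto_label`) or
    ``"percentile"`` with quantile ``percentile_q``. ``noise_floor`` is
    the minimum red-green excess (intensity levels) a pixel must show:
    the preprocessing chain standardizes brightness and local contrast,
    so a fixed floor separates tessellation from residual noise texture
    and keeps a tessellation-free fundus essentially unlabeled.
    """

    subtraction_pair: tuple[str, str] = ("red", "green")
    threshold_method: str = "otsu"
    percentile_q: float = 80.0
    min_blob_px: int = 16
    morph_radius_px: int = 0
    noise_floor: float = 25.0

    def __post_init__(self) -> None:
        for ch in self.subtraction_pair:
            if ch not in _CHANNEL_INDEX:
                raise InvalidConfig(f"unknown channel {ch!r}")
        if self.subtraction_pair[0] == self.subtraction_pair[1]:
            raise InvalidConfig("subtraction channels must differ")
        if self.threshold_method not in ("otsu", "percentile"):
            raise InvalidConfig(f"unknown threshold method {self.threshold_method!r}")
        if not (0.0 < self.percentile_q < 100.0):
            raise InvalidConfig("percentile_q outside (0, 100)")
        if self.min_blob_px < 1:
            raise InvalidConfig("min_blob_px must be positive")
        if self.morph_radius_px < 0:
            raise InvalidConfig("morph_radius_px must be non-negative")
        if self.noise_floor < 0:
            raise InvalidConfig("noise_floor must be non-negative")


def auto_label(img: FundusImage, roi: BinaryMask,
               cfg: AutolabelConfig | None = None) -> BinaryMask:
    """Label exposed choroid inside the ROI by channel subtraction.

    The signed channel difference is smoothed at the scale of a band,
    centered on its ROI median, and thresholded at the larger of the Otsu
    threshold and ``noise_floor``. Otsu adapts upward when tessellation
    is strong; the floor keeps a fundus with no tessellation (noise-only
    difference image) essentially unlabeled instead of splitting the
    noise distribution in half.
    """
    cfg = cfg or AutolabelConfig()
    if img.shape != roi.shape:
        raise EmptyROI(f"roi shape {roi.shape} does not match image {img.shape}")
    if not roi.pixels.any():
        raise EmptyROI("ROI mask has no pixels")
    i, j = (_CHANNEL_INDEX[c] for c in cfg.subtraction_pair)
    diff = img.pixels[:, :, i].astype(np.float64) - img.pixels[:, :, j].astype(np.float64)
    # smooth at the scale of a band to average pixel noise down, and
    # center on the ROI median (the retinal baseline)
    diff = ndimage.gaussian_filter(diff, 1.0)
    diff = diff - np.median(diff[roi.pixels])
    vals = diff[roi.pixels]
    if cfg.threshold_method == "percentile":
        t = np.percentile(vals, cfg.percentile_q)
    else:
        try:
            t = threshold_otsu(vals)
        except ValueError:  # constant difference image
            return BinaryMask(np.zeros(img.shape, dtype=bool), kind="choroid")
        t = max(t, cfg.noise_floor)
    raw = (diff > t) & roi.pixels
    if cfg.morph_radius_px > 0:
        selem = morphology.disk(cfg.morph_radius_px)
        raw = ndimage.binary_opening(raw, structure=selem)
        raw = ndimage.binary_closing(raw, structure=selem)
    cleaned = morphology.remove_small_objects(raw, max_size=cfg.min_blob_px - 1)
    return BinaryMask(cleaned & roi.pixels, kind="choroid")


def load_corrected_mask(path: str | Path,
                        expect_shape: tuple[int, int] | None = None) -> BinaryMask:
    """Read a manually corrected exposed-choroid mask (0/255 PNG).

    Gray multi-channel PNGs with equal channels are accepted; any other
    value set is rejected.
    """
    return BinaryMask.open(path, kind="choroid", expect_shape=expect_shape)
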