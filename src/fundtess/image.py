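"""Core raster types: fundus photographs, binary masks, confidence maps.

A :class:`FundusImage` is an 8-bit RGB raster; a :class:`BinaryMask` is a
boolean raster tagged as either the imaged fundus field (``roi``) or an
exposed-choroid region (``choroid``). Masks serialize as single-channel
0/255 PNG; images as 8-bit RGB PNG/JPEG. All rasters are row-major with
0-based pixel indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image as PILImage

from .errors import InvalidImage, MaskShapeMismatch, NonBinaryMask

MaskKind = Literal["roi", "choroid"]

MIN_SIDE = 64


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit RGB color fundus photograph.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, channel order red, green, blue.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InvalidImage(
                f"expected an (H, W, 3) RGB array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise InvalidImage(f"expected 8-bit intensities, got dtype {px.dtype}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise InvalidImage(
                f"image {px.shape[0]}x{px.shape[1]} below minimum {MIN_SIDE}x{MIN_SIDE}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @classmethod
    def open(cls, path: str | Path) -> "FundusImage":
        """Read an 8-bit RGB PNG or JPEG."""
        with PILImage.open(path) as im:
            return cls(np.asarray(im.convert("RGB")))

    def save(self, path: str | Path) -> None:
        PILImage.fromarray(self.pixels).save(path)


@dataclass(frozen=True)
class BinaryMask:
    """A per-pixel boolean raster annotating a fundus image.

    ``kind="roi"`` marks the imaged fundus field; ``kind="choroid"`` marks
    exposed choroid. A choroid mask is meaningful only inside its paired
    ROI; :meth:`clipped_to` enforces the subset relation.
    """

    pixels: np.ndarray
    kind: MaskKind = field(default="choroid")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise MaskShapeMismatch(f"mask must be 2-D, got shape {px.shape}")
        if px.dtype != bool:
            px = px.astype(bool)
        if self.kind not in ("roi", "choroid"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.pixels.shape)  # type: ignore[return-value]

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def clipped_to(self, roi: "BinaryMask") -> "BinaryMask":
        """Intersect with an ROI so the subset invariant holds."""
        if self.shape != roi.shape:
            raise MaskShapeMismatch(
                f"mask shape {self.shape} vs roi shape {roi.shape}"
            )
        return BinaryMask(self.pixels & roi.pixels, kind=self.kind)

    @classmethod
    def open(cls, path: str | Path, kind: MaskKind = "choroid",
             expect_shape: tuple[int, int] | None = None) -> "BinaryMask":
        """Read a 0/255 PNG mask.

        Gray multi-channel PNGs (all channels equal) are accepted and
        collapsed to one channel; any value other than 0 or 255 is
        rejected.
        """
        with PILImage.open(path) as im:
            arr = np.asarray(im)
        if arr.ndim == 3:
            if not (arr == arr[..., :1]).all():
                raise NonBinaryMask(f"{path}: multi-channel mask with unequal channels")
            arr = arr[..., 0]
        if arr.ndim != 2:
            raise NonBinaryMask(f"{path}: not a single-channel raster")
        values = np.unique(arr)
        if not np.isin(values, (0, 255)).all():
            raise NonBinaryMask(
                f"{path}: mask values other than 0/255 present: {values[:10].tolist()}"
            )
        if expect_shape is not None and tuple(arr.shape) != tuple(expect_shape):
            raise MaskShapeMismatch(
                f"{path}: mask shape {arr.shape} does not match image {expect_shape}"
            )
        return cls(arr == 255, kind=kind)

    def save(self, path: str | Path) -> None:
        PILImage.fromarray(self.pixels.astype(np.uint8) * 255).save(path)


@dataclass(frozen=True)
class ConfidenceMap:
    """Per-pixel probability that a pixel is exposed choroid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise MaskShapeMismatch(f"confidence map must be 2-D, got {v.shape}")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("confidence values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]
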