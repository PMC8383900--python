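"""Encoder-decoder segmentation of exposed choroid.

A compact fully-convolutional network maps an enhanced fundus photograph
to a per-pixel confidence map for exposed choroid; thresholding the map
yields the final mask. Two encoder depths are available: ``tiny`` (plain
conv stack, minutes on one CPU) and ``resnet18`` (a residual-block
encoder in the same spirit at small scale). Features are extracted at
half resolution and brought back to full resolution by nearest-neighbor
upsampling followed by convolution.

Training minimizes per-pixel binary cross-entropy (positive class
up-weighted against the foreground/background imbalance) with Adam. All
randomness flows from ``SegModelSpec.seed``, so identical spec + data +
seed reproduce identical losses and weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from . import nn
from .errors import (InvalidConfig, InvalidThreshold, MaskShapeMismatch,
                     ModelNotTrained, NoTrainingData)
from .image import BinaryMask, ConfidenceMap, FundusImage

_NORM_MEAN = 0.45
_NORM_STD = 0.25


@dataclass(frozen=True)
class SegModelSpec:
    """Architecture and training hyperparameters."""

    encoder_depth: str = "tiny"
    input_size: int = 128
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 2e-3
    seed: int = 0
    confidence_threshold: float = 0.5
    pos_weight: float = 3.0

    def __post_init__(self) -> None:
        if self.encoder_depth not in ("tiny", "resnet18"):
            raise InvalidConfig(f"unknown encoder_depth {self.encoder_depth!r}")
        if self.input_size < 16 or self.input_size % 2:
            raise InvalidConfig("input_size must be an even integer >= 16")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidConfig("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise InvalidConfig("learning_rate must be positive")
        if not (0.0 < self.confidence_threshold < 1.0):
            raise InvalidConfig("confidence_threshold outside (0, 1)")
        if self.pos_weight <= 0:
            raise InvalidConfig("pos_weight must be positive")


def _build(spec: SegModelSpec, rng: np.random.Generator) -> nn.Sequential:
    C = nn.Conv2D
    if spec.encoder_depth == "tiny":
        layers = [
            C(3, 8, rng=rng), nn.ReLU(),
            C(8, 16, stride=2, rng=rng), nn.ReLU(),
            C(16, 16, rng=rng), nn.ReLU(),
            nn.Upsample2x(),
            C(16, 8, rng=rng), nn.ReLU(),
            C(8, 1, k=1, pad=0, rng=rng),
        ]
    else:  # residual encoder
        layers = [
            C(3, 8, rng=rng), nn.ReLU(),
            nn.Residual([C(8, 8, rng=rng), nn.ReLU(), C(8, 8, rng=rng)]),
            nn.Residual([C(8, 8, rng=rng), nn.ReLU(), C(8, 8, rng=rng)]),
            C(8, 16, stride=2, rng=rng), nn.ReLU(),
            nn.Residual([C(16, 16, rng=rng), nn.ReLU(), C(16, 16, rng=rng)]),
            nn.Residual([C(16, 16, rng=rng), nn.ReLU(), C(16, 16, rng=rng)]),
            nn.Upsample2x(),
            C(16, 8, rng=rng), nn.ReLU(),
            C(8, 1, k=1, pad=0, rng=rng),
        ]
    return nn.Sequential(layers)


def _prep_image(img: FundusImage, size: int) -> np.ndarray:
    x = img.pixels.astype(np.float32) / 255.0
    if img.shape != (size, size):
        x = resize(x, (size, size), order=1, anti_aliasing=True,
                   preserve_range=True).astype(np.float32)
    x = (x - _NORM_MEAN) / _NORM_STD
    return x.transpose(2, 0, 1)


def _prep_mask(mask: BinaryMask, size: int) -> np.ndarray:
    y = mask.pixels.astype(np.float32)
    if mask.shape != (size, size):
        y = resize(y, (size, size), order=0, preserve_range=True).astype(np.float32)
    return y[None]


class SegModel:
    """A trained (or trainable) segmentation network."""

    def __init__(self, spec: SegModelSpec):
        self.spec = spec
        self.net = _build(spec, np.random.default_rng(spec.seed))
        self.trained = False
        self.history: list[float] = []
        self.data_digest: str | None = None

    # -- inference ---------------------------------------------------------
    def predict_confidence(self, img: FundusImage) -> ConfidenceMap:
        """Per-pixel exposed-choroid probability at the input resolution."""
        if not self.trained:
            raise ModelNotTrained("call train() or load() first")
        x = _prep_image(img, self.spec.input_size)[None]
        z = self.net.forward(x.astype(np.float32))
        p = nn.sigmoid(z)[0, 0].astype(np.float64)
        if p.shape != img.shape:
            p = resize(p, img.shape, order=0, preserve_range=True)
        return ConfidenceMap(np.clip(p, 0.0, 1.0))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights to ``path`` (binary) plus a ``.json`` sidecar."""
        path = Path(path)
        state = {name: value for name, value in self.net.named_params()}
        with open(path, "wb") as fh:
            np.savez(fh, **state)
        sidecar = {
            "spec": asdict(self.spec),
            "trained": self.trained,
            "history": self.history,
            "data_digest": self.data_digest,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        spec = SegModelSpec(**sidecar["spec"])
        model = cls(spec)
        with np.load(path) as data:
            model.net.load_named_params({k: data[k] for k in data.files})
        model.trained = bool(sidecar["trained"])
        model.history = list(sidecar["history"])
        model.data_digest = sidecar["data_digest"]
        return model


def train(pairs: list[tuple[FundusImage, BinaryMask]], spec: SegModelSpec) -> SegModel:
    """Fit the network on (image, exposed-choroid mask) pairs.

    Raises
    ------
    NoTrainingData
        If ``pairs`` is empty.
    MaskShapeMismatch
        If any mask does not match its image.
    """
    if not pairs:
        raise NoTrainingData("training set is empty")
    for img, mask in pairs:
        if img.shape != mask.shape:
            raise MaskShapeMismatch(
                f"mask {mask.shape} does not match image {img.shape}"
            )
    size = spec.input_size
    X = np.stack([_prep_image(im, size) for im, _ in pairs]).astype(np.float32)
    Y = np.stack([_prep_mask(m, size) for _, m in pairs]).astype(np.float32)

    digest = hashlib.sha256()
    for im, m in pairs:
        digest.update(im.pixels.tobytes())
        digest.update(np.packbits(m.pixels).tobytes())

    model = SegModel(spec)
    opt = nn.Adam(model.net, lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed + 1)
    n = len(pairs)
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            z = model.net.forward(X[idx])
            loss, dz = nn.bce_with_logits(z, Y[idx], pos_weight=spec.pos_weight)
            model.net.backward(dz)
            opt.step()
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    model.trained = True
    model.data_digest = digest.hexdigest()
    return model


def predict_confidence(model: SegModel, img: FundusImage) -> ConfidenceMap:
    """Functional alias for :meth:`SegModel.predict_confidence`."""
    return model.predict_confidence(img)


def threshold_confidence(cmap: ConfidenceMap, t: float) -> BinaryMask:
    """Pixels with confidence >= ``t`` become exposed choroid."""
    if not (0.0 < t < 1.0):
        raise InvalidThreshold(f"threshold {t} outside (0, 1)")
    return BinaryMask(cmap.values >= t, kind="choroid")
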