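"""Visual encoder: CNN feature extraction over a spatial grid.

The encoder turns a 1-channel 224x224 image into a grid of per-location
feature vectors a = {a_1 .. a_N}: convolutional features are taken
before any fully connected layer, adaptively average-pooled to D x D,
and flattened row-major to an (N, C) matrix with N = D^2.  The caption
decoder attends over these N spatial locations.

The default backbone is a small 3-block CNN trained from scratch
(C = 64); heavier classification backbones (DenseNet-121 and friends)
are pluggable — any module mapping (B, 1, H, W) -> (B, C, H', W') works
— and their documented channel counts are recorded in
:func:`backbone_channels`.  A fine-tune toggle freezes or unfreezes the
backbone parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, no_grad

#: channels C produced by the classification backbones discussed for real data
_BACKBONE_CHANNELS = {
    "densenet121": 1024,
    "vgg16": 512,
    "resnet101": 2048,
    "inceptionv3": 2048,
    "small_cnn": 64,
}


def backbone_channels(name: str) -> int:
    try:
        return _BACKBONE_CHANNELS[name.lower().replace("-", "")]
    except KeyError:
        raise KeyError(f"unknown backbone '{name}'") from None


@dataclass
class FeatureGrid:
    features: np.ndarray   # (N, C)
    side: int              # D, with N = D*D
    image_id: str = ""

    def __post_init__(self):
        n, _ = self.features.shape
        if n != self.side * self.side:
            raise ValueError("feature count must equal side**2")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite features")


class SmallCNN(nn.Module):
    """3-block CNN: 224 -> 55 -> 27 -> 13 spatial, 64 output channels.

    Convolutions are unpadded so a constant image yields a constant
    feature map (no border artefacts in the attention grid).
    """

    channels = 64

    def __init__(self, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(1, 16, 7, rng, stride=4)
        self.conv2 = nn.Conv2d(16, 32, 3, rng, stride=2)
        self.conv3 = nn.Conv2d(32, self.channels, 3, rng, stride=2)

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        return self.conv3(x).relu()


class ImageEncoder(nn.Module):
    """Backbone + adaptive average pooling to a D x D feature grid."""

    def __init__(self, rng=None, backbone=None, side: int = 7,
                 image_size: int = 224, finetune: bool = True):
        super().__init__()
        if backbone is None:
            if rng is None:
                rng = np.random.default_rng(0)
            backbone = SmallCNN(rng)
        self.backbone = backbone
        self.side = side
        self.image_size = image_size
        self.channels = getattr(backbone, "channels", None)
        set_finetune(self, finetune)

    @property
    def num_locations(self) -> int:
        return self.side * self.side

    def forward(self, images: Tensor) -> Tensor:
        """(B, 1, H, W) -> (B, N, C) row-major spatial feature grids."""
        if images.ndim != 4:
            raise ValueError(f"expected (B, 1, {self.image_size}, {self.image_size}) "
                             f"input, got shape {images.shape}")
        fmap = self.backbone(images)                       # (B, C, H', W')
        pooled = nn.adaptive_avg_pool2d(fmap, self.side)   # (B, C, D, D)
        return flatten_features(pooled)

    def encode_image(self, image: np.ndarray, image_id: str = "") -> FeatureGrid:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim == 2:
            image = image[None, :, :]
        if image.shape != (1, self.image_size, self.image_size):
            raise ValueError(
                f"expected image of shape (1, {self.image_size}, "
                f"{self.image_size}), got {image.shape}")
        with no_grad():
            grid = self.forward(Tensor(image[None]))
        return FeatureGrid(features=grid.data[0], side=self.side, image_id=image_id)


def flatten_features(pooled: Tensor) -> Tensor:
    """(B, C, D, D) -> (B, N, C); row i maps to location (i // D, i % D)."""
    B, C, D, D2 = pooled.shape
    if D != D2:
        raise ValueError("pooled grid must be square")
    return pooled.reshape((B, C, D * D)).transpose((0, 2, 1))


def set_finetune(encoder: ImageEncoder, enabled: bool):
    """Enable/disable gradient computation for the backbone parameters."""
    for p in encoder.backbone.parameters():
        p.requires_grad = bool(enabled)
    encoder.finetune = bool(enabled)
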