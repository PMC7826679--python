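"""Feature-extraction backbones.

Two architectures behind one contract — an extractor maps an NHWC image batch
to an NCHW feature map of declared spatial size and channel depth:

``inception_v3``
    The GoogLeNet Inception-v3 layout: stem (299×299×3 → 35×35×192), three
    Inception-A blocks (→ 35×35×288), grid reduction plus four Inception-B
    blocks (→ 17×17×768), a second reduction plus two Inception-C blocks
    (→ 8×8×2048).  The 8×8×2048 map is taken *before* global pooling, which is
    the input the label-wise aggregation stage expects.  Auxiliary classifiers
    are omitted (they are never wired into the relation network).

``tiny``
    Four conv–norm–ReLU stages whose strides are derived from the requested
    input/output sizes; defaults map 64×64×3 → 8×8×64.  It exists so the full
    pipeline trains on one CPU in minutes.

Input pixels in [0, 1] are rescaled to [−1, 1] (the Inception convention)
inside the extractor; set ``normalize=False`` in the config to disable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import avg_pool2d, concat, max_pool2d

__all__ = ["BackboneConfig", "build_backbone", "extract_features", "TinyBackbone", "InceptionV3Backbone"]


@dataclass(frozen=True)
class BackboneConfig:
    arch: str = "tiny"
    input_size: int | None = None
    out_spatial: tuple[int, int] = (8, 8)
    out_channels: int = 64
    pretrained: bool = False
    weights: str | Path | None = None
    normalize: bool = True
    seed: int = 0

    def resolved(self) -> "BackboneConfig":
        if self.arch == "inception_v3":
            return BackboneConfig(
                arch="inception_v3",
                input_size=299,
                out_spatial=(8, 8),
                out_channels=2048,
                pretrained=self.pretrained,
                weights=self.weights,
                normalize=self.normalize,
                seed=self.seed,
            )
        if self.arch == "tiny":
            return BackboneConfig(
                arch="tiny",
                input_size=self.input_size or 64,
                out_spatial=self.out_spatial,
                out_channels=self.out_channels,
                pretrained=self.pretrained,
                weights=self.weights,
                normalize=self.normalize,
                seed=self.seed,
            )
        raise ValueError(f"unknown backbone architecture {self.arch!r}")


class _Backbone(nn.Module):
    config: BackboneConfig

    def _prepare(self, images: np.ndarray | Tensor) -> Tensor:
        """NHWC [0,1] float images → NCHW tensor, rescaled to [−1, 1]."""
        if isinstance(images, Tensor):
            return images
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        expected = self.config.input_size
        if images.shape[1] != expected or images.shape[2] != expected:
            raise ValueError(
                f"backbone {self.config.arch!r} expects {expected}×{expected} input, "
                f"got {images.shape[1]}×{images.shape[2]}"
            )
        x = images.transpose(0, 3, 1, 2)
        if self.config.normalize:
            x = 2.0 * x - 1.0
        return Tensor(x)


class TinyBackbone(_Backbone):
    """Four-stage conv net; the number of stride-2 stages follows from the
    requested input/output spatial sizes, remaining stages are stride 1."""

    N_STAGES = 4

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        h_out, w_out = config.out_spatial
        if h_out != w_out:
            raise ValueError("tiny backbone assumes square output grids")
        halvings = int(round(np.log2(config.input_size / h_out)))
        if 2**halvings * h_out != config.input_size or halvings > self.N_STAGES:
            raise ValueError(
                f"cannot reach {h_out}×{w_out} from {config.input_size} with "
                f"{self.N_STAGES} stages of stride ≤ 2"
            )
        depth = config.out_channels
        widths = [max(8, depth // 8), max(8, depth // 4), max(8, depth // 2), depth]
        stages = []
        c_in = 3
        for i, width in enumerate(widths):
            stride = 2 if i < halvings else 1
            stages.append(nn.ConvBNReLU(c_in, width, 3, stride=stride, padding=1, rng=rng))
            c_in = width
        self.stages = stages

    def forward(self, images) -> Tensor:
        x = self._prepare(images)
        for stage in self.stages:
            x = stage(x)
        return x


class _InceptionA(nn.Module):
    def __init__(self, c_in: int, pool_channels: int, rng) -> None:
        super().__init__()
        self.b1 = nn.ConvBNReLU(c_in, 64, 1, rng=rng)
        self.b2_1 = nn.ConvBNReLU(c_in, 48, 1, rng=rng)
        self.b2_2 = nn.ConvBNReLU(48, 64, 5, padding=2, rng=rng)
        self.b3_1 = nn.ConvBNReLU(c_in, 64, 1, rng=rng)
        self.b3_2 = nn.ConvBNReLU(64, 96, 3, padding=1, rng=rng)
        self.b3_3 = nn.ConvBNReLU(96, 96, 3, padding=1, rng=rng)
        self.b4 = nn.ConvBNReLU(c_in, pool_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return concat(
            [
                self.b1(x),
                self.b2_2(self.b2_1(x)),
                self.b3_3(self.b3_2(self.b3_1(x))),
                self.b4(avg_pool2d(x, 3, 1, padding=1)),
            ],
            axis=1,
        )


class _ReductionA(nn.Module):
    def __init__(self, c_in: int, rng) -> None:
        super().__init__()
        self.b1 = nn.ConvBNReLU(c_in, 384, 3, stride=2, rng=rng)
        self.b2_1 = nn.ConvBNReLU(c_in, 64, 1, rng=rng)
        self.b2_2 = nn.ConvBNReLU(64, 96, 3, padding=1, rng=rng)
        self.b2_3 = nn.ConvBNReLU(96, 96, 3, stride=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return concat(
            [self.b1(x), self.b2_3(self.b2_2(self.b2_1(x))), max_pool2d(x, 3, 2)],
            axis=1,
        )


class _InceptionB(nn.Module):
    def __init__(self, c_in: int, mid: int, rng) -> None:
        super().__init__()
        self.b1 = nn.ConvBNReLU(c_in, 192, 1, rng=rng)
        self.b2_1 = nn.ConvBNReLU(c_in, mid, 1, rng=rng)
        self.b2_2 = nn.ConvBNReLU(mid, mid, (1, 7), padding=(0, 3), rng=rng)
        self.b2_3 = nn.ConvBNReLU(mid, 192, (7, 1), padding=(3, 0), rng=rng)
        self.b3_1 = nn.ConvBNReLU(c_in, mid, 1, rng=rng)
        self.b3_2 = nn.ConvBNReLU(mid, mid, (7, 1), padding=(3, 0), rng=rng)
        self.b3_3 = nn.ConvBNReLU(mid, mid, (1, 7), padding=(0, 3), rng=rng)
        self.b3_4 = nn.ConvBNReLU(mid, mid, (7, 1), padding=(3, 0), rng=rng)
        self.b3_5 = nn.ConvBNReLU(mid, 192, (1, 7), padding=(0, 3), rng=rng)
        self.b4 = nn.ConvBNReLU(c_in, 192, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b3 = self.b3_5(self.b3_4(self.b3_3(self.b3_2(self.b3_1(x)))))
        return concat(
            [
                self.b1(x),
                self.b2_3(self.b2_2(self.b2_1(x))),
                b3,
                self.b4(avg_pool2d(x, 3, 1, padding=1)),
            ],
            axis=1,
        )


class _ReductionB(nn.Module):
    def __init__(self, c_in: int, rng) -> None:
        super().__init__()
        self.b1_1 = nn.ConvBNReLU(c_in, 192, 1, rng=rng)
        self.b1_2 = nn.ConvBNReLU(192, 320, 3, stride=2, rng=rng)
        self.b2_1 = nn.ConvBNReLU(c_in, 192, 1, rng=rng)
        self.b2_2 = nn.ConvBNReLU(192, 192, (1, 7), padding=(0, 3), rng=rng)
        self.b2_3 = nn.ConvBNReLU(192, 192, (7, 1), padding=(3, 0), rng=rng)
        self.b2_4 = nn.ConvBNReLU(192, 192, 3, stride=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return concat(
            [
                self.b1_2(self.b1_1(x)),
                self.b2_4(self.b2_3(self.b2_2(self.b2_1(x)))),
                max_pool2d(x, 3, 2),
            ],
            axis=1,
        )


class _InceptionC(nn.Module):
    def __init__(self, c_in: int, rng) -> None:
        super().__init__()
        self.b1 = nn.ConvBNReLU(c_in, 320, 1, rng=rng)
        self.b2_1 = nn.ConvBNReLU(c_in, 384, 1, rng=rng)
        self.b2_2a = nn.ConvBNReLU(384, 384, (1, 3), padding=(0, 1), rng=rng)
        self.b2_2b = nn.ConvBNReLU(384, 384, (3, 1), padding=(1, 0), rng=rng)
        self.b3_1 = nn.ConvBNReLU(c_in, 448, 1, rng=rng)
        self.b3_2 = nn.ConvBNReLU(448, 384, 3, padding=1, rng=rng)
        self.b3_3a = nn.ConvBNReLU(384, 384, (1, 3), padding=(0, 1), rng=rng)
        self.b3_3b = nn.ConvBNReLU(384, 384, (3, 1), padding=(1, 0), rng=rng)
        self.b4 = nn.ConvBNReLU(c_in, 192, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b2 = self.b2_1(x)
        b3 = self.b3_2(self.b3_1(x))
        return concat(
            [
                self.b1(x),
                concat([self.b2_2a(b2), self.b2_2b(b2)], axis=1),
                concat([self.b3_3a(b3), self.b3_3b(b3)], axis=1),
                self.b4(avg_pool2d(x, 3, 1, padding=1)),
            ],
            axis=1,
        )


class InceptionV3Backbone(_Backbone):
    """Inception v3 up to the final 8×8×2048 convolutional feature map."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        # stem: 299 → 35×35×192
        self.stem = nn.Sequential(
            nn.ConvBNReLU(3, 32, 3, stride=2, rng=rng),      # 149×149×32
            nn.ConvBNReLU(32, 32, 3, rng=rng),               # 147×147×32
            nn.ConvBNReLU(32, 64, 3, padding=1, rng=rng),    # 147×147×64
        )
        self.stem2 = nn.Sequential(
            nn.ConvBNReLU(64, 80, 1, rng=rng),               # 73×73×80
            nn.ConvBNReLU(80, 192, 3, rng=rng),              # 71×71×192
        )
        self.mixed_a = [
            _InceptionA(192, 32, rng),                       # 35×35×256
            _InceptionA(256, 64, rng),                       # 35×35×288
            _InceptionA(288, 64, rng),                       # 35×35×288
        ]
        self.reduction_a = _ReductionA(288, rng)             # 17×17×768
        self.mixed_b = [
            _InceptionB(768, 128, rng),
            _InceptionB(768, 160, rng),
            _InceptionB(768, 160, rng),
            _InceptionB(768, 192, rng),
        ]
        self.reduction_b = _ReductionB(768, rng)             # 8×8×1280
        self.mixed_c = [_InceptionC(1280, rng), _InceptionC(2048, rng)]

    def forward(self, images) -> Tensor:
        x = self._prepare(images)
        x = self.stem(x)
        x = max_pool2d(x, 3, 2)                              # 73×73×64
        x = self.stem2(x)
        x = max_pool2d(x, 3, 2)                              # 35×35×192
        for block in self.mixed_a:
            x = block(x)
        x = self.reduction_a(x)
        for block in self.mixed_b:
            x = block(x)
        x = self.reduction_b(x)
        for block in self.mixed_c:
            x = block(x)
        return x


def build_backbone(config: BackboneConfig, rng: np.random.Generator | None = None) -> _Backbone:
    """Instantiate the extractor named by ``config.arch``.

    ``pretrained=True`` requires ``config.weights`` pointing at a saved state
    dict; there is no silent fall-back to random initialization.
    """
    config = config.resolved()
    if config.arch == "inception_v3":
        model = InceptionV3Backbone(config, rng)
    else:
        model = TinyBackbone(config, rng)
    if config.pretrained:
        if config.weights is None or not Path(config.weights).exists():
            raise FileNotFoundError(
                "pretrained backbone weights requested but no checkpoint found at "
                f"{config.weights!r}; pass weights= or set pretrained=False"
            )
        model.load_state_dict(dict(np.load(config.weights)))
    return model


def extract_features(images: np.ndarray, extractor: _Backbone) -> np.ndarray:
    """Run the extractor in inference mode; returns NCHW feature maps."""
    was_training = extractor.training
    extractor.eval()
    try:
        out = extractor(images).data
    finally:
        extractor.train(was_training)
    h, w = extractor.config.out_spatial
    expected = (out.shape[0], extractor.config.out_channels, h, w)
    if out.shape != expected:
        raise ValueError(f"feature-map shape {out.shape} != declared {expected}")
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values in extracted feature map")
    return out
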