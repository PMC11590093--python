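"""The four spatio-temporal classifier architectures.

All four map a standardized (batch, t, 8, 8) single-cell video to an
n-class probability vector:

* **CNN** — two conv blocks (8 then 16 channels, 3x3x3 kernels, ReLU,
  dropout, layer norm, max pooling). The first pool halves the temporal
  axis as well as the spatial one, taking 8x8 down to 2x2.
* **ResNet** — the same stem/pooling with two stages of two basic
  residual blocks, channel plans (8, 16) and (16, 32), no bottlenecks.
* **DenseNet** — two dense blocks (4 layers, growth 8) with a 1x1x1
  transition between, every layer receiving all previous feature maps.
* **CNN-LSTM** — three conv blocks pooling only spatially, the per-frame
  features fed to a 3-layer LSTM with hidden size 256; the last hidden
  state feeds the classifier head.

Every head is two fully connected layers ending in a softmax. Layer
normalization is used throughout. Before the head, the convolutional
models adaptively average the temporal axis to a fixed length so the same
architecture accepts any input length from the 30/60/90 min variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    AdaptiveAvgPoolTemporal,
    AddChannel,
    Conv3d,
    DenseBlock,
    Dropout,
    Flatten,
    Layer,
    LayerNorm,
    Linear,
    LSTM,
    MaxPool3d,
    Parameter,
    ReLU,
    ResidualBlock,
    Sequential,
    TemporalFeatures,
    softmax,
)

ARCHITECTURES = ("cnn", "resnet", "densenet", "cnnlstm")


@dataclass
class ModelConfig:
    architecture: str
    n_classes: int
    input_frames: int
    dropout: float = 0.2
    channels: tuple[int, int] = (8, 16)
    resnet_plan: tuple[tuple[int, int], ...] = ((8, 16), (16, 32))
    growth_rate: int = 8
    dense_layers: int = 4
    temporal_pool: int = 4  # adaptive temporal length before the head
    hidden_fc: int = 64
    lstm_hidden: int = 256
    lstm_layers: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.input_frames < 4:
            raise ValueError("need at least four frames")


class Classifier:
    """A backbone ending at logits plus a softmax output."""

    def __init__(self, backbone: Sequential, config: ModelConfig):
        self.backbone = backbone
        self.config = config
        self.training = False

    def parameters(self) -> list[Parameter]:
        return self.backbone.parameters()

    def train_mode(self, flag: bool) -> None:
        self.training = flag

    def logits(self, x: np.ndarray) -> np.ndarray:
        self.backbone.training = self.training
        return self.backbone.forward(np.asarray(x, dtype=np.float64))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(batch, t, 8, 8) -> (batch, n_classes) probabilities."""
        return softmax(self.logits(x))

    def backward(self, dlogits: np.ndarray) -> None:
        self.backbone.backward(dlogits)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.value[...] = w


def _head(in_features: int, cfg: ModelConfig, rng: np.random.Generator,
          seed_offset: int) -> list[Layer]:
    return [
        Flatten(),
        Linear(in_features, cfg.hidden_fc, rng=rng, name="head.fc1"),
        ReLU(),
        Dropout(cfg.dropout, seed=cfg.seed + seed_offset),
        Linear(cfg.hidden_fc, cfg.n_classes, rng=rng, name="head.fc2"),
    ]


def _conv_block(cin: int, cout: int, pool: tuple[int, int, int], cfg: ModelConfig,
                rng: np.random.Generator, idx: int) -> list[Layer]:
    return [
        Conv3d(cin, cout, rng=rng, name=f"block{idx}.conv"),
        ReLU(),
        Dropout(cfg.dropout, seed=cfg.seed + 100 + idx),
        LayerNorm(cout, name=f"block{idx}.ln"),
        MaxPool3d(pool),
    ]


def _check_temporal(cfg: ModelConfig) -> int:
    t_pooled = cfg.input_frames // 2
    if t_pooled < cfg.temporal_pool:
        raise ValueError(
            f"{cfg.input_frames} frames are too few for the temporal pooling plan "
            f"(pool by 2, then adaptive length {cfg.temporal_pool})"
        )
    return t_pooled


def build_model(config: ModelConfig) -> Classifier:
    """Instantiate one of the four architectures from its config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    c1, c2 = cfg.channels

    if cfg.architecture == "cnn":
        _check_temporal(cfg)
        layers: list[Layer] = [AddChannel()]
        layers += _conv_block(1, c1, (2, 2, 2), cfg, rng, 1)
        layers += _conv_block(c1, c2, (1, 2, 2), cfg, rng, 2)
        layers += [AdaptiveAvgPoolTemporal(cfg.temporal_pool)]
        layers += _head(c2 * cfg.temporal_pool * 2 * 2, cfg, rng, 1)

    elif cfg.architecture == "resnet":
        _check_temporal(cfg)
        layers = [
            AddChannel(),
            Conv3d(1, cfg.resnet_plan[0][0], rng=rng, name="stem.conv"),
            LayerNorm(cfg.resnet_plan[0][0], name="stem.ln"),
            ReLU(),
            MaxPool3d((2, 2, 2)),
        ]
        (s1_in, s1_out), (s2_in, s2_out) = cfg.resnet_plan
        layers += [
            ResidualBlock(s1_in, s1_out, rng, name="stage1.block1"),
            ResidualBlock(s1_out, s1_out, rng, name="stage1.block2"),
            MaxPool3d((1, 2, 2)),
            ResidualBlock(s2_in, s2_out, rng, name="stage2.block1"),
            ResidualBlock(s2_out, s2_out, rng, name="stage2.block2"),
            AdaptiveAvgPoolTemporal(cfg.temporal_pool),
        ]
        layers += _head(s2_out * cfg.temporal_pool * 2 * 2, cfg, rng, 2)

    elif cfg.architecture == "densenet":
        _check_temporal(cfg)
        stem_ch = c1
        layers = [
            AddChannel(),
            Conv3d(1, stem_ch, rng=rng, name="stem.conv"),
            LayerNorm(stem_ch, name="stem.ln"),
            ReLU(),
            MaxPool3d((2, 2, 2)),
        ]
        block1 = DenseBlock(stem_ch, cfg.dense_layers, cfg.growth_rate, rng, name="dense1")
        trans_out = block1.out_channels // 2
        layers += [
            block1,
            LayerNorm(block1.out_channels, name="trans.ln"),
            ReLU(),
            Conv3d(block1.out_channels, trans_out, kernel=(1, 1, 1), rng=rng,
                   name="trans.conv"),
            MaxPool3d((1, 2, 2)),
        ]
        block2 = DenseBlock(trans_out, cfg.dense_layers, cfg.growth_rate, rng, name="dense2")
        layers += [
            block2,
            LayerNorm(block2.out_channels, name="final.ln"),
            ReLU(),
            AdaptiveAvgPoolTemporal(cfg.temporal_pool),
        ]
        layers += _head(block2.out_channels * cfg.temporal_pool * 2 * 2, cfg, rng, 3)

    else:  # cnnlstm
        c3 = c2 * 2
        layers = [AddChannel()]
        layers += _conv_block(1, c1, (1, 2, 2), cfg, rng, 1)
        layers += _conv_block(c1, c2, (1, 2, 2), cfg, rng, 2)
        layers += _conv_block(c2, c3, (1, 2, 2), cfg, rng, 3)
        layers += [
            TemporalFeatures(),
            LSTM(c3, cfg.lstm_hidden, cfg.lstm_layers, rng, name="lstm"),
            Linear(cfg.lstm_hidden, cfg.hidden_fc, rng=rng, name="head.fc1"),
            ReLU(),
            Dropout(cfg.dropout, seed=cfg.seed + 200),
            Linear(cfg.hidden_fc, cfg.n_classes, rng=rng, name="head.fc2"),
        ]

    return Classifier(Sequential(*layers), cfg)
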