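"""LC-Net: an encoder-decoder segmentation network for dense canopies.

The encoder is the first five blocks of VGG16 (2,2,3,3,3 convolutions of
64,128,256,512,512 channels, max-pooling after blocks 1-4 only, so the
deepest features sit at stride 16).  The decoder has two branches: the
primary branch runs an FC block (the convolutional stand-in for VGG16's
fully-connected layers) and three decoder blocks with skip connections to
the pre-pool outputs of encoder blocks 4, 3 and 2, finishing at stride 2;
the secondary branch applies local context pyramid pooling (LCPP) to the
deepest encoder features.  LCPP mean-pools the input at several kernel
scales (stride 1, same shape), concatenates, and projects back to the
input channel count with 1x1 convolutions — multiple context vectors local
to large regions, in place of a single global context vector, so the
network stays usable across image sizes and ground sample distances.
The LCPP output is resized (bilinear in space, a learned 1x1 projection in
channels) to match the primary branch, concatenated, mixed by two further
convolutions, and reduced to logits at stride 2; bilinear x2 upsampling and
softmax produce the per-pixel class distribution.

Every convolution is followed by ReLU and then batch normalisation (that
order is deliberate and configurable), except the plain conv+ReLU encoder.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .types import N_CLASSES

# VGG16 feature-extractor geometry: convs per block and block widths.
VGG_BLOCK_CONVS = (2, 2, 3, 3, 3)
VGG_BLOCK_CHANNELS = (64, 128, 256, 512, 512)
ENCODER_REDUCTION = 16  # stride of the deepest encoder features


@dataclass
class NetworkConfig:
    """LC-Net hyperparameters.

    ``backbone_width_multiplier`` scales the VGG block widths for
    desk-scale experiments; ``fc_channels``/``mix_channels`` default to the
    full-size 1024/128.  ``lcpp_enabled=False`` gives the ablated
    "LC-Net without LCPP" variant.
    """

    n_classes: int = N_CLASSES
    fc_channels: int = 1024
    mix_channels: int = 128
    lcpp_pool_kernels: tuple[int, ...] = (3, 5)
    lcpp_n_convs: int = 2
    backbone_width_multiplier: float = 1.0
    lcpp_enabled: bool = True
    pretrained_backbone: bool = False
    bn_momentum: float = 0.9

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(k % 2 == 0 or k < 1 for k in self.lcpp_pool_kernels):
            raise ValueError("all LCPP pool kernels must be odd")
        if self.fc_channels < 1 or self.mix_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if not (0 < self.backbone_width_multiplier <= 1):
            raise ValueError("backbone_width_multiplier must lie in (0, 1]")
        if self.lcpp_n_convs < 1:
            raise ValueError("lcpp_n_convs must be >= 1")

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(c * self.backbone_width_multiplier)))
                     for c in VGG_BLOCK_CHANNELS)


@dataclass
class SegmentationOutput:
    """Per-pixel class distribution (and raw logits) at input resolution."""

    probabilities: np.ndarray  # H x W x n_classes, rows sum to 1
    logits: np.ndarray

    def validate(self) -> None:
        sums = self.probabilities.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-pixel probabilities do not sum to 1")

    @property
    def class_map(self) -> np.ndarray:
        return self.probabilities.argmax(axis=-1).astype(np.uint8)


class DecoderBlock:
    """Bilinear-resize deep features to the skip's size, concat, mix twice."""

    def __init__(self, deep_c: int, skip_c: int, mix_c: int, rng: np.random.Generator):
        self.deep_c = deep_c
        self.resize = nn.Resize()
        self.mix = nn.Chain([
            nn.conv_act_norm(deep_c + skip_c, mix_c, 3, rng),
            nn.conv_act_norm(mix_c, mix_c, 3, rng),
        ])

    def params(self) -> list[nn.Param]:
        return self.mix.params()

    def forward(self, deep: np.ndarray, skip: np.ndarray, train: bool = False) -> np.ndarray:
        self.resize.out_hw = (skip.shape[1], skip.shape[2])
        d = self.resize.forward(deep, train=train)
        return self.mix.forward(np.concatenate([d, skip], axis=-1), train=train)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gcat = self.mix.backward(gy)
        gdeep = self.resize.backward(gcat[..., : self.deep_c])
        gskip = gcat[..., self.deep_c :]
        return gdeep, np.ascontiguousarray(gskip)


class LCPPModule:
    """Local context pyramid pooling: shape-preserving in space and channels."""

    def __init__(self, c: int, kernels: tuple[int, ...], n_convs: int,
                 rng: np.random.Generator):
        self.pools = [nn.AvgPoolSame(k) for k in kernels]
        chains = [nn.conv_act_norm(len(kernels) * c, c, 1, rng)]
        chains += [nn.conv_act_norm(c, c, 1, rng) for _ in range(n_convs - 1)]
        self.convs = nn.Chain(chains)
        self.c = c

    def params(self) -> list[nn.Param]:
        return self.convs.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pooled = [p.forward(x, train=train) for p in self.pools]
        return self.convs.forward(np.concatenate(pooled, axis=-1), train=train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gcat = self.convs.backward(gy)
        gx = np.zeros_like(gcat[..., : self.c])
        for i, p in enumerate(self.pools):
            gx += p.backward(gcat[..., i * self.c : (i + 1) * self.c])
        return gx


class LCNet:
    """The full network; construction seeds all Xavier initialisation."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.config.validate()
        cfg = self.config
        rng = np.random.default_rng(seed)
        ch = cfg.encoder_channels

        self.enc_blocks: list[nn.Chain] = []
        cin = 3
        for n_convs, cout in zip(VGG_BLOCK_CONVS, ch):
            layers = []
            for _ in range(n_convs):
                layers.append(nn.conv_act_norm(cin, cout, 3, rng, norm=False))
                cin = cout
            self.enc_blocks.append(nn.Chain(layers))
        self.pools = [nn.MaxPool2() for _ in range(4)]

        fc = cfg.fc_channels
        self.fc = nn.Chain([
            nn.conv_act_norm(ch[4], fc, 3, rng),
            nn.conv_act_norm(fc, fc, 3, rng),
            nn.conv_act_norm(fc, fc, 3, rng),
            nn.conv_act_norm(fc, fc, 1, rng),
        ])

        mix = cfg.mix_channels
        self.decoders = [
            DecoderBlock(fc, ch[3], mix, rng),
            DecoderBlock(mix, ch[2], mix, rng),
            DecoderBlock(mix, ch[1], mix, rng),
        ]

        if cfg.lcpp_enabled:
            self.lcpp = LCPPModule(ch[4], tuple(cfg.lcpp_pool_kernels), cfg.lcpp_n_convs, rng)
            self.lcpp_proj = nn.Conv2D(ch[4], mix, 1, rng)
            self.lcpp_resize = nn.Resize()
            head_in = 2 * mix
        else:
            self.lcpp = None
            head_in = mix
        self.head_mix = nn.Chain([
            nn.conv_act_norm(head_in, mix, 3, rng),
            nn.conv_act_norm(mix, mix, 3, rng),
        ])
        self.head_logits = nn.Conv2D(mix, cfg.n_classes, 1, rng)
        self._cache: dict = {}

    # ------------------------------------------------------------------ params
    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.enc_blocks:
            ps += b.params()
        ps += self.fc.params()
        for d in self.decoders:
            ps += d.params()
        if self.lcpp is not None:
            ps += self.lcpp.params()
            ps += self.lcpp_proj.params()
        ps += self.head_mix.params()
        ps += self.head_logits.params()
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def fingerprint(self) -> dict:
        cfg = self.config
        return {
            "n_classes": cfg.n_classes,
            "fc_channels": cfg.fc_channels,
            "mix_channels": cfg.mix_channels,
            "lcpp_pool_kernels": list(cfg.lcpp_pool_kernels),
            "lcpp_n_convs": cfg.lcpp_n_convs,
            "backbone_width_multiplier": cfg.backbone_width_multiplier,
            "lcpp_enabled": cfg.lcpp_enabled,
            "parameter_count": self.parameter_count(),
        }

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.value[...] = v

    def save(self, path: str) -> None:
        arrays = {f"p{i}": v for i, v in enumerate(self.state())}
        np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
        with open((path[:-4] if path.endswith(".npz") else path) + ".json", "w") as fh:
            json.dump(self.fingerprint(), fh, indent=2)

    # ----------------------------------------------------------------- forward
    def encode(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """Pre-pool conv-stack outputs of the five encoder blocks."""
        h, w = x.shape[1], x.shape[2]
        if h % ENCODER_REDUCTION or w % ENCODER_REDUCTION:
            raise ValueError(
                f"input spatial dims {(h, w)} must be divisible by the encoder "
                f"reduction factor {ENCODER_REDUCTION}"
            )
        feats = []
        for i, block in enumerate(self.enc_blocks):
            x = block.forward(x, train=train)
            feats.append(x)
            if i < 4:
                x = self.pools[i].forward(x, train=train)
        return feats

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits at input resolution for an N x H x W x 3 float batch."""
        H, W = x.shape[1], x.shape[2]
        feats = self.encode(x, train=train)
        d = self.fc.forward(feats[4], train=train)
        for dec, skip in zip(self.decoders, (feats[3], feats[2], feats[1])):
            d = dec.forward(d, skip, train=train)
        if self.lcpp is not None:
            l = self.lcpp.forward(feats[4], train=train)
            self.lcpp_resize.out_hw = (d.shape[1], d.shape[2])
            l = self.lcpp_resize.forward(l, train=train)
            l = self.lcpp_proj.forward(l, train=train)
            h2 = np.concatenate([d, l], axis=-1)
        else:
            h2 = d
        h2 = self.head_mix.forward(h2, train=train)
        logits_s2 = self.head_logits.forward(h2, train=train)
        self._cache = {"stride2_hw": (logits_s2.shape[1], logits_s2.shape[2]),
                       "out_hw": (H, W)}
        return nn.bilinear_resize(logits_s2, (H, W))

    def logits_stride2(self, x: np.ndarray) -> np.ndarray:
        """Pre-upsample logits (stride-2 resolution), inference mode."""
        feats = self.encode(x, train=False)
        d = self.fc.forward(feats[4], train=False)
        for dec, skip in zip(self.decoders, (feats[3], feats[2], feats[1])):
            d = dec.forward(d, skip, train=False)
        if self.lcpp is not None:
            l = self.lcpp.forward(feats[4], train=False)
            self.lcpp_resize.out_hw = (d.shape[1], d.shape[2])
            l = self.lcpp_proj.forward(self.lcpp_resize.forward(l), train=False)
            h2 = np.concatenate([d, l], axis=-1)
        else:
            h2 = d
        return self.head_logits.forward(self.head_mix.forward(h2))

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        """Backprop from full-resolution logit gradients; returns input grads."""
        mix = self.config.mix_channels
        g = nn.bilinear_resize_grad(glogits.astype(nn.FLOAT), self._cache["stride2_hw"])
        g = self.head_logits.backward(g)
        g = self.head_mix.backward(g)
        if self.lcpp is not None:
            gd = np.ascontiguousarray(g[..., :mix])
            gl = np.ascontiguousarray(g[..., mix:])
            gl = self.lcpp_proj.backward(gl)
            gl = self.lcpp_resize.backward(gl)
            gf5_lcpp = self.lcpp.backward(gl)
        else:
            gd = g
            gf5_lcpp = None
        skip_grads: dict[int, np.ndarray] = {}
        for dec, idx in zip(reversed(self.decoders), (1, 2, 3)):
            gd, gskip = dec.backward(gd)
            skip_grads[idx] = gskip
        gf5 = self.fc.backward(gd)
        if gf5_lcpp is not None:
            gf5 = gf5 + gf5_lcpp
        g = gf5
        for i in range(4, -1, -1):
            if i in skip_grads:
                g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)
        return g

    # ----------------------------------------------------------------- predict
    def predict(self, image: np.ndarray) -> SegmentationOutput:
        """Segment one H x W x 3 uint8 image."""
        x = preprocess(image)[None]
        logits = self.forward_batch(x, train=False)[0]
        return SegmentationOutput(probabilities=nn.softmax(logits), logits=logits)


def preprocess(image: np.ndarray) -> np.ndarray:
    """uint8 RGB -> zero-centred float32 in [-0.5, 0.5]."""
    return (np.asarray(image, dtype=nn.FLOAT) / 255.0) - 0.5


def build_encoder(config: NetworkConfig, seed: int = 0) -> LCNet:
    """A network whose ``encode`` exposes every block output (spec surface)."""
    return LCNet(config, seed=seed)


def forward(image: np.ndarray, network: LCNet) -> SegmentationOutput:
    """Functional inference entry point."""
    return network.predict(image)
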