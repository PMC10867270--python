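"""The ridge-segmentation network.

An encoder-decoder convolutional network for binary (background / ridge)
semantic segmentation of aerial farmland imagery. Three ingredients target
the geometry of field ridges — long, thin, roughly axis-aligned strips:

* a five-block convolutional encoder whose first four block outputs are kept
  as skip connections;
* an atrous-spatial-pyramid-pooling (ASPP) bottleneck on the deepest feature
  map, widening the receptive field with parallel dilated convolutions;
* a decoder that at each of four stages upsamples 2x, fuses with the matching
  skip, refines with a convolutional block and then applies a *strip pooling*
  gate that aggregates context along whole rows and whole columns.

The network is fully convolutional: any input whose height and width are
divisible by 16 is accepted, and logits come back at full resolution.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["ModelConfig", "StripPool", "ASPP", "ASPNet",
           "receptive_field_offsets", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Hyper-parameters of the network.

    ``channel_schedule`` gives the output width of the five encoder blocks;
    when omitted it is derived from ``base_channels`` as (1, 2, 4, 8, 8) x
    base. ``aspp_out_channels`` defaults to the deepest encoder width.
    """

    in_channels: int = 3
    n_classes: int = 2
    base_channels: int = 64
    channel_schedule: tuple[int, ...] | None = None
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    aspp_out_channels: int | None = None
    upsample_mode: str = "bilinear"  # or "transposed"
    fusion_mode: str = "concat"      # or "add"
    seed: int = 0

    def __post_init__(self):
        if self.channel_schedule is None:
            b = self.base_channels
            self.channel_schedule = (b, 2 * b, 4 * b, 8 * b, 8 * b)
        self.channel_schedule = tuple(int(c) for c in self.channel_schedule)
        if len(self.channel_schedule) != 5:
            raise ValueError("channel_schedule must have exactly 5 entries")
        self.aspp_rates = tuple(int(r) for r in self.aspp_rates)
        if (len(self.aspp_rates) != 3 or min(self.aspp_rates) < 1
                or list(self.aspp_rates) != sorted(set(self.aspp_rates))):
            raise ValueError("aspp_rates must be 3 strictly increasing positive integers")
        if self.aspp_out_channels is None:
            self.aspp_out_channels = self.channel_schedule[-1]
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        if self.fusion_mode not in ("concat", "add"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


class StripPool(nn.Module):
    """Row/column strip-pooling attention gate.

    The input map is averaged along each row (giving an H x 1 profile) and
    along each column (1 x W), each profile is passed through a length-3
    one-dimensional convolution, the two profiles are broadcast back to
    H x W and summed pixel-wise, and a 1x1 convolution followed by a
    sigmoid turns the sum into a gate that multiplies the original input.
    Channel count is preserved throughout.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv_h = nn.Conv2d(channels, channels, (3, 1), rng, padding=(1, 0))
        self.conv_w = nn.Conv2d(channels, channels, (1, 3), rng, padding=(0, 1))
        self.conv_fuse = nn.Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"strip_pool expects {self.channels} channels, got {x.shape[1]}")
        pooled_h = self.conv_h(F.mean_axis(x, axis=3))   # (N,C,H,1)
        pooled_w = self.conv_w(F.mean_axis(x, axis=2))   # (N,C,1,W)
        fused = F.add(pooled_h, pooled_w)                # broadcast-expand to (N,C,H,W)
        gate = F.sigmoid(self.conv_fuse(fused))
        return F.mul(x, gate)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling bottleneck.

    Four parallel branches — one 1x1 convolution and three 3x3 convolutions
    dilated at the configured rates, all padding-preserving — are applied to
    the deepest encoder map, concatenated along channels, and projected by a
    1x1 convolution to ``out_channels``.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rates: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        self.rates = tuple(rates)
        branches = [nn.ConvBNReLU(in_channels, out_channels, rng, kernel_size=1)]
        for r in self.rates:
            branches.append(nn.ConvBNReLU(in_channels, out_channels, rng,
                                          kernel_size=3, dilation=r))
        self.branches = nn.ModuleList(branches)
        self.project = nn.ConvBNReLU(len(branches) * out_channels, out_channels,
                                     rng, kernel_size=1)

    def forward(self, x: Tensor) -> Tensor:
        outs = [b(x) for b in self.branches]
        return self.project(F.concat(outs, axis=1))


class _EncoderBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng, pool: bool):
        super().__init__()
        self.pool = pool
        self.conv1 = nn.ConvBNReLU(in_ch, out_ch, rng)
        self.conv2 = nn.ConvBNReLU(out_ch, out_ch, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.pool:
            x = F.max_pool2d(x)
        return self.conv2(self.conv1(x))


class _DecoderStage(nn.Module):
    """Upsample 2x, fuse with the skip, refine, strip-pool."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, cfg: ModelConfig, rng):
        super().__init__()
        self.fusion_mode = cfg.fusion_mode
        self.upsample_mode = cfg.upsample_mode
        if cfg.upsample_mode == "transposed":
            self.up = nn.ConvTranspose2x(in_ch, in_ch, rng)
        if cfg.fusion_mode == "add":
            self.match = nn.Conv2d(in_ch, skip_ch, 1, rng)
            fuse_in = skip_ch
        else:
            fuse_in = in_ch + skip_ch
        self.fuse = nn.ConvBNReLU(fuse_in, out_ch, rng)
        self.refine = nn.ConvBNReLU(out_ch, out_ch, rng)
        self.strip_pool = StripPool(out_ch, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        if self.upsample_mode == "transposed":
            x = self.up(x)
            if x.shape[2:] != skip.shape[2:]:
                raise ValueError(f"upsampled map {x.shape[2:]} does not match "
                                 f"skip {skip.shape[2:]}")
        else:
            x = F.upsample_bilinear(x, (skip.shape[2], skip.shape[3]))
        if self.fusion_mode == "add":
            x = F.add(self.match(x), skip)
        else:
            x = F.concat([x, skip], axis=1)
        return self.strip_pool(self.refine(self.fuse(x)))


class ASPNet(nn.Module):
    """Encoder-decoder ridge segmentation network (see module docstring)."""

    DIVISOR = 16  # four 2x downsamplings

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        cs = cfg.channel_schedule
        blocks = []
        in_ch = cfg.in_channels
        for i, out_ch in enumerate(cs):
            blocks.append(_EncoderBlock(in_ch, out_ch, rng, pool=i > 0))
            in_ch = out_ch
        self.encoder = nn.ModuleList(blocks)
        self.aspp = ASPP(cs[4], cfg.aspp_out_channels, cfg.aspp_rates, rng)
        stages = []
        in_ch = cfg.aspp_out_channels
        for i in (3, 2, 1, 0):  # deepest skip first
            stages.append(_DecoderStage(in_ch, cs[i], cs[i], cfg, rng))
            in_ch = cs[i]
        self.decoder = nn.ModuleList(stages)
        self.head = nn.Conv2d(cs[0], cfg.n_classes, 1, rng)

    # -- forward pieces ----------------------------------------------------
    def _check_size(self, h: int, w: int) -> None:
        if h % self.DIVISOR or w % self.DIVISOR:
            raise ValueError(
                f"input height and width must be divisible by {self.DIVISOR}; got {h}x{w}")

    def encoder_forward(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Run the five encoder blocks; return the four skips and the deepest map."""
        self._check_size(x.shape[2], x.shape[3])
        feats = []
        for block in self.encoder:
            x = block(x)
            feats.append(x)
        return feats[:4], feats[4]

    def decoder_forward(self, skips: list[Tensor], bottleneck: Tensor) -> Tensor:
        """Fuse the ASPP output with the skips, deepest first; emit logits."""
        if len(skips) != 4:
            raise ValueError(f"expected 4 skip maps, got {len(skips)}")
        x = bottleneck
        for stage, skip in zip(self.decoder, reversed(skips)):
            x = stage(x, skip)
        return self.head(x)

    def forward(self, x: Tensor) -> Tensor:
        skips, deepest = self.encoder_forward(x)
        return self.decoder_forward(skips, self.aspp(deepest))

    # -- inference ---------------------------------------------------------
    @staticmethod
    def _to_batch(img: np.ndarray) -> np.ndarray:
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
        x = img.astype(np.float32)
        if img.dtype == np.uint8:
            x /= 255.0
        return np.ascontiguousarray(x.transpose(2, 0, 1))[None]

    def predict_logits(self, img: np.ndarray) -> np.ndarray:
        """Class logits (K x H x W) for a single H x W x 3 image, eval mode."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(self._to_batch(img)))
        finally:
            if was_training:
                self.train()
        return out.data[0]

    def predict(self, img: np.ndarray) -> np.ndarray:
        """Segment one image: per-pixel argmax over the class logits.

        Ties resolve to label 0 (background) — the conservative choice for a
        detector that should not hallucinate ridges.
        """
        logits = self.predict_logits(img)
        return (logits[1] > logits[0]).astype(np.uint8)

    # -- persistence -------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        """Serialise weights plus the embedded :class:`ModelConfig` to one file."""
        arrays = self.state_dict()
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)


def load_checkpoint(path) -> ASPNet:
    """Rebuild an :class:`ASPNet` from a checkpoint written by ``save_checkpoint``."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    raw = arrays.pop("__config__")
    cfg = ModelConfig.from_dict(json.loads(bytes(raw).decode()))
    model = ASPNet(cfg)
    model.load_state_dict(arrays)
    return model


def receptive_field_offsets(conv: nn.Conv2d, size: int = 48,
                            eps: float = 1.0) -> set[tuple[int, int]]:
    """Finite-difference probe of a convolution's spatial footprint.

    Perturbs the centre pixel of a zero input and returns the set of
    (dy, dx) output offsets whose value changes — for a 3x3 convolution
    dilated at rate r this is exactly {-r, 0, +r} x {-r, 0, +r}.
    """
    cin = conv.weight.data.shape[1]
    c = size // 2
    base = np.zeros((1, cin, size, size), dtype=np.float64)
    pert = base.copy()
    pert[0, :, c, c] = eps
    w64 = nn.Tensor(conv.weight.data.astype(np.float64))
    out0 = F.conv2d(nn.Tensor(base), w64, None, conv.padding, conv.dilation).data
    out1 = F.conv2d(nn.Tensor(pert), w64, None, conv.padding, conv.dilation).data
    diff = np.abs(out1 - out0).max(axis=(0, 1))
    ys, xs = np.nonzero(diff)
    return {(int(y) - c, int(x) - c) for y, x in zip(ys, xs)}
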