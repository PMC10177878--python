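"""Multi-resolution backbone with deformable convolution and CBAM attention.

Parallel branches at strides 4/8/16(/32) exchange information after every
stage (HRNet-style); the final block of each branch uses deformable
convolution, whose per-position sampling offsets are predicted by a
zero-initialized convolution so training starts from the regular-convolution
limit.  Branch outputs are bilinearly upsampled to the highest resolution,
concatenated and fused by 1x1 convolution; stepwise average pooling then
yields a three-level feature pyramid P3/P4/P5 (strides 8/16/32), each gated
by channel-then-spatial attention.

Two built-in profiles: `full` (widths 18/36/72/144, 4 stages, reduction 16)
and `desk`, a CPU-sized analog (widths 8/16/32, 2 stages, reduction 4).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .grad import Tensor, concat, avg_pool2x2, grid_sample, upsample_bilinear

__all__ = ["BackboneConfig", "DeformConv2d", "ChannelAttention",
           "SpatialAttention", "CBAM", "HRBackbone", "FeaturePyramid"]


@dataclasses.dataclass
class BackboneConfig:
    widths: tuple = (8, 16, 32)
    stages: int = 2
    dcn: bool = True
    cbam: bool = True
    reduction_ratio: int = 4
    out_channels: int = 32

    @staticmethod
    def full() -> "BackboneConfig":
        return BackboneConfig(widths=(18, 36, 72, 144), stages=4,
                              reduction_ratio=16, out_channels=128)

    @staticmethod
    def desk() -> "BackboneConfig":
        return BackboneConfig()


@dataclasses.dataclass
class FeaturePyramid:
    """P3/P4/P5 feature maps at strides 8/16/32, common channel width.

    `fine` is the fused stride-4 map the pyramid is pooled from; the mask
    branch samples point-wise features from it.
    """
    P3: Tensor
    P4: Tensor
    P5: Tensor
    fine: Tensor | None = None
    strides: tuple = (8, 16, 32)

    def as_dict(self) -> dict:
        return {"P3": self.P3, "P4": self.P4, "P5": self.P5,
                "fine": self.fine}


class DeformConv2d(nn.Module):
    """3x3 deformable convolution: y(p0) = sum_l w(pl) F(p0 + pl + dp_l).

    Fractional sampling positions are resolved by bilinear interpolation;
    samples falling outside the map contribute zero.  The offset-predicting
    convolution is zero-initialized, so an untrained layer equals the
    regular convolution with the same kernel.
    """

    K = 3

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * 9))
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, 3, 3)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.offset_conv = nn.Conv2d(cin, 2 * 9, 3, rng=rng, zero_init=True)

    def forward(self, x: Tensor, offsets: Tensor | None = None) -> Tensor:
        N, C, H, W = x.data.shape
        if offsets is None:
            offsets = self.offset_conv(x)
        if offsets.data.shape != (N, 18, H, W):
            raise ValueError(
                f"offset shape {offsets.data.shape} != {(N, 18, H, W)}")
        P = H * W
        base_y, base_x = np.mgrid[0:H, 0:W]
        base_x = (base_x + 0.5).ravel()[None, :].repeat(N, axis=0)
        base_y = (base_y + 0.5).ravel()[None, :].repeat(N, axis=0)
        samples = []
        for kh in range(3):
            for kw in range(3):
                ell = kh * 3 + kw
                ox = offsets[:, 2 * ell, :, :].reshape(N, P)
                oy = offsets[:, 2 * ell + 1, :, :].reshape(N, P)
                px = base_x + (kw - 1)
                py = base_y + (kh - 1)
                samples.append(grid_sample(x, px, py, ox, oy))  # (N, C, P)
        stack = concat(samples, axis=1)                         # (N, 9C, P)
        # channel order of `stack` is l*C + c -> matches weight (F, kh, kw, C)
        wm = self.weight.transpose(0, 2, 3, 1).reshape(
            self.weight.shape[0], 9 * C)
        out = stack.transpose(0, 2, 1) @ wm.transpose(1, 0) + self.bias
        return out.transpose(0, 2, 1).reshape(N, -1, H, W)


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gate from parallel global average + max pooling
    through a shared two-layer MLP, fused by addition."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.data.shape
        flat = x.reshape(N, C, H * W)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        gate = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return gate.sigmoid()                 # (N, C) in (0, 1)


class SpatialAttention(nn.Module):
    """Per-pixel sigmoid gate from channel-wise average + max maps."""

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        self.conv = nn.Conv2d(2, 1, kernel, rng=rng or np.random.default_rng(0))

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()  # (N,1,H,W)


class CBAM(nn.Module):
    """Channel attention first, then spatial attention (sequential gating)."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(7, rng)

    def forward(self, x: Tensor) -> Tensor:
        N, C = x.data.shape[:2]
        mc = self.channel(x).reshape(N, C, 1, 1)
        x1 = x * mc
        ms = self.spatial(x1)
        return x1 * ms


class _BranchBlock(nn.Module):
    """Two 3x3 convolutions with ReLU; the second may be deformable."""

    def __init__(self, width: int, use_dcn: bool, rng: np.random.Generator):
        self.conv1 = nn.ConvNorm(width, width, 3, rng=rng)
        self.use_dcn = use_dcn
        if use_dcn:
            self.conv2 = DeformConv2d(width, width, rng=rng)
        else:
            self.conv2 = nn.Conv2d(width, width, 3, rng=rng)
        self.norm2 = nn.GroupNorm(width)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm2(self.conv2(self.conv1(x).relu())).relu()


class _Exchange(nn.Module):
    """Full cross-resolution information exchange between branches."""

    def __init__(self, widths: tuple, rng: np.random.Generator):
        self.widths = widths
        n = len(widths)
        self.down: dict = {}
        self.lateral: dict = {}
        mods = []
        for i in range(n):          # target branch
            for j in range(n):      # source branch
                if j < i:
                    chain = []
                    cin = widths[j]
                    for step in range(i - j):
                        cout = widths[i] if step == i - j - 1 else cin
                        chain.append(nn.ConvNorm(cin, cout, 3, stride=2, rng=rng))
                        cin = cout
                    self.down[(i, j)] = chain
                    mods.extend(chain)
                elif j > i:
                    lat = nn.Conv2d(widths[j], widths[i], 1, rng=rng)
                    self.lateral[(i, j)] = lat
                    mods.append(lat)
        self._mods = mods  # registered for parameter collection

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        n = len(feats)
        outs = []
        for i in range(n):
            acc = feats[i]
            for j in range(n):
                if j == i:
                    continue
                if j < i:
                    t = feats[j]
                    for conv in self.down[(i, j)]:
                        t = conv(t).relu()
                else:
                    t = self.lateral[(i, j)](feats[j])
                    H, W = feats[i].data.shape[2:]
                    t = upsample_bilinear(t, H, W)
                acc = acc + t
            outs.append(acc.relu())
        return outs


class HRBackbone(nn.Module):
    """The full feature extractor: stem -> parallel stages -> fused pyramid."""

    def __init__(self, config: BackboneConfig | None = None, seed: int = 0):
        cfg = config or BackboneConfig()
        self.config = cfg
        rng = np.random.default_rng(seed)
        w = cfg.widths
        self.stem1 = nn.ConvNorm(1, w[0], 3, stride=2, rng=rng)
        self.stem2 = nn.ConvNorm(w[0], w[0], 3, stride=2, rng=rng)
        self.transitions = [nn.ConvNorm(w[i], w[i + 1], 3, stride=2, rng=rng)
                            for i in range(len(w) - 1)]
        self.blocks = []
        self.exchanges = []
        for s in range(cfg.stages):
            is_last = s == cfg.stages - 1
            self.blocks.append([_BranchBlock(wi, cfg.dcn and is_last, rng)
                                for wi in w])
            self.exchanges.append(_Exchange(w, rng))
        self.fuse = nn.ConvNorm(sum(w), cfg.out_channels, 1, rng=rng)
        if cfg.cbam:
            self.cbams = [CBAM(cfg.out_channels, cfg.reduction_ratio, rng)
                          for _ in range(3)]
        else:
            self.cbams = []

    def forward(self, x: Tensor) -> FeaturePyramid:
        H = x.data.shape[2]
        if H % 32 or x.data.shape[3] % 32:
            raise ValueError(
                f"input side {x.data.shape[2:]} not divisible by 32; resize first")
        t = self.stem2(self.stem1(x).relu()).relu()
        feats = [t]
        for tr in self.transitions:
            feats.append(tr(feats[-1]).relu())
        for blocks, exchange in zip(self.blocks, self.exchanges):
            feats = [blk(f) for blk, f in zip(blocks, feats)]
            feats = exchange(feats)
        # fuse at the highest resolution (stride 4)
        Hh, Wh = feats[0].data.shape[2:]
        ups = [feats[0]] + [upsample_bilinear(f, Hh, Wh) for f in feats[1:]]
        fused = self.fuse(concat(ups, axis=1)).relu()
        p3 = avg_pool2x2(fused)
        p4 = avg_pool2x2(p3)
        p5 = avg_pool2x2(p4)
        if self.cbams:
            p3, p4, p5 = (cb(p) for cb, p in zip(self.cbams, (p3, p4, p5)))
        return FeaturePyramid(p3, p4, p5, fine=fused)
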