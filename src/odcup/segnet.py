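"""Segmentation generator: encoder with atrous spatial pyramid pooling,
high/low-level feature fusion, a boundary-regression branch and a
boundary-conditioned mask branch.

The boundary branch is three convolutions with channel widths (head, head, 1)
per structure — (256, 256, 1) in the full-width configuration — implemented
as a shared two-layer trunk with one 1-channel head per structure (disc, cup);
a fully duplicated per-structure variant is available via
``shared_boundary_trunk=False``.  The mask branch consumes the concatenation
of the shared features and the boundary prediction, so boundary evidence
conditions the mask directly.  Both outputs use per-channel sigmoids: disc
and cup are predicted as two non-exclusive labels because the cup is a subset
of the disc and a mutually-exclusive softmax could not express that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["SegOutputs", "ASPP", "Backbone", "build_backbone", "SegmentationNet", "BACKBONES"]


@dataclass
class SegOutputs:
    """Dense predictions for one batch, all spatially aligned with the input.

    ``mask_prob`` and ``boundary_pred`` are (N, 2, H, W) tensors in [0, 1]
    with channel 0 = disc, channel 1 = cup; ``shared_features`` is the fused
    feature map both branches read from.
    """

    mask_prob: nn.Tensor
    boundary_pred: nn.Tensor
    shared_features: nn.Tensor


#: named backbone configurations; `tiny` is the reduced-width desk-scale variant
BACKBONES = {
    "deeplab_like": dict(widths=(32, 64, 128), aspp_rates=(1, 6, 12, 18), head_width=256),
    "tiny": dict(widths=(8, 16, 24), aspp_rates=(1, 2, 4), head_width=16),
}


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling: parallel dilated 3×3 convolutions at the
    given rates (rate 1 degenerates to a 1×1 convolution), fused by 1×1."""

    def __init__(self, channels: int, rates=(1, 6, 12, 18), *, rng):
        self.rates = tuple(int(r) for r in rates)
        branches = []
        for r in self.rates:
            if r == 1:
                branches.append(nn.Conv2d(channels, channels, 1, rng=rng))
            else:
                branches.append(nn.Conv2d(channels, channels, 3, padding=r, dilation=r, rng=rng))
        self.branches = branches
        self.fuse = nn.Conv2d(channels * len(self.rates), channels, 1, rng=rng)

    def forward(self, x):
        feats = [b(x).relu() for b in self.branches]
        return self.fuse(nn.concat(feats, axis=1)).relu()


class Backbone(nn.Module):
    """Three stride-2 stages, ASPP on the deepest features, then fusion of the
    upsampled high-level context with the early low-level tap.  The fused
    ("shared") feature map sits at 1/2 input resolution."""

    stride = 8  # input dims must divide this

    def __init__(self, widths=(8, 16, 24), aspp_rates=(1, 2, 4), *, rng):
        w0, w1, w2 = widths
        self.stem = nn.Conv2d(3, w0, 3, stride=2, padding=1, rng=rng)  # low-level tap, /2
        self.stage2 = nn.Conv2d(w0, w1, 3, stride=2, padding=1, rng=rng)  # /4
        self.stage3 = nn.Conv2d(w1, w2, 3, stride=2, padding=1, rng=rng)  # /8
        self.aspp = ASPP(w2, aspp_rates, rng=rng)
        self.low_proj = nn.Conv2d(w0, w0, 1, rng=rng)
        self.fuse = nn.Conv2d(w2 + w0, w1, 3, padding=1, rng=rng)
        self.out_channels = w1

    def forward(self, x):
        low = self.stem(x).relu()
        mid = self.stage2(low).relu()
        high = self.aspp(self.stage3(mid).relu())
        up = nn.upsample_nearest(high, 4)
        fused = self.fuse(nn.concat([up, self.low_proj(low).relu()], axis=1)).relu()
        return fused  # /2 resolution


def build_backbone(name: str, **overrides) -> Backbone:
    """Instantiate a registered backbone; unknown names list the registry."""
    if name not in BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; registry: {sorted(BACKBONES)}")
    cfg = {**BACKBONES[name]}
    cfg.pop("head_width")
    cfg.update({k: v for k, v in overrides.items() if k in ("widths", "aspp_rates")})
    rng = overrides.get("rng", np.random.default_rng(0))
    return Backbone(cfg["widths"], cfg["aspp_rates"], rng=rng)


class _BoundaryBranch(nn.Module):
    """(head, head, 1)-channel convolution stack per structure."""

    def __init__(self, in_channels, head_width, shared_trunk=True, *, rng):
        self.shared_trunk = bool(shared_trunk)
        if self.shared_trunk:
            self.trunks = [self._trunk(in_channels, head_width, rng)]
        else:
            self.trunks = [self._trunk(in_channels, head_width, rng) for _ in range(2)]
        self.heads = [nn.Conv2d(head_width, 1, 1, rng=rng) for _ in range(2)]

    @staticmethod
    def _trunk(cin, width, rng):
        return nn.Sequential(
            nn.Conv2d(cin, width, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(width, width, 3, padding=1, rng=rng),
            nn.ReLU(),
        )

    def forward(self, feats):
        outs = []
        for i, head in enumerate(self.heads):
            trunk = self.trunks[0] if self.shared_trunk else self.trunks[i]
            outs.append(head(trunk(feats)))
        return nn.concat(outs, axis=1)  # logits, (N, 2, h, w)


class SegmentationNet(nn.Module):
    """Full generator: backbone → boundary branch → boundary-conditioned mask."""

    def __init__(self, backbone: str = "tiny", aspp_rates=None,
                 shared_boundary_trunk: bool = True, seed: int = 0):
        if backbone not in BACKBONES:
            raise KeyError(f"unknown backbone {backbone!r}; registry: {sorted(BACKBONES)}")
        cfg = BACKBONES[backbone]
        rng = np.random.default_rng(seed)
        rates = aspp_rates if aspp_rates is not None else cfg["aspp_rates"]
        self.backbone_name = backbone
        self.backbone = Backbone(cfg["widths"], rates, rng=rng)
        c = self.backbone.out_channels
        hw = cfg["head_width"]
        self.boundary_branch = _BoundaryBranch(c, hw, shared_boundary_trunk, rng=rng)
        self.mask_head = nn.Sequential(
            nn.Conv2d(c + 2, hw, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(hw, hw, 3, padding=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(hw, 2, 1, rng=rng),
        )

    def forward(self, x, zero_boundary: bool = False) -> SegOutputs:
        """Run the generator; ``zero_boundary`` ablates the boundary input of
        the mask branch (diagnostic only)."""
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        n, c, h, w = x.shape
        if h % Backbone.stride or w % Backbone.stride:
            raise ValueError(
                f"input dims ({h}, {w}) must be divisible by the backbone stride {Backbone.stride}"
            )
        feats = self.backbone(x)
        b_logits = self.boundary_branch(feats)
        b_prob_half = b_logits.sigmoid()
        b_in = b_prob_half * 0.0 if zero_boundary else b_prob_half
        m_logits = self.mask_head(nn.concat([feats, b_in], axis=1))
        mask_prob = nn.upsample_nearest(m_logits, 2).sigmoid()
        boundary_pred = nn.upsample_nearest(b_prob_half, 2)
        return SegOutputs(mask_prob=mask_prob, boundary_pred=boundary_pred, shared_features=feats)
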