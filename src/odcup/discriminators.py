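"""Patch discriminators for output-space adversarial adaptation.

Three discriminators share one architecture and differ only in their input:

* ``D_b+`` — boundary predictions, source vs. autoencoder-enhanced domain;
* ``D_b``  — boundary predictions, new-source (source ∪ enhanced) vs. target;
* ``D_m``  — mask probability maps, new-source vs. target.

The architecture is a fully-convolutional PatchGAN: five 4×4 convolutions at
stride 2 with channels 64/128/256/512/1, LeakyReLU (slope 0.2) after the
first four and a sigmoid after the last.  Same-padding makes the output a
(H/32, W/32) grid of per-patch real/fake probabilities — 16×16 for a 512-px
input — and each output unit sees a 94×94-pixel receptive field.

The module also provides analytic and empirical receptive-field calculators
used to verify that geometry.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn

logger = logging.getLogger(__name__)

__all__ = [
    "PatchDiscriminator",
    "build_discriminator",
    "receptive_field",
    "empirical_receptive_field",
    "DISC_CHANNELS",
    "DISC_KERNELS",
    "DISC_STRIDES",
]

DISC_CHANNELS = (64, 128, 256, 512, 1)
DISC_KERNELS = (4, 4, 4, 4, 4)
DISC_STRIDES = (2, 2, 2, 2, 2)


class PatchDiscriminator(nn.Module):
    """Five-layer 4×4/stride-2 PatchGAN head over dense prediction maps."""

    def __init__(self, in_channels: int, slope: float = 0.2, channels=DISC_CHANNELS,
                 *, rng: np.random.Generator):
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        self.in_channels = int(in_channels)
        self.slope = float(slope)
        chans = (self.in_channels, *channels)
        convs = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            convs.append(nn.Conv2d(cin, cout, 4, stride=2, padding=1, rng=rng))
        self.convs = convs

    def forward(self, x) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        for conv in self.convs[:-1]:
            x = conv(x).leaky_relu(self.slope)
        return self.convs[-1](x).sigmoid()

    @property
    def layer_spec(self) -> tuple[list[int], list[int]]:
        ks = [c.weight.shape[2] for c in self.convs]
        ss = [c.stride for c in self.convs]
        return ks, ss


def build_discriminator(in_channels: int, slope: float = 0.2, channels=DISC_CHANNELS,
                        seed: int = 0) -> PatchDiscriminator:
    """Construct a patch discriminator with seeded weight initialisation."""
    return PatchDiscriminator(in_channels, slope, channels, rng=np.random.default_rng(seed))


def receptive_field(kernels, strides) -> int:
    """Analytic receptive field of a stack of convolutions.

    r = 1 + Σ_i (k_i − 1) · Π_{j<i} s_j.  For the five-layer 4×4/stride-2
    stack this gives 1 + 3·(1+2+4+8+16) = 94.
    """
    kernels, strides = list(kernels), list(strides)
    if len(kernels) != len(strides):
        raise ValueError("kernels and strides must have equal length")
    if not kernels:
        raise ValueError("layer spec must be nonempty")
    r, jump = 1, 1
    for k, s in zip(kernels, strides):
        r += (k - 1) * jump
        jump *= s
    return r


def empirical_receptive_field(disc: PatchDiscriminator, input_size: int = 256) -> int:
    """Measured receptive field: extent of input pixels influencing one unit.

    Backpropagates from a central output unit of a forward pass on a
    ``input_size``-square input and measures the row extent of nonzero input
    gradient.  LeakyReLU/sigmoid gradients never vanish identically, so the
    nonzero-gradient support equals the geometric receptive field, clipped by
    the input extent (a warning is logged when clipping occurs).
    """
    ks, ss = disc.layer_spec
    analytic = receptive_field(ks, ss)
    x = nn.Tensor(
        np.random.default_rng(0).normal(size=(1, disc.in_channels, input_size, input_size)).astype(np.float32),
        requires_grad=True,
    )
    out = disc(x)
    h = out.shape[2]
    mask = np.zeros(out.shape, dtype=np.float32)
    mask[0, 0, h // 2, out.shape[3] // 2] = 1.0
    (out * nn.Tensor(mask)).sum().backward()
    hit = np.abs(x.grad[0]).sum(axis=(0, 2)) > 0
    rows = np.nonzero(hit)[0]
    extent = int(rows.max() - rows.min() + 1)
    if extent < analytic and (rows.min() == 0 or rows.max() == input_size - 1):
        logger.warning(
            "empirical receptive field clipped by input size %d (analytic %d)",
            input_size, analytic,
        )
    return extent
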