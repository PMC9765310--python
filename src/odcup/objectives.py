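"""Loss functions for the adversarial segmentation framework.

Supervised terms: multi-label cross-entropy on the mask probabilities (L_m)
and mean-squared error on the boundary regressions (L_b), both over the
labelled new source domain (source images plus their enhanced copies, which
share labels).  Adversarial terms: binary cross-entropy of each patch
discriminator's grid against the domain-label convention 1 = source/new
source, 0 = enhanced/target.  The generator objective is

    L = L_m + L_b + λ_adv · (L_adv_m + L_adv_b + L_adv_b+),

while each discriminator minimises its own real-vs-fake objective with the
generator frozen.

Every function accepts either numpy arrays (returning a float) or autograd
tensors (returning a differentiable scalar tensor).  Logarithm arguments are
clamped to [1e-7, 1 − 1e-7]; loss values quoted anywhere in this package
include that clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor

EPS = 1e-7

__all__ = [
    "EPS",
    "LossReport",
    "bce",
    "mask_loss",
    "boundary_loss",
    "disc_loss_b_plus",
    "adv_loss_b_plus",
    "disc_loss_b",
    "adv_loss_b",
    "disc_loss_m",
    "adv_loss_m",
    "total_loss",
]


def _wrap(x):
    """Return (tensor, was_tensor)."""
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _ret(t: Tensor, tensor_out: bool):
    return t if tensor_out else float(t.data)


def bce(p, label) -> float | Tensor:
    """Mean binary cross-entropy of a probability grid against a label.

    ``label`` may be a scalar domain label (0 or 1) or an array of per-element
    targets; probabilities at exactly 0/1 are epsilon-clamped.
    """
    pt, keep = _wrap(p)
    y = np.asarray(label, dtype=np.float64)
    pc = pt.clamp(EPS, 1.0 - EPS)
    loss = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log()).mean()
    return _ret(loss, keep)


def mask_loss(p_m, y_m) -> float | Tensor:
    """Multi-label cross-entropy over pixels and both structure channels."""
    pt, keep = _wrap(p_m)
    y = np.asarray(y_m, dtype=np.float64)
    if pt.shape != y.shape:
        raise ValueError(f"shape mismatch: {pt.shape} vs {y.shape}")
    return _ret(_wrap(bce(pt, y))[0], keep)


def boundary_loss(p_b, y_b) -> float | Tensor:
    """Mean-squared boundary regression error."""
    pt, keep = _wrap(p_b)
    y = np.asarray(y_b, dtype=np.float64)
    if pt.shape != y.shape:
        raise ValueError(f"shape mismatch: {pt.shape} vs {y.shape}")
    return _ret((pt - Tensor(y)).square().mean(), keep)


# -- adversarial terms -------------------------------------------------------
# Each takes the discriminator plus batches of dense predictions (N, 2, H, W)
# and applies the discriminator inside, per-batch-normalised.


def _domain_bce(disc, batch, label):
    bt, keep = _wrap(batch)
    if bt.shape[0] < 1:
        raise ValueError("empty prediction batch")
    out = disc(bt)
    return _wrap(bce(out, float(label)))[0], keep


def disc_loss_b_plus(disc, p_b_source, p_b_enhanced) -> float | Tensor:
    """Boundary discriminator objective, source (1) vs. enhanced (0)."""
    a, ka = _domain_bce(disc, p_b_source, 1)
    b, kb = _domain_bce(disc, p_b_enhanced, 0)
    return _ret(a + b, ka or kb)


def adv_loss_b_plus(disc, p_b_enhanced) -> float | Tensor:
    """Generator term driving enhanced-domain boundaries toward 'source'."""
    t, keep = _domain_bce(disc, p_b_enhanced, 1)
    return _ret(t, keep)


def disc_loss_b(disc, p_b_new_source, p_b_target) -> float | Tensor:
    """Boundary discriminator objective, new source (1) vs. target (0);
    the two batches are normalised independently."""
    a, ka = _domain_bce(disc, p_b_new_source, 1)
    b, kb = _domain_bce(disc, p_b_target, 0)
    return _ret(a + b, ka or kb)


def adv_loss_b(disc, p_b_target) -> float | Tensor:
    """Generator term driving target boundaries toward the new source."""
    t, keep = _domain_bce(disc, p_b_target, 1)
    return _ret(t, keep)


def disc_loss_m(disc, p_m_new_source, p_m_target) -> float | Tensor:
    """Mask discriminator objective, new source (1) vs. target (0)."""
    a, ka = _domain_bce(disc, p_m_new_source, 1)
    b, kb = _domain_bce(disc, p_m_target, 0)
    return _ret(a + b, ka or kb)


def adv_loss_m(disc, p_m_target) -> float | Tensor:
    """Generator term driving target masks toward the new source."""
    t, keep = _domain_bce(disc, p_m_target, 1)
    return _ret(t, keep)


@dataclass
class LossReport:
    """All generator-loss components of one iteration (adversarial components
    stored before λ weighting)."""

    l_m: float
    l_b: float
    l_adv_m: float
    l_adv_b: float
    l_adv_b_plus: float
    lambda_adv: float
    l_adv: float
    l_total: float


def total_loss(l_m, l_b, l_adv_m=0.0, l_adv_b=0.0, l_adv_b_plus=0.0,
               lambda_adv: float = 0.01) -> LossReport:
    """Combine components into the generator objective and report it.

    The report satisfies L_adv = L_adv_m + L_adv_b + L_adv_b+ and
    L_total = L_m + L_b + λ_adv·L_adv exactly.
    """
    vals = {
        "l_m": l_m, "l_b": l_b, "l_adv_m": l_adv_m,
        "l_adv_b": l_adv_b, "l_adv_b_plus": l_adv_b_plus,
    }
    out = {}
    for name, v in vals.items():
        f = float(v.data) if isinstance(v, Tensor) else float(v)
        if not np.isfinite(f):
            raise ValueError(f"non-finite loss component {name}: {f}")
        out[name] = f
    l_adv = out["l_adv_m"] + out["l_adv_b"] + out["l_adv_b_plus"]
    return LossReport(
        **out,
        lambda_adv=float(lambda_adv),
        l_adv=l_adv,
        l_total=out["l_m"] + out["l_b"] + float(lambda_adv) * l_adv,
    )
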