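"""Closed-form, hand-computed and composition oracles for every loss term."""

import math

import numpy as np
import pytest

from odcup import nn, objectives as obj
from odcup.discriminators import build_discriminator

LN2 = math.log(2.0)


class _ConstantDisc:
    """Stand-in discriminator returning a constant 4x4 patch grid."""

    def __init__(self, value):
        self.value = value

    def __call__(self, batch):
        n = batch.shape[0] if hasattr(batch, "shape") else len(batch)
        return nn.Tensor(np.full((n, 1, 4, 4), self.value))


class TestBce:
    def test_half_probability_is_ln2_for_both_labels(self):
        p = np.full((4, 4), 0.5)
        assert obj.bce(p, 1) == pytest.approx(LN2, abs=1e-12)
        assert obj.bce(p, 0) == pytest.approx(LN2, abs=1e-12)

    def test_confident_correct(self):
        assert obj.bce(np.full((2, 2), 0.9), 1) == pytest.approx(-math.log(0.9), abs=1e-9)

    def test_extreme_probabilities_clamped(self):
        val = obj.bce(np.array([[1.0]]), 0)
        assert np.isfinite(val)
        assert val == pytest.approx(-math.log(obj.EPS), rel=1e-3)


class TestMaskAndBoundaryLoss:
    def test_perfect_prediction_near_zero(self):
        y = (np.random.default_rng(0).random((2, 2, 3, 3)) > 0.5).astype(float)
        assert obj.mask_loss(np.clip(y, obj.EPS, 1 - obj.EPS), y) < 1e-5
        assert obj.boundary_loss(y, y) == 0.0

    def test_uninformative_prediction_is_ln2(self):
        y = np.array([[[[1.0, 0.0], [0.0, 1.0]]]])
        assert obj.mask_loss(np.full_like(y, 0.5), y) == pytest.approx(LN2, abs=1e-12)

    def test_hand_computed_mask_loss(self):
        """2x2x2 case computed by hand term by term."""
        p = np.array([[[[0.9, 0.1], [0.8, 0.6]], [[0.3, 0.7], [0.5, 0.2]]]])
        y = np.array([[[[1.0, 0.0], [1.0, 1.0]], [[0.0, 1.0], [0.0, 0.0]]]])
        manual = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert obj.mask_loss(p, y) == pytest.approx(manual, abs=1e-6)

    def test_constant_gap_boundary_loss(self):
        y = np.zeros((1, 2, 4, 4))
        assert obj.boundary_loss(np.full_like(y, 0.5), y) == pytest.approx(0.25)

    def test_hand_computed_boundary_loss(self):
        p = np.array([[0.2, 0.4], [0.9, 0.1]])
        y = np.array([[0.0, 0.5], [1.0, 0.0]])
        assert obj.boundary_loss(p, y) == pytest.approx(np.mean((p - y) ** 2))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            obj.mask_loss(np.zeros((1, 2, 3, 3)), np.zeros((1, 2, 4, 4)))


@pytest.mark.parametrize(
    "disc_fn,expected",
    [
        (obj.disc_loss_b_plus, 2 * LN2),
        (obj.disc_loss_b, 2 * LN2),
        (obj.disc_loss_m, 2 * LN2),
    ],
)
def test_uninformed_discriminator_losses(disc_fn, expected):
    batch = np.random.default_rng(0).random((2, 2, 8, 8))
    assert disc_fn(_ConstantDisc(0.5), batch, batch) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("adv_fn", [obj.adv_loss_b_plus, obj.adv_loss_b, obj.adv_loss_m])
def test_adversarial_losses_at_half_and_fooled(adv_fn):
    batch = np.random.default_rng(0).random((3, 2, 8, 8))
    assert adv_fn(_ConstantDisc(0.5), batch) == pytest.approx(LN2, abs=1e-9)
    assert adv_fn(_ConstantDisc(1 - 1e-9), batch) == pytest.approx(0.0, abs=1e-6)


class _SplitDisc:
    """Perfect discriminator: ~1 on the first batch it sees, ~0 afterwards."""

    def __init__(self):
        self.calls = 0

    def __call__(self, batch):
        self.calls += 1
        v = 1 - 1e-9 if self.calls == 1 else 1e-9
        return nn.Tensor(np.full((batch.shape[0], 1, 4, 4), v))


def test_perfect_split_discriminator_is_zero_loss():
    b = np.random.default_rng(1).random((2, 2, 8, 8))
    for fn in (obj.disc_loss_b_plus, obj.disc_loss_b, obj.disc_loss_m):
        assert fn(_SplitDisc(), b, b) == pytest.approx(0.0, abs=1e-6)


class TestCompositionOracle:
    """Each adversarial operation must equal a manual composition of `bce`
    over the discriminator's patch grids, using a real discriminator."""

    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(42)
        disc = build_discriminator(2, channels=(4, 8, 8, 8, 1), seed=7)
        a = rng.random((3, 2, 128, 128))  # grids are 4x4 patches
        b = rng.random((2, 2, 128, 128))
        return disc, a, b

    def manual(self, disc, batch, label):
        return obj.bce(disc(nn.Tensor(batch.astype(np.float32))).data, label)

    def test_disc_losses(self, setup):
        disc, a, b = setup
        for fn in (obj.disc_loss_b_plus, obj.disc_loss_b, obj.disc_loss_m):
            expected = self.manual(disc, a, 1) + self.manual(disc, b, 0)
            assert fn(disc, a, b) == pytest.approx(expected, abs=1e-6)

    def test_adv_losses(self, setup):
        disc, a, _ = setup
        expected = self.manual(disc, a, 1)
        for fn in (obj.adv_loss_b_plus, obj.adv_loss_b, obj.adv_loss_m):
            assert fn(disc, a) == pytest.approx(expected, abs=1e-6)

    def test_empty_batch_rejected(self, setup):
        disc, a, _ = setup
        with pytest.raises(ValueError):
            obj.adv_loss_b(disc, np.zeros((0, 2, 32, 32)))


class TestTotalLoss:
    def test_identities_hold_exactly(self):
        r = obj.total_loss(1.0, 2.0, 0.5, 0.25, 0.25, lambda_adv=0.01)
        assert r.l_adv == 1.0
        assert r.l_total == pytest.approx(3.01)
        assert r.l_total == r.l_m + r.l_b + r.lambda_adv * r.l_adv

    def test_zero_adversarial_terms(self):
        r = obj.total_loss(0.3, 0.2)
        assert r.l_total == pytest.approx(0.5)
        r = obj.total_loss(0.3, 0.2, 1.0, 1.0, 1.0, lambda_adv=0.0)
        assert r.l_total == pytest.approx(0.5)

    def test_nonfinite_component_named(self):
        with pytest.raises(ValueError, match="l_adv_b"):
            obj.total_loss(1.0, 1.0, 0.0, float("nan"), 0.0)


def test_gradient_step_moves_prediction_toward_target():
    """One-pixel finite-difference sanity: descending L_m moves p toward y."""
    w = nn.Parameter(np.array([[[[0.0]]]]))
    y = np.ones((1, 1, 1, 1))
    for _ in range(50):
        p = w.sigmoid()
        loss = obj.mask_loss(p, y)
        w.grad = None
        loss.backward()
        w.data = w.data - 0.5 * w.grad
    assert w.sigmoid().data.item() > 0.9
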