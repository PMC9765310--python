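"""Alternating adversarial training of the segmentation generator.

One iteration draws one source image, its enhanced sibling (when the
autoencoder is enabled) and one unlabelled target image, then

1. updates the generator by one Adam step on
   L = L_m + L_b + λ_adv·(L_adv_m + L_adv_b + L_adv_b+), with every
   discriminator frozen;
2. updates each enabled discriminator by one SGD step on its own
   real-vs-fake objective, with the generator frozen (predictions detached).

The enhanced domain is rebuilt once per epoch from the frozen autoencoder.
Boundary ground truth — which the mask annotations do not provide — is
synthesised per structure as the morphological gradient (mask XOR its 1-px
erosion) smoothed with a Gaussian of width ``boundary_sigma`` and rescaled to
peak 1, giving the soft regression target the boundary branch needs.

Ablations are pure configuration: ``use_cae`` (enhanced domain + its losses),
``use_bmal`` (the two new-source/target discriminators), ``use_db_plus``
(the source/enhanced boundary discriminator, which requires ``use_cae``).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter, map_coordinates, rotate as nd_rotate
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import nn, objectives
from .cae import ConvAutoencoder
from .discriminators import build_discriminator
from .segnet import SegmentationNet

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentationConfig",
    "TrainConfig",
    "boundary_ground_truth",
    "apply_augmentations",
    "DomainAdaptiveSegmenter",
    "train",
]


def boundary_ground_truth(mask: np.ndarray, sigma: float) -> np.ndarray:
    """Soft boundary target for a (H, W, 2) binary mask.

    Per channel: morphological gradient (mask XOR 1-px erosion, so a structure
    touching the image border contributes its border pixels), Gaussian-smoothed
    with ``sigma`` and rescaled to maximum 1.  ``sigma=0`` returns the hard
    edge.  An empty channel yields an all-zero map with a warning.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    mask = np.asarray(mask).astype(bool)
    out = np.zeros(mask.shape, dtype=np.float64)
    for ch in range(mask.shape[-1]):
        m = mask[..., ch]
        if not m.any():
            logger.warning("boundary_ground_truth: channel %d is empty", ch)
            continue
        edge = m ^ binary_erosion(m)
        soft = edge.astype(np.float64)
        if sigma > 0:
            soft = gaussian_filter(soft, sigma)
        peak = soft.max()
        if peak > 0:
            soft /= peak
        out[..., ch] = soft
    return out


@dataclass(frozen=True)
class AugmentationConfig:
    """Stochastic training-time augmentations.

    Geometric transforms (rotation, elastic) are applied identically to image
    and mask (nearest-neighbour for the mask); photometric ones (noise,
    contrast, erasure) touch only the image.
    """

    gaussian_noise: bool = False
    noise_sd: float = 0.01
    random_erasure: bool = False
    erasure_frac: float = 0.15
    rotation: bool = False
    rot_max_deg: float = 10.0
    rot_right_angles: bool = False
    contrast: bool = False
    contrast_jitter: float = 0.1
    elastic: bool = False
    elastic_alpha: float = 4.0
    elastic_sigma: float = 8.0

    @classmethod
    def none(cls):
        return cls()

    @classmethod
    def default_train(cls):
        return cls(gaussian_noise=True, rotation=True, contrast=True)


def apply_augmentations(image: np.ndarray, mask: np.ndarray,
                        config: AugmentationConfig, seed: int):
    """Jointly augment one (image, mask) pair; pure function of (inputs, seed).

    The mask stays binary with cup ⊆ disc after every transform.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float64).copy()
    msk = np.asarray(mask).astype(bool).copy()

    if config.rotation:
        if config.rot_right_angles:
            k = int(rng.integers(4))
            img = np.rot90(img, k, axes=(0, 1)).copy()
            msk = np.rot90(msk, k, axes=(0, 1)).copy()
        else:
            ang = float(rng.uniform(-config.rot_max_deg, config.rot_max_deg))
            img = nd_rotate(img, ang, axes=(1, 0), reshape=False, order=1, mode="nearest")
            msk = nd_rotate(msk.astype(np.uint8), ang, axes=(1, 0), reshape=False,
                            order=0, mode="constant") > 0

    if config.elastic:
        h, w = msk.shape[:2]
        disp = [
            gaussian_filter(rng.uniform(-1, 1, (h, w)), config.elastic_sigma) * config.elastic_alpha
            for _ in range(2)
        ]
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = [rr + disp[0], cc + disp[1]]
        img = np.stack(
            [map_coordinates(img[..., c], coords, order=1, mode="nearest") for c in range(img.shape[-1])],
            axis=-1,
        )
        msk = np.stack(
            [map_coordinates(msk[..., c].astype(np.uint8), coords, order=0, mode="constant")
             for c in range(msk.shape[-1])],
            axis=-1,
        ) > 0

    if config.contrast:
        factor = 1.0 + float(rng.uniform(-config.contrast_jitter, config.contrast_jitter))
        img = (img - 0.5) * factor + 0.5

    if config.gaussian_noise:
        img = img + rng.normal(0.0, config.noise_sd, img.shape)

    if config.random_erasure:
        h, w = img.shape[:2]
        eh = max(1, int(h * config.erasure_frac * rng.uniform(0.5, 1.0)))
        ew = max(1, int(w * config.erasure_frac * rng.uniform(0.5, 1.0)))
        r0 = int(rng.integers(0, h - eh + 1))
        c0 = int(rng.integers(0, w - ew + 1))
        img[r0 : r0 + eh, c0 : c0 + ew] = img.mean(axis=(0, 1))

    msk[..., 1] &= msk[..., 0]  # elastic nearest-sampling cannot break this, but guard anyway
    return np.clip(img, 0.0, 1.0), msk


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings and ablation toggles.

    Defaults follow the full-scale recipe (Adam 2.5e-5 for the generator, SGD
    1e-3 for the discriminators); desk-scale experiments override the rates
    and epoch budget.
    """

    seg_lr: float = 2.5e-5
    disc_lr: float = 1e-3
    lambda_adv: float = 0.01
    #: epochs of purely supervised generator updates before the adversarial
    #: terms engage.  Without a warm-up the all-blank boundary map is a
    #: degenerate equilibrium: both domains emit identical blank maps, the
    #: boundary discriminators sit at chance, and their gradient noise keeps
    #: the saturated boundary branch from ever learning the contour ridge.
    #: Discriminators train from the start; only the generator's λ is gated.
    adv_warmup_epochs: int = 5
    epochs: int = 20
    seed: int = 0
    use_cae: bool = True
    use_bmal: bool = True
    use_db_plus: bool = True
    backbone: str = "tiny"
    boundary_sigma: float = 3.0
    jitter_sd: float = 0.1
    cae_widths: tuple = (16, 24, 32)
    cae_latent: int = 8
    cae_epochs: int = 60
    cae_lr: float = 1e-3
    #: channel widths of the three patch discriminators; the default is the
    #: full-width stack, desk-scale runs may narrow it (geometry is unchanged)
    disc_channels: tuple = (64, 128, 256, 512, 1)
    augmentations: AugmentationConfig = field(default_factory=AugmentationConfig.default_train)

    def validate(self) -> None:
        if self.seg_lr <= 0 or self.disc_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.use_db_plus and not self.use_cae:
            raise ValueError("use_db_plus requires use_cae: the source/enhanced "
                             "discriminator needs the enhanced domain to exist")


class DomainAdaptiveSegmenter(BaseEstimator):
    """Disc/cup segmenter with autoencoder augmentation and adversarial
    domain adaptation, presented as a scikit-learn estimator.

    ``fit(X, y, X_target=...)`` trains on labelled source images plus
    unlabelled target images; ``predict`` returns binary (N, H, W, 2) masks
    with the cup clipped to the disc, ``predict_proba`` the raw per-channel
    probabilities.  All per-iteration loss components are kept in ``log_``.
    """

    def __init__(self, seg_lr=2.5e-5, disc_lr=1e-3, lambda_adv=0.01,
                 adv_warmup_epochs=5, epochs=20,
                 seed=0, use_cae=True, use_bmal=True, use_db_plus=True,
                 backbone="tiny", boundary_sigma=3.0, jitter_sd=0.1,
                 cae_widths=(16, 24, 32), cae_latent=8, cae_epochs=60, cae_lr=1e-3,
                 disc_channels=(64, 128, 256, 512, 1), augmentations=None):
        self.seg_lr = seg_lr
        self.disc_lr = disc_lr
        self.lambda_adv = lambda_adv
        self.adv_warmup_epochs = adv_warmup_epochs
        self.epochs = epochs
        self.seed = seed
        self.use_cae = use_cae
        self.use_bmal = use_bmal
        self.use_db_plus = use_db_plus
        self.backbone = backbone
        self.boundary_sigma = boundary_sigma
        self.jitter_sd = jitter_sd
        self.cae_widths = cae_widths
        self.cae_latent = cae_latent
        self.cae_epochs = cae_epochs
        self.cae_lr = cae_lr
        self.disc_channels = disc_channels
        self.augmentations = augmentations

    # -- config plumbing -----------------------------------------------------
    def _config(self) -> TrainConfig:
        aug = self.augmentations if self.augmentations is not None else AugmentationConfig.default_train()
        cfg = TrainConfig(
            seg_lr=self.seg_lr, disc_lr=self.disc_lr, lambda_adv=self.lambda_adv,
            adv_warmup_epochs=self.adv_warmup_epochs,
            epochs=self.epochs, seed=self.seed, use_cae=self.use_cae,
            use_bmal=self.use_bmal, use_db_plus=self.use_db_plus,
            backbone=self.backbone, boundary_sigma=self.boundary_sigma,
            jitter_sd=self.jitter_sd, cae_widths=tuple(self.cae_widths),
            cae_latent=self.cae_latent, cae_epochs=self.cae_epochs,
            cae_lr=self.cae_lr, disc_channels=tuple(self.disc_channels),
            augmentations=aug,
        )
        cfg.validate()
        return cfg

    # -- training ------------------------------------------------------------
    def fit(self, X, y, X_target=None):
        cfg = self._config()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(bool)
        if X.ndim != 4 or y.shape[:3] != X.shape[:3]:
            raise ValueError("X must be (N, H, W, 3) with aligned (N, H, W, 2) masks")
        if cfg.use_bmal:
            if X_target is None or len(X_target) == 0:
                raise ValueError("use_bmal requires a nonempty unlabelled target set")
            X_target = np.asarray(X_target, dtype=np.float64)

        ss = np.random.SeedSequence(cfg.seed)
        (s_seg, s_dbp, s_db, s_dm, s_cae, s_sample, s_aug, s_jit, s_tgt) = [
            int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(9)
        ]

        self.seg_ = SegmentationNet(cfg.backbone, seed=s_seg)
        self.discs_ = {}
        if cfg.use_db_plus:
            self.discs_["d_b_plus"] = build_discriminator(2, channels=cfg.disc_channels, seed=s_dbp)
        if cfg.use_bmal:
            self.discs_["d_b"] = build_discriminator(2, channels=cfg.disc_channels, seed=s_db)
            self.discs_["d_m"] = build_discriminator(2, channels=cfg.disc_channels, seed=s_dm)

        self.cae_ = None
        if cfg.use_cae:
            self.cae_ = ConvAutoencoder(
                widths=cfg.cae_widths, latent_channels=cfg.cae_latent,
                epochs=cfg.cae_epochs, lr=cfg.cae_lr, jitter_sd=cfg.jitter_sd,
                seed=s_cae,
            ).fit(X)

        seg_opt = nn.Adam(self.seg_.parameters(), lr=cfg.seg_lr)
        disc_opts = {k: nn.SGD(d.parameters(), lr=cfg.disc_lr, momentum=0.9)
                     for k, d in self.discs_.items()}

        sample_rng = np.random.default_rng(s_sample)
        aug_rng = np.random.default_rng(s_aug)
        jitter_rng = np.random.default_rng(s_jit)
        # target indices come from their own stream so that disabling the
        # adversarial branch does not perturb the supervised sampling sequence
        target_rng = np.random.default_rng(s_tgt)

        n = X.shape[0]
        rows = []
        last_good = self._snapshot()
        diverged = False
        for epoch in range(cfg.epochs):
            enhanced = None
            if cfg.use_cae:
                z = self.cae_.encode(X)
                if cfg.jitter_sd > 0:
                    z = z + jitter_rng.normal(0.0, cfg.jitter_sd, z.shape).astype(z.dtype)
                enhanced = self.cae_.decode(z)
            order = sample_rng.permutation(n)
            for it, i in enumerate(order):
                img_s, msk_s = apply_augmentations(
                    X[i], y[i], cfg.augmentations, int(aug_rng.integers(2**31)))
                batch = {"src": (img_s, msk_s)}
                if cfg.use_cae:
                    img_e, msk_e = apply_augmentations(
                        enhanced[i], y[i], cfg.augmentations, int(aug_rng.integers(2**31)))
                    batch["enh"] = (img_e, msk_e)
                if cfg.use_bmal:
                    j = int(target_rng.integers(len(X_target)))
                    # target images pass through the same augmentation
                    # pipeline, so the discriminators cannot separate the
                    # domains on augmentation artefacts alone
                    img_t, _ = apply_augmentations(
                        X_target[j], np.zeros((*X_target[j].shape[:2], 2), dtype=bool),
                        cfg.augmentations, int(target_rng.integers(2**31)))
                    batch["tgt"] = (img_t, None)

                lam = cfg.lambda_adv if epoch >= cfg.adv_warmup_epochs else 0.0
                row = self._step(cfg, batch, seg_opt, disc_opts, lam)
                row.update(epoch=epoch, iteration=epoch * n + it)
                rows.append(row)
                if not np.isfinite(row["l_total"]):
                    logger.warning("training diverged at epoch %d; restoring last good checkpoint", epoch)
                    self._restore(last_good)
                    diverged = True
                    break
            if diverged:
                break
            last_good = self._snapshot()

        self.log_ = pd.DataFrame(rows)
        self.config_ = cfg
        return self

    def _step(self, cfg, batch, seg_opt, disc_opts, lam):
        """One generator step then one step per discriminator; ``lam`` is the
        effective adversarial weight (zero during warm-up)."""
        to_t = lambda img: nn.Tensor(np.transpose(img, (2, 0, 1))[None].astype(np.float32))
        outs = {k: self.seg_(to_t(img)) for k, (img, _) in batch.items()}

        # --- generator step (discriminators frozen) ---
        l_m = l_b = nn.Tensor(np.float64(0.0))
        n_lab = 0
        for k in ("src", "enh"):
            if k not in batch:
                continue
            _, msk = batch[k]
            yb = boundary_ground_truth(msk, cfg.boundary_sigma)
            y_m = np.transpose(msk, (2, 0, 1))[None].astype(np.float64)
            y_b = np.transpose(yb, (2, 0, 1))[None]
            l_m = l_m + objectives.mask_loss(outs[k].mask_prob, y_m)
            l_b = l_b + objectives.boundary_loss(outs[k].boundary_pred, y_b)
            n_lab += 1
        l_m = l_m / n_lab
        l_b = l_b / n_lab

        adv_bp = adv_b = adv_m = None
        total = l_m + l_b
        if cfg.use_db_plus:
            adv_bp = objectives.adv_loss_b_plus(self.discs_["d_b_plus"], outs["enh"].boundary_pred)
        if cfg.use_bmal:
            adv_b = objectives.adv_loss_b(self.discs_["d_b"], outs["tgt"].boundary_pred)
            adv_m = objectives.adv_loss_m(self.discs_["d_m"], outs["tgt"].mask_prob)
        adv_terms = [t for t in (adv_m, adv_b, adv_bp) if t is not None]
        if adv_terms:
            adv_sum = adv_terms[0]
            for t in adv_terms[1:]:
                adv_sum = adv_sum + t
            total = total + lam * adv_sum

        seg_opt.zero_grad()
        for d in self.discs_.values():
            d.zero_grad()
        total.backward()
        seg_opt.step()

        report = objectives.total_loss(
            l_m, l_b,
            l_adv_m=adv_m.item() if adv_m is not None else 0.0,
            l_adv_b=adv_b.item() if adv_b is not None else 0.0,
            l_adv_b_plus=adv_bp.item() if adv_bp is not None else 0.0,
            lambda_adv=lam,
        )
        row = asdict(report)

        # --- discriminator steps (generator frozen: detached predictions) ---
        det = {k: dict(b=o.boundary_pred.detach(), m=o.mask_prob.detach()) for k, o in outs.items()}
        d_losses = {"l_d_b_plus": np.nan, "l_d_b": np.nan, "l_d_m": np.nan}
        if cfg.use_db_plus:
            d_losses["l_d_b_plus"] = self._disc_step(
                disc_opts["d_b_plus"],
                lambda: objectives.disc_loss_b_plus(self.discs_["d_b_plus"], det["src"]["b"], det["enh"]["b"]))
        if cfg.use_bmal:
            new_src_b = nn.concat([det[k]["b"] for k in ("src", "enh") if k in det], axis=0)
            new_src_m = nn.concat([det[k]["m"] for k in ("src", "enh") if k in det], axis=0)
            d_losses["l_d_b"] = self._disc_step(
                disc_opts["d_b"],
                lambda: objectives.disc_loss_b(self.discs_["d_b"], new_src_b, det["tgt"]["b"]))
            d_losses["l_d_m"] = self._disc_step(
                disc_opts["d_m"],
                lambda: objectives.disc_loss_m(self.discs_["d_m"], new_src_m, det["tgt"]["m"]))
        row.update(d_losses)
        return row

    @staticmethod
    def _disc_step(opt, loss_fn):
        opt.zero_grad()
        loss = loss_fn()
        loss.backward()
        opt.step()
        return loss.item()

    # -- checkpointing -------------------------------------------------------
    def _snapshot(self):
        snap = {"seg": self.seg_.state_dict()}
        for k, d in self.discs_.items():
            snap[k] = d.state_dict()
        return snap

    def _restore(self, snap):
        self.seg_.load_state_dict(snap["seg"])
        for k, d in self.discs_.items():
            d.load_state_dict(snap[k])

    def save(self, path):
        """Serialise generator, discriminators and autoencoder to one .npz."""
        self._require_fitted()
        out = {f"seg.{k}": v for k, v in self.seg_.state_dict().items()}
        for name, d in self.discs_.items():
            out.update({f"{name}.{k}": v for k, v in d.state_dict().items()})
        if self.cae_ is not None:
            out.update({f"cae.{k}": v for k, v in self.cae_.model_.state_dict().items()})
        np.savez(path, **out)

    def load(self, path):
        """Restore a checkpoint produced by :meth:`save` into a configured
        (possibly unfitted) estimator."""
        cfg = self._config()
        with np.load(path) as f:
            groups: dict[str, dict] = {}
            for key in f.files:
                head, rest = key.split(".", 1)
                groups.setdefault(head, {})[rest] = f[key]
        self.seg_ = SegmentationNet(cfg.backbone, seed=0)
        self.seg_.load_state_dict(groups["seg"])
        self.discs_ = {}
        for name in ("d_b_plus", "d_b", "d_m"):
            if name in groups:
                self.discs_[name] = build_discriminator(2, channels=cfg.disc_channels, seed=0)
                self.discs_[name].load_state_dict(groups[name])
        self.cae_ = None
        if "cae" in groups:
            from .cae import _CAEModel

            cae = ConvAutoencoder(widths=cfg.cae_widths, latent_channels=cfg.cae_latent,
                                  jitter_sd=cfg.jitter_sd, seed=0)
            cae.model_ = _CAEModel(tuple(cfg.cae_widths), cfg.cae_latent,
                                   rng=np.random.default_rng(0))
            cae.model_.load_state_dict(groups["cae"])
            self.cae_ = cae
        self.config_ = cfg
        return self

    # -- inference -----------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel disc/cup probabilities, shape (N, H, W, 2)."""
        self._require_fitted()
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[None]
        out = []
        for i in range(X.shape[0]):
            xb = nn.Tensor(np.transpose(X[i], (2, 0, 1))[None].astype(np.float32))
            probs = self.seg_(xb).mask_prob.data[0]
            out.append(np.transpose(probs, (1, 2, 0)))
        return np.asarray(out, dtype=np.float64)

    def predict(self, X) -> np.ndarray:
        """Binary (N, H, W, 2) masks, cup clipped into the disc."""
        probs = self.predict_proba(X)
        masks = probs >= 0.5
        masks[..., 1] &= masks[..., 0]
        return masks

    def score(self, X, y) -> float:
        """Mean disc Dice over a labelled set (sklearn scorer convention)."""
        from .metrics import dsc

        preds = self.predict(X)
        y = np.asarray(y).astype(bool)
        return float(np.mean([dsc(preds[i, ..., 0], y[i, ..., 0]) for i in range(len(preds))]))

    def _require_fitted(self):
        if not hasattr(self, "seg_"):
            raise NotFittedError("DomainAdaptiveSegmenter is not fitted")


def train(config: TrainConfig, source, target):
    """Functional wrapper over :class:`DomainAdaptiveSegmenter`.

    ``source`` is a list of (image, mask) pairs, ``target`` a list of images
    (or (image, _) pairs).  Returns (fitted estimator, per-iteration loss log).
    """
    config.validate()
    est = DomainAdaptiveSegmenter(**{
        k: getattr(config, k) for k in (
            "seg_lr", "disc_lr", "lambda_adv", "epochs", "seed", "use_cae",
            "use_bmal", "use_db_plus", "adv_warmup_epochs",
            "backbone", "boundary_sigma", "jitter_sd",
            "cae_widths", "cae_latent", "cae_epochs", "cae_lr", "disc_channels",
            "augmentations",
        )
    })
    X = np.stack([img for img, _ in source])
    y = np.stack([msk for _, msk in source])
    Xt = None
    if target:
        Xt = np.stack([t[0] if isinstance(t, tuple) else t for t in target])
    est.fit(X, y, X_target=Xt)
    return est, est.log_
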