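"""Convolutional-autoencoder source-domain augmentation.

A symmetric autoencoder — four stride-2 encoder convolutions with widths
(32, 64, 128, latent) mirrored by transposed convolutions and a final sigmoid
— is pretrained to reconstruct the labelled source images and then frozen.
Because the bottleneck is lossy, reconstructions keep the anatomy (disc, cup,
large vessels) but blur fine detail; passing each source image through the
frozen model therefore yields an "enhanced" sibling that shares the source
label while differing photometrically.  Optional Gaussian jitter on the
latent code adds further diversity.  The union of the source set and its 1:1
enhanced copies forms the new source domain used by the adversarial trainer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from . import nn

logger = logging.getLogger(__name__)

__all__ = ["ConvAutoencoder", "EnhancedDataset", "reconstruction_loss", "augment_domain"]

DOWNSCALE = 16  # four stride-2 stages


def _to_nchw(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[None]
    return np.transpose(X, (0, 3, 1, 2))


def _to_nhwc(X: np.ndarray) -> np.ndarray:
    return np.transpose(X, (0, 2, 3, 1))


class _CAEModel(nn.Module):
    def __init__(self, widths, latent_channels, *, rng):
        w0, w1, w2 = widths
        lc = latent_channels
        self.enc = nn.Sequential(
            nn.Conv2d(3, w0, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.Conv2d(w0, w1, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.Conv2d(w1, w2, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.Conv2d(w2, lc, 3, stride=2, padding=1, rng=rng),
        )
        self.dec = nn.Sequential(
            nn.ConvTranspose2d(lc, w2, 4, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.ConvTranspose2d(w2, w1, 4, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.ConvTranspose2d(w1, w0, 4, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.ConvTranspose2d(w0, 3, 4, stride=2, padding=1, rng=rng), nn.Sigmoid(),
        )

    def forward(self, x):
        return self.dec(self.enc(x))


def reconstruction_loss(x: np.ndarray, x_plus: np.ndarray, reduction: str = "mean") -> float:
    """Squared-L2 reconstruction error between an image and its decoding.

    ``reduction='mean'`` (default) normalises by element count so the loss is
    size-invariant; ``'sum'`` gives the raw squared norm.
    """
    x = np.asarray(x, dtype=np.float64)
    x_plus = np.asarray(x_plus, dtype=np.float64)
    if x.shape != x_plus.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_plus.shape}")
    sq = (x - x_plus) ** 2
    return float(sq.mean() if reduction == "mean" else sq.sum())


class ConvAutoencoder(BaseEstimator, TransformerMixin):
    """Frozen-bottleneck autoencoder augmenter with a scikit-learn surface.

    Parameters
    ----------
    widths : encoder stage widths (the decoder mirrors them).
    latent_channels : bottleneck channels; latent spatial dims are input/16.
    epochs, lr, batch_size, patience : pretraining budget (Adam, early stop
        when the epoch loss has not improved for ``patience`` epochs).
    jitter_sd : SD of Gaussian noise added to latent codes in ``transform``.
    seed : controls init, batching and jitter.
    """

    def __init__(self, widths=(32, 64, 128), latent_channels=16, epochs=200,
                 lr=1e-3, batch_size=4, patience=20, jitter_sd=0.1, seed=0):
        self.widths = widths
        self.latent_channels = latent_channels
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.patience = patience
        self.jitter_sd = jitter_sd
        self.seed = seed

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y=None):
        """Pretrain on source images X of shape (N, H, W, 3), values in [0,1]."""
        Xn = _to_nchw(X)
        self._check_dims(Xn)
        rng = np.random.default_rng(self.seed)
        self.model_ = _CAEModel(self.widths, self.latent_channels, rng=rng)
        opt = nn.Adam(self.model_.parameters(), lr=self.lr)
        n = Xn.shape[0]
        self.history_ = []
        best, since_best = np.inf, 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = nn.Tensor(Xn[idx])
                out = self.model_(xb)
                loss = (out - xb).square().mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += loss.item() * len(idx)
            ep_loss /= n
            self.history_.append(ep_loss)
            if ep_loss < best - 1e-6:
                best, since_best = ep_loss, 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        return self

    def transform(self, X, jitter_sd: float | None = None) -> np.ndarray:
        """Map images to their enhanced siblings via the frozen bottleneck."""
        z = self.encode(X)
        sd = self.jitter_sd if jitter_sd is None else jitter_sd
        if sd > 0:
            rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 1]).generate_state(1)[0])
            z = z + rng.normal(0.0, sd, z.shape).astype(z.dtype)
        return self.decode(z)

    # -- encoder/decoder -----------------------------------------------------
    def encode(self, X) -> np.ndarray:
        """Latent codes of shape (N, latent_channels, H/16, W/16)."""
        self._require_fitted()
        Xn = _to_nchw(X)
        self._check_dims(Xn)
        return self.model_.enc(nn.Tensor(Xn)).data.copy()

    def decode(self, z) -> np.ndarray:
        """Decode latent codes back to (N, H, W, 3) images in [0, 1]."""
        self._require_fitted()
        out = self.model_.dec(nn.Tensor(np.asarray(z, dtype=np.float32)))
        return _to_nhwc(out.data).astype(np.float64)

    def reconstruct(self, X) -> np.ndarray:
        return self.decode(self.encode(X))

    # -- helpers -------------------------------------------------------------
    @staticmethod
    def _check_dims(Xn):
        h, w = Xn.shape[2], Xn.shape[3]
        if h % DOWNSCALE or w % DOWNSCALE:
            raise ValueError(
                f"image dims ({h}, {w}) must be divisible by {DOWNSCALE} "
                f"(four stride-2 encoder stages)"
            )

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("ConvAutoencoder must be fitted (or loaded) first")

    def save(self, path):
        self._require_fitted()
        self.model_.save(path)

    def load(self, path):
        if not hasattr(self, "model_"):
            self.model_ = _CAEModel(self.widths, self.latent_channels,
                                    rng=np.random.default_rng(self.seed))
        self.model_.load(path)
        return self


@dataclass
class EnhancedDataset:
    """1:1 enhanced copies of a source set; labels are shared by index."""

    pairs: list  # (enhanced image, mask, source index)

    def __len__(self):
        return len(self.pairs)


def augment_domain(source, cae: ConvAutoencoder, jitter_sd: float | None = None) -> EnhancedDataset:
    """Build the enhanced domain from labelled source pairs.

    ``source`` is a list of (image, mask); the result has exactly one enhanced
    image per source image, carrying the source mask unchanged.  An unfitted
    autoencoder logs a warning and is fitted on the fly with its configured
    budget.
    """
    if not hasattr(cae, "model_"):
        logger.warning("augment_domain called with an unfitted autoencoder; fitting on the source set")
        cae.fit(np.stack([img for img, _ in source]))
    X = np.stack([img for img, _ in source])
    enhanced = cae.transform(X, jitter_sd=jitter_sd)
    return EnhancedDataset(
        pairs=[(enhanced[i], source[i][1], i) for i in range(len(source))]
    )
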