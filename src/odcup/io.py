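"""Dataset I/O in lossless PNG with REFUGE-style label encoding.

Label masks are 8-bit grayscale PNGs with exactly three values: 0 = cup,
128 = disc rim (disc minus cup), 255 = background.  In memory a mask is a
(H, W, 2) boolean array, channel 0 = disc (cup included), channel 1 = cup, so
cup ⊆ disc holds by construction of the decoding (disc = value ≤ 128,
cup = value == 0).
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "DatasetManifest",
    "load_image_dir",
    "write_run_manifest",
]

_ALLOWED = {0, 128, 255}


def read_mask(path) -> np.ndarray:
    """Decode a label PNG to a (H, W, 2) boolean mask (disc, cup)."""
    arr = np.asarray(Image.open(path).convert("L"))
    values = set(np.unique(arr).tolist())
    bad = values - _ALLOWED
    if bad:
        raise ValueError(
            f"{path}: unexpected mask values {sorted(bad)}; expected subset of {sorted(_ALLOWED)}"
        )
    disc = arr <= 128
    cup = arr == 0
    return np.stack([disc, cup], axis=-1)


def write_mask(mask: np.ndarray, path) -> None:
    """Encode a (H, W, 2) boolean mask to the 0/128/255 convention."""
    mask = np.asarray(mask).astype(bool)
    disc, cup = mask[..., 0], mask[..., 1]
    if np.any(cup & ~disc):
        raise ValueError("cup channel must be a subset of the disc channel")
    out = np.full(disc.shape, 255, dtype=np.uint8)
    out[disc] = 128
    out[cup] = 0
    Image.fromarray(out, mode="L").save(path)


def read_image(path) -> np.ndarray:
    """8-bit RGB PNG -> (H, W, 3) float in [0, 1]."""
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0


def write_image(img: np.ndarray, path) -> None:
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="RGB").save(path)


def write_prob_map(prob: np.ndarray, path) -> None:
    """Store one probability channel losslessly as 16-bit grayscale PNG."""
    arr = np.clip(np.asarray(prob), 0.0, 1.0)
    Image.fromarray((arr * 65535.0 + 0.5).astype(np.uint16)).save(path)


def read_prob_map(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.float64) / 65535.0


@dataclass
class DatasetManifest:
    """Accounting of one dataset directory: which files belong to which domain
    and whether a mask exists (unlabelled target entries have none)."""

    root: str
    split: str
    entries: list  # (image file, mask file or None, domain tag, label or None)

    def validate(self) -> None:
        root = Path(self.root)
        for img, msk, domain, _ in self.entries:
            if not (root / img).exists():
                raise FileNotFoundError(root / img)
            if msk is not None and not (root / msk).exists():
                raise FileNotFoundError(root / msk)
            if domain == "target" and self.split == "train" and msk is not None:
                raise ValueError(f"target-domain training entry {img} must not carry a mask")


def load_image_dir(root) -> list[tuple[np.ndarray, np.ndarray | None, str]]:
    """Read an ``images/`` (+ optional ``masks/``) directory tree.

    Returns (image, mask-or-None, stem) sorted by filename.
    """
    root = Path(root)
    img_dir = root / "images"
    msk_dir = root / "masks"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"{img_dir} does not exist")
    out = []
    for p in sorted(img_dir.glob("*.png")):
        mask = None
        mp = msk_dir / p.name
        if mp.exists():
            mask = read_mask(mp)
        out.append((read_image(p), mask, p.stem))
    if not out:
        raise FileNotFoundError(f"no PNG images under {img_dir}")
    return out


def write_run_manifest(out_dir, config: dict, seed: int) -> Path:
    """Drop a reproducibility manifest (config hash, seed, versions) next to
    the outputs of a pipeline command."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
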