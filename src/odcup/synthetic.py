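"""Seeded synthetic fundus-image generator with ground-truth disc/cup masks.

Emulates the geometry that matters for optic-disc/optic-cup segmentation: a
bright elliptical disc on a reddish retinal background, a still-brighter cup
ellipse nested inside (and generally off-centre), and dark curvilinear vessels
entering the disc.  A configurable source→target shift in brightness, contrast
and vessel density stands in for images acquired on different scanners, which
is the domain-adaptation setting the segmentation models here are built for.

Images are (H, W, 3) floats in [0, 1]; masks are (H, W, 2) booleans with
channel 0 = disc and channel 1 = cup, cup ⊆ disc always.  Every function is a
pure function of its parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

logger = logging.getLogger(__name__)

__all__ = [
    "EyeParams",
    "DomainShift",
    "DomainSpec",
    "GeometryError",
    "ellipse_mask",
    "generate_eye",
    "generate_domain",
    "sample_domain_params",
    "glaucoma_cohort",
    "source_domain_spec",
    "target_domain_spec",
]


class GeometryError(ValueError):
    """Raised when the requested disc/cup geometry is impossible."""


@dataclass(frozen=True)
class EyeParams:
    """Geometric and photometric parameters of one synthetic eye.

    Axes are semi-axes in pixels, given as (row, col); ``cup_offset`` displaces
    the cup centre relative to the disc centre.  ``brightness`` and
    ``contrast`` are multiplicative factors; ``noise_sd`` is the SD of
    additive Gaussian pixel noise.
    """

    image_size: int = 128
    disc_center: tuple[float, float] = (64.0, 64.0)
    disc_axes: tuple[float, float] = (26.0, 22.0)
    cup_axes: tuple[float, float] = (13.0, 11.0)
    cup_offset: tuple[float, float] = (0.0, 2.0)
    vessel_count: int = 6
    vessel_width: int = 2
    background_tone: float = 0.45
    brightness: float = 1.0
    contrast: float = 1.0
    noise_sd: float = 0.02

    def validate(self) -> None:
        s = self.image_size
        if not (self.cup_axes[0] < self.disc_axes[0] and self.cup_axes[1] < self.disc_axes[1]):
            raise GeometryError("cup semi-axes must be strictly smaller than disc semi-axes")
        for ax in (0, 1):
            lo = self.disc_center[ax] - self.disc_axes[ax]
            hi = self.disc_center[ax] + self.disc_axes[ax]
            if lo < 0 or hi > s - 1:
                raise GeometryError(f"disc ellipse exceeds image bounds on axis {ax}")
        disc = ellipse_mask(s, self.disc_center, self.disc_axes)
        cup = ellipse_mask(s, self._cup_center(), self.cup_axes)
        if np.any(cup & ~disc):
            raise GeometryError("cup ellipse is not fully inside the disc ellipse")

    def _cup_center(self) -> tuple[float, float]:
        return (self.disc_center[0] + self.cup_offset[0], self.disc_center[1] + self.cup_offset[1])


@dataclass(frozen=True)
class DomainShift:
    """Photometric/anatomic offsets of one domain relative to a reference.

    ``brightness`` is an additive intensity offset applied to the rendered
    image (so it moves the per-image mean by the same amount, before
    clipping); ``contrast`` adds to the contrast factor; ``vessel_density``
    adds to the vessel count.
    """

    brightness: float = 0.0
    contrast: float = 0.0
    vessel_density: int = 0


#: uniform sampling intervals per EyeParams field, (low, high)
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "disc_axis_row": (22.0, 30.0),
    "disc_aspect": (0.80, 0.95),
    "cup_ratio": (0.35, 0.65),
    "vessel_count": (4, 8),
    "vessel_width": (1, 3),
    "background_tone": (0.40, 0.50),
    "brightness": (0.9, 1.1),
    "contrast": (0.9, 1.1),
    "noise_sd": (0.01, 0.03),
}


@dataclass(frozen=True)
class DomainSpec:
    """A collection of eyes to draw: sample sizes, parameter ranges, shift."""

    n_images: int
    seed: int
    image_size: int = 128
    param_ranges: dict = field(default_factory=lambda: dict(_DEFAULT_RANGES))
    shift: DomainShift = field(default_factory=DomainShift)

    def validate(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        for key, (lo, hi) in self.param_ranges.items():
            if hi < lo:
                raise ValueError(f"empty sampling range for {key!r}: ({lo}, {hi})")


def ellipse_mask(size: int, center, axes) -> np.ndarray:
    """Rasterize a filled ellipse by the centre-inclusion test.

    A pixel (r, c) belongs to the ellipse iff its centre satisfies
    ((r-r0)/a)^2 + ((c-c0)/b)^2 <= 1, with 0-based row-major coordinates.
    """
    r = np.arange(size)[:, None]
    c = np.arange(size)[None, :]
    a, b = axes
    return ((r - center[0]) / a) ** 2 + ((c - center[1]) / b) ** 2 <= 1.0


def _bezier_points(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def _draw_vessels(img: np.ndarray, params: EyeParams, rng: np.random.Generator) -> None:
    """Darken quadratic Bézier strokes running from the border into the disc.

    Vessels only modify the image, never the masks.
    """
    s = params.image_size
    center = np.asarray(params.disc_center, dtype=float)
    for _ in range(params.vessel_count):
        side = rng.integers(4)
        along = rng.uniform(0, s - 1)
        start = np.array(
            [[0.0, along], [s - 1.0, along], [along, 0.0], [along, s - 1.0]][side]
        )
        # end inside or just past the disc, control point bends the stroke
        end = center + rng.normal(0, 0.6, 2) * np.asarray(params.disc_axes)
        ctrl = (start + end) / 2 + rng.normal(0, s / 8.0, 2)
        pts = _bezier_points(start, ctrl, end, 3 * s)
        stroke = np.zeros((s, s), dtype=bool)
        radius = max(params.vessel_width / 2.0, 0.5)
        for r, c in pts:
            rr, cc = draw_disk((r, c), radius + 0.5, shape=(s, s))
            stroke[rr, cc] = True
        img[stroke] *= np.array([0.55, 0.35, 0.35])


def generate_eye(params: EyeParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic eye; returns (image, mask).

    The mask channels are the exact rasterized ellipses; photometric effects
    (smoothing, vessels, brightness/contrast, noise) touch only the image.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    s = params.image_size

    disc = ellipse_mask(s, params.disc_center, params.disc_axes)
    cup = ellipse_mask(s, params._cup_center(), params.cup_axes)

    # reddish retinal background with a mild radial falloff
    r = np.arange(s)[:, None]
    c = np.arange(s)[None, :]
    radial = np.sqrt((r - s / 2) ** 2 + (c - s / 2) ** 2) / (s / np.sqrt(2))
    base = params.background_tone * np.array([1.0, 0.55, 0.30])
    img = base[None, None, :] * (1.0 - 0.25 * radial)[:, :, None]

    img[disc] = np.array([0.93, 0.78, 0.42]) * params.background_tone / 0.45
    img[cup] = np.array([0.99, 0.92, 0.62]) * params.background_tone / 0.45
    img = gaussian_filter(img, sigma=(1.0, 1.0, 0.0))

    _draw_vessels(img, params, rng)

    img = (img - 0.5) * params.contrast + 0.5
    img = img * params.brightness
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    mask = np.stack([disc, cup], axis=-1)
    return img.astype(np.float64), mask


def sample_domain_params(spec: DomainSpec) -> list[EyeParams]:
    """Draw the per-eye parameters of a domain (pure function of the spec)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rngs = rng.spawn(spec.n_images)
    out = []
    for erng in rngs:
        rr = {k: erng.uniform(lo, hi) for k, (lo, hi) in spec.param_ranges.items()}
        s = spec.image_size
        a_r = rr["disc_axis_row"] * s / 128.0
        a_c = a_r * rr["disc_aspect"]
        cr = rr["cup_ratio"]
        margin_r = a_r * (1 - cr)
        off = (erng.uniform(-0.3, 0.3) * margin_r, erng.uniform(-0.3, 0.3) * a_c * (1 - cr))
        center = (
            s / 2 + erng.uniform(-s / 16, s / 16),
            s / 2 + erng.uniform(-s / 16, s / 16),
        )
        p = EyeParams(
            image_size=s,
            disc_center=center,
            disc_axes=(a_r, a_c),
            cup_axes=(cr * a_r, cr * a_c),
            cup_offset=off,
            vessel_count=max(0, int(round(rr["vessel_count"])) + spec.shift.vessel_density),
            vessel_width=max(1, int(round(rr["vessel_width"]))),
            background_tone=rr["background_tone"],
            brightness=rr["brightness"],
            contrast=rr["contrast"] + spec.shift.contrast,
            noise_sd=rr["noise_sd"],
        )
        p.validate()
        out.append(p)
    return out


def generate_domain(spec: DomainSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Render all eyes of a domain; same spec (incl. seed) ⇒ identical output."""
    params = sample_domain_params(spec)
    pairs = []
    for i, p in enumerate(params):
        img, mask = generate_eye(p, seed=_eye_seed(spec.seed, i))
        if spec.shift.brightness:
            img = np.clip(img + spec.shift.brightness, 0.0, 1.0)
        pairs.append((img, mask))
    return pairs


def _eye_seed(domain_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([domain_seed, index]).generate_state(1)[0] % (2**31))


def source_domain_spec(n: int, seed: int, image_size: int = 128) -> DomainSpec:
    """Reference (labelled) acquisition conditions."""
    return DomainSpec(n_images=n, seed=seed, image_size=image_size)


def target_domain_spec(n: int, seed: int, image_size: int = 128) -> DomainSpec:
    """Shifted (unlabelled) acquisition conditions: darker, flatter, more
    vessels — emulating a different scanner."""
    return DomainSpec(
        n_images=n,
        seed=seed,
        image_size=image_size,
        shift=DomainShift(brightness=-0.28, contrast=-0.5, vessel_density=6),
    )


def glaucoma_cohort(
    n: int,
    prevalence: float,
    cdr_normal: tuple[float, float],
    cdr_glaucoma: tuple[float, float],
    seed: int,
    image_size: int = 128,
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Draw a screening cohort of eyes with class-conditional cup-to-disc ratio.

    Labels (1 = glaucomatous) are Bernoulli(prevalence); each eye's true
    vertical CDR is drawn uniformly from its class interval, which sets the
    cup axes relative to the disc axes.
    """
    for iv in (cdr_normal, cdr_glaucoma):
        if not (0.0 < iv[0] <= iv[1] < 1.0):
            raise ValueError(f"CDR interval must lie inside (0, 1): {iv}")
    if cdr_glaucoma[0] <= cdr_normal[1]:
        logger.warning(
            "glaucoma CDR interval %s overlaps/abuts normal interval %s; "
            "classes will not be separable by CDR",
            cdr_glaucoma,
            cdr_normal,
        )
    rng = np.random.default_rng(seed)
    base = sample_domain_params(DomainSpec(n_images=n, seed=seed, image_size=image_size))
    labels = (rng.random(n) < prevalence).astype(int)
    out = []
    for i, (p, lab) in enumerate(zip(base, labels)):
        lo, hi = cdr_glaucoma if lab else cdr_normal
        cdr = rng.uniform(lo, hi)
        p = replace(p, cup_axes=(cdr * p.disc_axes[0], cdr * p.disc_axes[1]),
                    cup_offset=(0.0, p.cup_offset[1] * 0.5))
        p.validate()
        img, mask = generate_eye(p, seed=_eye_seed(seed, i))
        out.append((img, mask, int(lab)))
    return out
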