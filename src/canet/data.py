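"""Dataset I/O, augmentation and the synthetic colonoscopy-style generator.

Datasets follow the Kvasir-SEG directory layout::

    root/
      images/<stem>.png|jpg      3-channel endoscopy-style frames
      masks/<stem>.png           binary lesion masks, matching stems

The synthetic generator emulates the axes that make real polyp data hard:
foreground objects with widely varying area (down to a fraction of a percent
of the frame), smoothly deformed elliptical outlines, adjustable
foreground/background contrast (which may approach zero) and multiplicative
speckle over a textured background.  Masks are exact by construction and the
whole dataset is a pure function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


# ---------------------------------------------------------------------------
# sample discovery and loading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplePair:
    image_path: Path
    mask_path: Path
    id: str


def scan_dataset(root) -> list[SamplePair]:
    """Pair image and mask files by filename stem, sorted by id.

    Unmatched files on either side are skipped with a warning.
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    for d in (img_dir, mask_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"dataset directory missing: {d}")
    images = {p.stem: p for p in sorted(img_dir.iterdir())
              if p.suffix.lower() in IMAGE_EXTENSIONS}
    masks = {p.stem: p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() in IMAGE_EXTENSIONS}
    for stem in sorted(set(images) ^ set(masks)):
        side = "mask" if stem in images else "image"
        logger.warning("skipping %r: no matching %s file", stem, side)
    pairs = [SamplePair(images[s], masks[s], s) for s in sorted(set(images) & set(masks))]
    if not pairs:
        raise ValueError(f"no image/mask pairs found under {root}")
    return pairs


def split_train_test(pairs, n_train: int, seed: int) -> tuple[list, list]:
    """Seeded disjoint exhaustive split (e.g. 880/120 of a 1000-image set)."""
    pairs = list(pairs)
    if not 0 < n_train < len(pairs):
        raise ValueError(f"n_train={n_train} must lie in (0, {len(pairs)})")
    order = np.random.default_rng(seed).permutation(len(pairs))
    train = [pairs[i] for i in order[:n_train]]
    test = [pairs[i] for i in order[n_train:]]
    return train, test


def load_sample(pair: SamplePair, target_size: tuple[int, int] = (256, 256),
                normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Load one pair as (3,H,W) float image and (1,H,W) {0,1} mask.

    Image: bilinear resize, scaled to [0,1] then (x - 0.5)/0.5 when
    `normalize`.  Mask: nearest-neighbour resize, binarised at intensity
    > 127 (tolerant of near-binary JPEG masks).
    """
    h, w = target_size
    try:
        img = Image.open(pair.image_path).convert("RGB")
        msk = Image.open(pair.mask_path).convert("L")
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise IOError(f"cannot decode sample {pair.id!r}: {exc}") from exc
    img = img.resize((w, h), Image.BILINEAR)
    msk = msk.resize((w, h), Image.NEAREST)
    image = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    if normalize:
        image = (image - 0.5) / 0.5
    mask = (np.asarray(msk) > 127).astype(np.float32)[None]
    return image, mask


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationPolicy:
    """Seeded default policy: flips + 90-degree rotations + mild photometric
    jitter.  Geometric ops hit image and mask identically; photometric ops
    touch the image only."""

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_rot90: float = 0.5
    p_jitter: float = 0.3
    brightness: float = 0.1
    contrast: float = 0.1
    seed: int = 0
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        for p in (self.p_hflip, self.p_vflip, self.p_rot90, self.p_jitter):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"augmentation probability {p} outside [0, 1]")
        self.rng = np.random.default_rng(self.seed)


def augment(image: np.ndarray, mask: np.ndarray,
            policy: AugmentationPolicy) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random draw of the policy to an aligned (image, mask) pair."""
    if image.shape[1:] != mask.shape[1:]:
        raise ValueError(f"image {image.shape} and mask {mask.shape} are misaligned")
    rng = policy.rng
    if rng.random() < policy.p_hflip:
        image, mask = image[:, :, ::-1], mask[:, :, ::-1]
    if rng.random() < policy.p_vflip:
        image, mask = image[:, ::-1, :], mask[:, ::-1, :]
    if rng.random() < policy.p_rot90:
        k = int(rng.integers(1, 4))
        image = np.rot90(image, k, axes=(1, 2))
        mask = np.rot90(mask, k, axes=(1, 2))
    if rng.random() < policy.p_jitter:
        scale = 1.0 + policy.contrast * float(rng.uniform(-1, 1))
        shift = policy.brightness * float(rng.uniform(-1, 1))
        image = image * scale + shift
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    n_images: int = 200
    image_size: tuple[int, int] = (96, 96)
    polyps_per_image: tuple[int, int] = (1, 3)
    area_fraction: tuple[float, float] = (0.002, 0.25)
    contrast: tuple[float, float] = (0.3, 0.9)
    texture_noise: float = 0.08
    blur_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        for name in ("polyps_per_image", "area_fraction", "contrast"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range {lo}..{hi} is not well-ordered")
        if self.area_fraction[1] > 0.4:
            raise ValueError("area_fraction upper bound > 0.4 cannot be guaranteed")


def _blob_outline(rng: np.random.Generator, n_theta: int = 256) -> np.ndarray:
    """Unit radial profile rho(theta): squashed ellipse + low-frequency wobble."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    aspect = rng.uniform(0.6, 1.0)
    rho = aspect / np.sqrt((aspect * np.cos(theta)) ** 2 + np.sin(theta) ** 2)
    for m in (2, 3, 4):
        rho *= 1.0 + rng.uniform(0.0, 0.06) * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    rot = rng.uniform(0, 2 * np.pi)
    return np.roll(rho, int(rot / (2 * np.pi) * n_theta))


def _draw_blob(mask: np.ndarray, rng: np.random.Generator,
               target_px: float) -> bool:
    """Add one non-overlapping blob of ~target_px pixels; False if no room."""
    h, w = mask.shape
    rho = _blob_outline(rng)
    unit_area = 0.5 * np.mean(rho**2) * 2 * np.pi  # polar area of the unit profile
    scale = np.sqrt(target_px / unit_area)
    margin = scale * rho.max() + 1
    if 2 * margin + 2 >= min(h, w):
        scale = (min(h, w) / 2 - 2) / rho.max()
        margin = scale * rho.max() + 1
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(50):
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        theta = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
        radius = np.interp(theta, np.linspace(0, 2 * np.pi, rho.size, endpoint=False),
                           rho, period=2 * np.pi)
        blob = np.hypot(yy - cy, xx - cx) <= scale * radius
        if blob.any() and not (blob & mask).any():
            mask |= blob
            return True
    return False


def _render_image(mask: np.ndarray, rng: np.random.Generator,
                  spec: SyntheticSpec) -> np.ndarray:
    """Textured background + contrast-offset foreground + speckle, as HxWx3."""
    h, w = mask.shape
    base = rng.uniform(0.25, 0.5)
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 12.0)
    texture = 0.5 * texture / (np.abs(texture).max() + 1e-8)
    contrast = rng.uniform(*spec.contrast)
    soft = gaussian_filter(mask.astype(np.float32), spec.blur_sigma)
    chan_weights = np.array([1.0, 0.7, 0.6])  # lesions skew reddish
    img = np.empty((h, w, 3), dtype=np.float32)
    for c in range(3):
        bg = base * (0.8 + 0.4 * rng.random()) + 0.2 * texture
        img[..., c] = bg + contrast * 0.45 * chan_weights[c] * soft
    if spec.texture_noise > 0:
        img *= 1.0 + spec.texture_noise * rng.standard_normal(img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def generate_synthetic(spec: SyntheticSpec, out_root) -> list[SamplePair]:
    """Write a seeded synthetic dataset in the standard layout; return pairs."""
    spec.validate()
    out_root = Path(out_root)
    img_dir, mask_dir = out_root / "images", out_root / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    total_px = h * w
    lo, hi = spec.area_fraction
    pairs = []
    for i in range(spec.n_images):
        n_polyps = int(rng.integers(spec.polyps_per_image[0],
                                    spec.polyps_per_image[1] + 1))
        target_total = rng.uniform(lo, hi)
        weights = rng.dirichlet(np.ones(n_polyps))
        fractions = np.sort(target_total * weights)[::-1]
        fractions[0] = max(fractions[0], lo)  # the largest blob alone meets the floor
        mask = np.zeros((h, w), dtype=bool)
        for frac in fractions:
            _draw_blob(mask, rng, max(frac * total_px, 4.0))
        if not mask.any():  # safeguard: a centred disk of the minimum area
            yy, xx = np.mgrid[0:h, 0:w]
            r = np.sqrt(max(lo * total_px, 4.0) / np.pi) + 1
            mask = np.hypot(yy - h / 2, xx - w / 2) <= r
        # pixel quantisation can nudge tiny/huge blobs out of the requested
        # range; morphological correction restores the constructive guarantee
        min_px = int(np.ceil(lo * total_px))
        max_px = int(np.floor(hi * total_px))
        while mask.sum() < min_px:
            mask = binary_dilation(mask)
        while mask.sum() > max_px and mask.sum() > 4:
            mask = binary_erosion(mask)
        image = _render_image(mask, rng, spec)
        stem = f"synthetic_{i:04d}"
        Image.fromarray((image * 255).round().astype(np.uint8)).save(img_dir / f"{stem}.png")
        Image.fromarray(mask.astype(np.uint8) * 255).save(mask_dir / f"{stem}.png")
        pairs.append(SamplePair(img_dir / f"{stem}.png", mask_dir / f"{stem}.png", stem))
    return pairs
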