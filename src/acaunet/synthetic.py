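"""Synthetic fundus-like images with exact ground-truth disc masks.

Real disc-centered fundus crops show a bright, roughly circular optic disc on
a darker, textured reddish background, crossed by dark vessels.  The
generator emulates exactly those features — a jittered bright ellipse with a
soft rim, a low-frequency reddish texture field, dark Bezier vessel curves
and additive Gaussian noise — and returns the exact disc support as the
mask.  It does not emulate pathology (exudates, atrophy), illumination
falloff at the fundus border, or camera vignetting.

Also here: the dataset-expansion augmentation (the eight-element dihedral
orbit of flips, matching an eightfold dataset expansion), online photometric
jitter (brightness and small translations), and PNG/TIFF dataset I/O in the
``root/{images,masks}/<id>.png`` layout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "SamplePair",
    "generate_sample",
    "generate_dataset",
    "augment_eightfold",
    "jitter_photometric",
    "write_dataset",
    "read_dataset",
    "to_batch",
]

_DISC_COLOR = np.array([1.00, 0.90, 0.62], dtype=np.float32)
_BG_COLOR = np.array([0.58, 0.27, 0.17], dtype=np.float32)
_VESSEL_COLOR = np.array([0.30, 0.08, 0.07], dtype=np.float32)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic disc renderer.

    ``disc_radius_range`` and ``disc_center_jitter`` are fractions of the
    image side; the spec is rejected if the largest possible disc could leave
    the frame under the largest jitter.
    """

    size: int = 448
    disc_radius_range: tuple[float, float] = (0.12, 0.18)
    disc_center_jitter: float = 0.05
    disc_brightness: float = 0.95
    background_texture_scale: float = 0.12
    vessel_count: int = 4
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.disc_radius_range
        if not 0 < lo <= hi:
            raise ValueError("disc_radius_range must satisfy 0 < lo <= hi")
        if hi + self.disc_center_jitter >= 0.5:
            raise ValueError(
                f"disc (radius {hi}) plus jitter {self.disc_center_jitter} "
                "does not fit inside the image for all draws"
            )


@dataclass
class SamplePair:
    """One image/mask pair: image (H,W,3) float32 in [0,1], mask (H,W) uint8."""

    image: np.ndarray
    mask: np.ndarray
    id: str


def _rng_for(spec: SyntheticSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index])


def generate_sample(spec: SyntheticSpec, index: int) -> SamplePair:
    """Render sample ``index``; deterministic given ``(spec.seed, index)``."""
    rng = _rng_for(spec, index)
    s = spec.size

    # textured reddish background
    texture = rng.standard_normal((s, s)).astype(np.float32)
    texture = gaussian_filter(texture, sigma=s / 16.0)
    texture /= max(float(np.abs(texture).max()), 1e-8)
    image = _BG_COLOR[None, None, :] * (
        1.0 + spec.background_texture_scale * texture[..., None]
    )

    # bright quasi-elliptical disc with a soft rim
    r_frac = rng.uniform(*spec.disc_radius_range)
    rx = r_frac * s
    ry = rx * rng.uniform(0.85, 1.0)
    theta = rng.uniform(0.0, np.pi)
    cx = s / 2.0 + rng.uniform(-spec.disc_center_jitter, spec.disc_center_jitter) * s
    cy = s / 2.0 + rng.uniform(-spec.disc_center_jitter, spec.disc_center_jitter) * s
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    u = (xx - cx + 0.5) * np.cos(theta) + (yy - cy + 0.5) * np.sin(theta)
    v = -(xx - cx + 0.5) * np.sin(theta) + (yy - cy + 0.5) * np.cos(theta)
    d = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    rim = max(2.0 / min(rx, ry), 0.05)  # soft rim thickness (inside the ellipse)
    weight = np.clip((1.0 - d) / rim, 0.0, 1.0).astype(np.float32)
    mask = (weight > 0).astype(np.uint8)
    disc = spec.disc_brightness * _DISC_COLOR
    image = image * (1.0 - weight[..., None]) + disc[None, None, :] * weight[..., None]

    # dark vessel curves crossing the frame near the disc centre
    if spec.vessel_count > 0:
        vmask = np.zeros((s, s), dtype=bool)
        for _ in range(spec.vessel_count):
            p0 = _edge_point(rng, s)
            p2 = _edge_point(rng, s)
            mid = np.array([cy, cx]) + rng.uniform(-0.2, 0.2, size=2) * s
            pts = _bezier(p0, mid, p2, n=3 * s)
            pts = np.clip(np.round(pts).astype(int), 0, s - 1)
            for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
                rr, cc = draw_line(r0, c0, r1, c1)
                vmask[rr, cc] = True
        vmask = dilation(vmask, disk(max(s // 180, 1)))
        vblend = gaussian_filter(vmask.astype(np.float32), sigma=0.8) * 0.65
        image = image * (1.0 - vblend[..., None]) + _VESSEL_COLOR * vblend[..., None]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SamplePair(image=image, mask=mask, id=f"synth-{spec.seed}-{index:04d}")


def _edge_point(rng: np.random.Generator, s: int) -> np.ndarray:
    side = rng.integers(0, 4)
    t = rng.uniform(0, s - 1)
    return np.array({0: (0.0, t), 1: (s - 1.0, t), 2: (t, 0.0), 3: (t, s - 1.0)}[int(side)])


def _bezier(p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2


def generate_dataset(spec: SyntheticSpec, n: int) -> list[SamplePair]:
    return [generate_sample(spec, i) for i in range(n)]


# ------------------------------------------------------------------ augmentation

def _d4_transforms():
    """The eight elements of the dihedral group of the square."""
    return [
        ("orig", lambda a: a),
        ("hflip", lambda a: a[:, ::-1]),
        ("vflip", lambda a: a[::-1, :]),
        ("rot180", lambda a: a[::-1, ::-1]),
        ("transpose", lambda a: a.swapaxes(0, 1)),
        ("anti-transpose", lambda a: a.swapaxes(0, 1)[::-1, ::-1]),
        ("rot90", lambda a: a.swapaxes(0, 1)[::-1, :]),
        ("rot270", lambda a: a.swapaxes(0, 1)[:, ::-1]),
    ]


def augment_eightfold(pair: SamplePair) -> list[SamplePair]:
    """The full flip orbit of a square sample: horizontal, vertical and
    diagonal flips compose to exactly eight distinct orientations, expanding
    the dataset eightfold.  Image and mask are transformed identically."""
    h, w = pair.mask.shape
    if h != w:
        raise ValueError("diagonal flips require square images")
    out = []
    for name, f in _d4_transforms():
        out.append(
            SamplePair(
                image=np.ascontiguousarray(f(pair.image)),
                mask=np.ascontiguousarray(f(pair.mask)),
                id=f"{pair.id}-{name}",
            )
        )
    return out


def jitter_photometric(pair: SamplePair,
                       brightness_range: tuple[float, float] = (0.9, 1.1),
                       shift_range: tuple[int, int] = (-5, 5),
                       rng: np.random.Generator | None = None) -> SamplePair | None:
    """Random brightness scaling (image only) and integer translation with
    zero padding (image and mask identically).  Returns ``None``, with a
    warning, if the shift ejects the entire disc from the frame."""
    rng = rng or np.random.default_rng()
    factor = rng.uniform(*brightness_range)
    lo, hi = shift_range
    dx = int(rng.integers(lo, hi + 1))
    dy = int(rng.integers(lo, hi + 1))
    image = np.clip(pair.image * factor, 0.0, 1.0).astype(np.float32)
    image = _shift2d(image, dy, dx)
    mask = _shift2d(pair.mask, dy, dx)
    if pair.mask.any() and not mask.any():
        warnings.warn(f"shift ({dx},{dy}) ejected the disc of {pair.id}; dropped")
        return None
    return SamplePair(image=image, mask=mask, id=f"{pair.id}-j")


def _shift2d(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.zeros_like(a)
    h, w = a.shape[:2]
    if abs(dy) >= h or abs(dx) >= w:
        return out
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[yd, xd] = a[ys, xs]
    return out


# --------------------------------------------------------------------------- I/O

def write_dataset(pairs: list[SamplePair], root: str | Path) -> None:
    """Write ``root/images/<id>.png`` (8-bit RGB) and ``root/masks/<id>.png``
    (8-bit, 0/255)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        iio.imwrite(root / "images" / f"{pair.id}.png",
                    np.round(pair.image * 255).astype(np.uint8))
        iio.imwrite(root / "masks" / f"{pair.id}.png",
                    (pair.mask * 255).astype(np.uint8))


def read_dataset(root: str | Path, size: int | None = None) -> list[SamplePair]:
    """Read a ``root/{images,masks}`` layout (PNG or TIFF).

    Masks are binarized at half intensity; with ``size`` given, images are
    bilinearly resized (stretching, not padding) and masks resampled
    nearest-neighbour to stay binary.  Images without a matching mask are
    skipped and counted in a log message.
    """
    root = Path(root)
    image_files = sorted(
        p for p in (root / "images").iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    pairs: list[SamplePair] = []
    skipped = 0
    for img_path in image_files:
        mask_path = None
        for suffix in (".png", ".tif", ".tiff"):
            cand = root / "masks" / (img_path.stem + suffix)
            if cand.exists():
                mask_path = cand
                break
        if mask_path is None:
            skipped += 1
            logger.warning("image %s has no matching mask; skipped", img_path.name)
            continue
        image = np.asarray(iio.imread(img_path), dtype=np.float32)
        if image.ndim == 2:
            image = np.repeat(image[..., None], 3, axis=2)
        if image.max() > 1.0:
            image /= 255.0
        mask = np.asarray(iio.imread(mask_path), dtype=np.float32)
        if mask.ndim == 3:
            mask = mask[..., 0]
        mask = (mask >= 0.5 * max(mask.max(), 1.0)).astype(np.uint8)
        if size is not None and image.shape[:2] != (size, size):
            image = resize(image, (size, size), order=1, anti_aliasing=True,
                           preserve_range=True).astype(np.float32)
            mask = resize(mask, (size, size), order=0, preserve_range=True,
                          anti_aliasing=False).astype(np.uint8)
        pairs.append(SamplePair(image=np.clip(image, 0, 1), mask=mask, id=img_path.stem))
    if skipped:
        logger.warning("%d image(s) without masks were skipped", skipped)
    return pairs


def to_batch(pairs: list[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into network-ready arrays (N,3,H,W) and (N,H,W)."""
    images = np.stack([p.image.transpose(2, 0, 1) for p in pairs]).astype(np.float32)
    masks = np.stack([p.mask for p in pairs]).astype(np.float32)
    return images, masks
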