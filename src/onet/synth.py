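"""Deterministic synthetic multi-class segmentation/classification data.

Generates grayscale (or RGB) images containing non-overlapping organ-like
shapes — ellipses, rectangles and annuli — on a noisy background, with
pixel-exact index masks and a per-image class label (the class of the
largest drawn shape).  Images emulate the geometry of 2-D medical slices:
a handful of compact structures of distinct intensity over low-contrast
background.  They deliberately do not emulate CT Hounsfield statistics or
dermoscopic colour texture.

Reproducibility: a master seed spawns an independent stream per image
index, so regenerating with more images never perturbs earlier ones, and
the same spec always produces bit-identical pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse as _draw_ellipse

SHAPE_KINDS = ("ellipse", "rectangle", "annulus")


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    n_images: int = 64
    image_size: int = 224
    n_classes: int = 4                      # background + 3 shape classes
    shapes: tuple = ()                      # per foreground class; cycled default
    size_range: tuple = ()                  # (min, max) semi-axis in pixels
    intensity_means: tuple = ()             # per class incl. background
    intensity_std: float = 0.05
    background_noise_std: float = 0.05
    rgb: bool = False
    seed: int = 0
    max_placement_tries: int = 50

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need background plus at least one foreground class")
        k = self.n_classes - 1
        if not self.shapes:
            self.shapes = tuple(SHAPE_KINDS[i % len(SHAPE_KINDS)] for i in range(k))
        if len(self.shapes) != k:
            raise ValueError(f"need one shape kind per foreground class ({k})")
        for s in self.shapes:
            if s not in SHAPE_KINDS:
                raise ValueError(f"unknown shape kind {s!r}")
        if not self.size_range:
            lo = max(4, self.image_size // 14)
            hi = max(lo + 2, self.image_size // 4)
            self.size_range = (lo, hi)
        if not self.intensity_means:
            # background dim, classes evenly spaced and well separated
            self.intensity_means = (0.15,) + tuple(
                0.35 + 0.5 * i / max(k - 1, 1) for i in range(k))
        if len(self.intensity_means) != self.n_classes:
            raise ValueError("need one intensity mean per class incl. background")


@dataclass
class SynthDataset:
    images: np.ndarray      # (N, H, W) or (N, H, W, 3) uint8
    masks: np.ndarray       # (N, H, W) uint8 labels 0..K-1
    labels: pd.DataFrame    # columns: filename, label
    spec: SynthSpec

    def __len__(self) -> int:
        return self.images.shape[0]


def _image_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _shape_pixels(kind: str, cy: int, cx: int, a: int, b: int,
                  rot: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    if kind == "ellipse":
        return _draw_ellipse(cy, cx, a, b, shape=(size, size), rotation=rot)
    if kind == "rectangle":
        rr, cc = np.meshgrid(np.arange(max(0, cy - a), min(size, cy + a)),
                             np.arange(max(0, cx - b), min(size, cx + b)),
                             indexing="ij")
        return rr.reshape(-1), cc.reshape(-1)
    if kind == "annulus":
        rr, cc = _draw_ellipse(cy, cx, a, b, shape=(size, size), rotation=rot)
        hole = np.zeros((size, size), bool)
        hr, hc = _draw_ellipse(cy, cx, max(1, a // 2), max(1, b // 2),
                               shape=(size, size), rotation=rot)
        hole[hr, hc] = True
        keep = ~hole[rr, cc]
        return rr[keep], cc[keep]
    raise ValueError(f"unknown shape kind {kind!r}")


def generate_image(spec: SynthSpec, index: int
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """One image + mask + class label, reproducible from (seed, index)."""
    rng = _image_rng(spec.seed, index)
    size = spec.image_size
    mask = np.zeros((size, size), dtype=np.uint8)
    k = spec.n_classes - 1
    n_shapes = int(rng.integers(1, spec.n_classes))  # 1 .. n_classes-1
    classes = rng.choice(np.arange(1, spec.n_classes), size=n_shapes,
                         replace=False)
    areas: dict[int, int] = {}
    lo, hi = spec.size_range
    for cid in classes:
        kind = spec.shapes[int(cid) - 1]
        placed = False
        for _ in range(spec.max_placement_tries):
            a = int(rng.integers(lo, hi + 1))
            b = int(rng.integers(lo, hi + 1))
            # oversized shapes clip at the frame instead of failing placement
            margin = min(max(a, b) + 1, (size - 1) // 2)
            cy = int(rng.integers(margin, size - margin))
            cx = int(rng.integers(margin, size - margin))
            rot = float(rng.uniform(0, np.pi))
            rr, cc = _shape_pixels(kind, cy, cx, a, b, rot, size)
            if rr.size == 0 or mask[rr, cc].any():
                continue
            mask[rr, cc] = cid
            areas[int(cid)] = rr.size
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a non-overlapping {kind} for class {cid} "
                f"after {spec.max_placement_tries} tries (image {index})")
    label = max(areas, key=areas.get)

    means = np.asarray(spec.intensity_means)[mask]
    stds = np.where(mask == 0, spec.background_noise_std, spec.intensity_std)
    if spec.rgb:
        img = means[..., None] + rng.normal(0, 1, (size, size, 3)) * stds[..., None]
    else:
        img = means + rng.normal(0, 1, (size, size)) * stds
    img = np.clip(img, 0, 1)
    return (img * 255).round().astype(np.uint8), mask, label


def generate_dataset(spec: SynthSpec) -> SynthDataset:
    """Generate the full dataset in memory (deterministic in ``spec.seed``)."""
    images, masks, labels = [], [], []
    for i in range(spec.n_images):
        img, mask, label = generate_image(spec, i)
        images.append(img)
        masks.append(mask)
        labels.append(label)
    df = pd.DataFrame({
        "filename": [f"img_{i:04d}.png" for i in range(spec.n_images)],
        "label": labels,
    })
    return SynthDataset(np.stack(images), np.stack(masks), df, spec)


def write_dataset(ds: SynthDataset, out_dir) -> Path:
    """Write images/, masks/ (8-bit index PNGs) and labels.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(ds.labels["filename"]):
        Image.fromarray(ds.images[i]).save(out / "images" / name)
        Image.fromarray(ds.masks[i]).save(out / "masks" / name)
    ds.labels.to_csv(out / "labels.csv", index=False)
    return out


def load_dataset(data_dir) -> tuple[np.ndarray, np.ndarray | None, pd.DataFrame | None]:
    """Read back images/, masks/ (if present) and labels.csv (if present)."""
    data_dir = Path(data_dir)
    img_dir = data_dir / "images"
    if not img_dir.is_dir():
        raise FileNotFoundError(f"no images/ directory under {data_dir}")
    names = sorted(p.name for p in img_dir.glob("*.png"))
    if not names:
        raise FileNotFoundError(f"no PNG images in {img_dir}")
    images = np.stack([np.asarray(Image.open(img_dir / n)) for n in names])
    masks = None
    if (data_dir / "masks").is_dir():
        masks = np.stack([np.asarray(Image.open(data_dir / "masks" / n))
                          for n in names])
    labels = None
    if (data_dir / "labels.csv").is_file():
        labels = pd.read_csv(data_dir / "labels.csv")
    return images, masks, labels


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mask: np.ndarray, rng,
            small_angle: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Random flips and k*90-degree rotation, identically applied to image
    and mask.  ``small_angle`` > 0 additionally rotates by a uniform angle
    in [-small_angle, small_angle] degrees (nearest-neighbour for the mask).
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape[:2]} differ")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if rng.random() < 0.5:
        image, mask = image[:, ::-1].copy(), mask[:, ::-1].copy()
    if rng.random() < 0.5:
        image, mask = image[::-1].copy(), mask[::-1].copy()
    k = int(rng.integers(0, 4))
    if k:
        image = np.rot90(image, k, axes=(0, 1)).copy()
        mask = np.rot90(mask, k, axes=(0, 1)).copy()
    if small_angle > 0:
        from skimage.transform import rotate
        angle = float(rng.uniform(-small_angle, small_angle))
        image = rotate(image.astype(float) / 255.0, angle, order=1,
                       preserve_range=True)
        image = (np.clip(image, 0, 1) * 255).round().astype(np.uint8)
        mask = rotate(mask, angle, order=0, preserve_range=True).astype(mask.dtype)
    return image, mask
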