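"""Datasets: synthetic two-class histology-like tiles, directory loading, splitting.

The synthetic generator emulates the statistical structure of breast-biopsy
tile collections: two texture classes (benign / malignant) with an
imbalanced prevalence of roughly 70% malignant, where malignant tiles carry
a denser, more irregular population of dark "nuclei" blobs on a paler
stained background.  It is a testbed for the classification pipeline, not a
simulator of real histology.

Labels are integers: ``BENIGN = 0`` and ``MALIGNANT = 1`` (malignant is the
positive class everywhere in this package).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

BENIGN = 0
MALIGNANT = 1
LABEL_NAMES = {BENIGN: "benign", MALIGNANT: "malignant"}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

TILE_SIZE = 32  # model input is TILE_SIZE x TILE_SIZE x 3

MAGNIFICATIONS = ("40x", "100x", "200x", "400x")

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "LABEL_NAMES",
    "TILE_SIZE",
    "LabeledDataset",
    "SyntheticParams",
    "generate_synthetic_dataset",
    "load_image_directory",
    "stratified_split",
    "save_dataset",
    "pixel_mean_threshold_accuracy",
]


@dataclass
class LabeledDataset:
    """A uniform stack of RGB tiles with binary labels.

    ``images`` has shape (n, H, W, 3) with intensities in [0, 1];
    ``labels`` has shape (n,) with values in {0, 1}.
    """

    images: np.ndarray
    labels: np.ndarray
    magnification_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError(f"images must be (n, H, W, 3), got {self.images.shape}")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels differ in length")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("pixel intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(self.images[idx], self.labels[idx], self.magnification_tag)

    @property
    def n_malignant(self) -> int:
        return int(np.sum(self.labels == MALIGNANT))

    @property
    def n_benign(self) -> int:
        return int(np.sum(self.labels == BENIGN))


@dataclass(frozen=True)
class SyntheticParams:
    """Generative recipe for the synthetic tile dataset.

    Each tile is a class-specific background colour plus elliptical nuclei
    blobs plus i.i.d. Gaussian pixel noise, clipped to [0, 1].  Malignant
    tiles draw more nuclei and more eccentric ones.  Colour units are
    normalized RGB in [0, 1]; radii are in pixels on the 32x32 tile.
    """

    n_images: int = 400
    malignant_fraction: float = 0.686  # prevalence of the positive class
    nuclei_count_mean_benign: float = 7.0
    nuclei_count_mean_malignant: float = 18.0
    nucleus_radius_range: tuple[float, float] = (1.5, 4.0)
    background_mean_benign: tuple[float, float, float] = (0.88, 0.76, 0.86)
    background_mean_malignant: tuple[float, float, float] = (0.72, 0.55, 0.68)
    nucleus_mean_benign: tuple[float, float, float] = (0.45, 0.32, 0.58)
    nucleus_mean_malignant: tuple[float, float, float] = (0.28, 0.14, 0.42)
    color_spread: float = 0.03
    noise_sd: float = 0.03
    seed: int = 0
    tile_size: int = TILE_SIZE

    def __post_init__(self) -> None:
        if not (0.0 < self.malignant_fraction < 1.0):
            raise ValueError("malignant_fraction must lie strictly in (0, 1)")
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        lo, hi = self.nucleus_radius_range
        if lo < 1.0 or hi < lo:
            raise ValueError("nucleus radii must be >= 1 pixel and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def noise_free(self) -> "SyntheticParams":
        """The same recipe with pixel noise switched off (separability dial)."""
        return replace(self, noise_sd=0.0, color_spread=0.0)


def _draw_tile(rng: np.random.Generator, params: SyntheticParams, label: int) -> np.ndarray:
    s = params.tile_size
    if label == MALIGNANT:
        bg = np.array(params.background_mean_malignant)
        nuc = np.array(params.nucleus_mean_malignant)
        rate = params.nuclei_count_mean_malignant
        ecc_max = 0.65  # malignant nuclei are more elongated/irregular
    else:
        bg = np.array(params.background_mean_benign)
        nuc = np.array(params.nucleus_mean_benign)
        rate = params.nuclei_count_mean_benign
        ecc_max = 0.25

    img = np.empty((s, s, 3))
    img[:] = np.clip(bg + rng.normal(0, params.color_spread, 3), 0, 1)

    yy, xx = np.mgrid[0:s, 0:s]
    n_nuclei = max(1, int(rng.poisson(rate)))
    lo, hi = params.nucleus_radius_range
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, s, 2)
        r = rng.uniform(lo, hi)
        ecc = rng.uniform(0.0, ecc_max)
        a, b = r * (1 + ecc), r * (1 - ecc)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        color = np.clip(nuc + rng.normal(0, params.color_spread, 3), 0, 1)
        img[mask] = color

    if params.noise_sd > 0:
        img += rng.normal(0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_dataset(params: SyntheticParams) -> LabeledDataset:
    """Generate a seeded synthetic two-class tile dataset.

    Identical ``params`` (including the seed) give a bitwise-identical
    dataset.  Class labels are drawn i.i.d. Bernoulli(malignant_fraction);
    if a class ends up empty the draw is retried with one forced example of
    each class so both classes are always present.
    """
    rng = np.random.default_rng(params.seed)
    labels = (rng.random(params.n_images) < params.malignant_fraction).astype(np.int64)
    if params.n_images >= 2 and (labels.min() == labels.max()):
        labels[0] = BENIGN
        labels[1] = MALIGNANT
    images = np.stack([_draw_tile(rng, params, int(lab)) for lab in labels])
    return LabeledDataset(images, labels, magnification_tag="synthetic")


def _to_tile(img: Image.Image, tile_size: int) -> np.ndarray:
    """Resize (bilinear, aspect ratio not preserved) and scale to [0, 1]."""
    img = img.convert("RGB").resize((tile_size, tile_size), Image.BILINEAR)
    return np.asarray(img, dtype=np.float64) / 255.0


_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


def _collect(files, label, tile_size, images, labels, skipped):
    for path in sorted(files):
        try:
            with Image.open(path) as im:
                arr = _to_tile(im, tile_size)
        except Exception as exc:  # unreadable file: warn and skip
            logger.warning("skipping unreadable image %s: %s", path, exc)
            skipped.append(path)
            continue
        images.append(arr)
        labels.append(label)


def load_image_directory(
    root, layout: str = "flat", magnification: str | None = None, tile_size: int = TILE_SIZE
) -> LabeledDataset:
    """Load a labelled image directory and resize every image to a tile.

    ``flat`` layout expects ``root/benign/*`` and ``root/malignant/*``.
    ``breakhis`` layout expects ``root/{benign,malignant}/{40x,100x,200x,400x}/*``
    and requires ``magnification`` to pick one group.  Grayscale files are
    replicated to three channels; unreadable files are skipped with a
    logged warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"image directory not found: {root}")
    if layout not in ("flat", "breakhis"):
        raise ValueError(f"unknown layout {layout!r}")
    if layout == "breakhis":
        if magnification not in MAGNIFICATIONS:
            raise ValueError(f"breakhis layout needs magnification in {MAGNIFICATIONS}")
        tag = magnification
    else:
        tag = "flat"

    images: list[np.ndarray] = []
    labels: list[int] = []
    skipped: list[Path] = []
    for name, label in NAME_TO_LABEL.items():
        cls_dir = root / name if layout == "flat" else root / name / magnification
        files = [
            p for p in cls_dir.glob("*") if p.suffix.lower() in _IMAGE_SUFFIXES
        ] if cls_dir.is_dir() else []
        before = len(labels)
        _collect(files, label, tile_size, images, labels, skipped)
        if len(labels) == before:
            raise ValueError(f"no readable {name} images under {cls_dir}")
    if skipped:
        logger.warning("skipped %d unreadable file(s)", len(skipped))
    return LabeledDataset(np.stack(images), np.array(labels), magnification_tag=tag)


def save_dataset(ds: LabeledDataset, out_dir) -> Path:
    """Write a dataset as PNG tiles plus a CSV manifest.

    Tiles land in per-class subdirectories (``benign/``, ``malignant/``) so
    the directory can be read back with :func:`load_image_directory`;
    returns the manifest path.
    """
    out_dir = Path(out_dir)
    rows = ["filename,label,magnification_tag"]
    for i, (img, lab) in enumerate(zip(ds.images, ds.labels)):
        cls = LABEL_NAMES[int(lab)]
        (out_dir / cls).mkdir(parents=True, exist_ok=True)
        name = f"{cls}/tile_{i:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / name)
        rows.append(f"{name},{cls},{ds.magnification_tag}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def stratified_split(
    ds: LabeledDataset, test_fraction: float = 0.30, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded stratified train/test split; parts are disjoint and exhaustive."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    for name, count in (("benign", ds.n_benign), ("malignant", ds.n_malignant)):
        if count < 2:
            raise ValueError(f"class {name} has {count} member(s); need >= 2 to stratify")
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(ds))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=ds.labels, random_state=seed
    )
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def pixel_mean_threshold_accuracy(ds: LabeledDataset) -> float:
    """Accuracy (%) of the best single threshold on the per-tile mean intensity.

    A sanity oracle: on noise-free synthetic data with disjoint class colour
    means this reaches 100, so any trained classifier has headroom to match.
    """
    means = ds.images.mean(axis=(1, 2, 3))
    order = np.argsort(means)
    sorted_labels = ds.labels[order]
    n = len(ds)
    best = 0
    # threshold between consecutive sorted means; either polarity
    for cut in range(n + 1):
        below_mal = np.sum(sorted_labels[:cut] == MALIGNANT)
        above_mal = ds.n_malignant - below_mal
        acc_a = below_mal + (n - cut - above_mal)  # malignant iff below cut
        acc_b = above_mal + (cut - below_mal)  # malignant iff above cut
        best = max(best, acc_a, acc_b)
    return 100.0 * best / n
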