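"""Synthetic blood-smear image generator.

Produces labelled stand-ins for stained peripheral-blood-smear microscopy
crops of single white cells.  The class signal is geometric, mirroring the
morphology that separates leukemic blasts from normal leukocytes: blasts are
rendered with a much larger nucleus-to-cell area ratio (mean 0.70, sd 0.08,
versus 0.35, sd 0.05 for normal cells — non-overlapping at two standard
deviations, so the signal is learnable) and a more irregular,
Fourier-perturbed cell boundary.  Colours follow a Romanowsky-stain palette:
dark purple nucleus, pale violet cytoplasm, light background with faint red
blood cells as distractors.

These images are not biophysically realistic; they exist so the enhancement,
training and tuning machinery can be exercised end-to-end without the
external dataset.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .image import IMAGE_EXTENSIONS, load_image, save_image

__all__ = [
    "SmearSpec", "render_cell_image", "synthetic_dataset",
    "generate_dataset", "load_image_folder", "FolderDataset", "CLASS_ALIASES",
]

#: on-disk folder aliases: the public dataset names its leukemia class "all"
#: (acute lymphoblastic leukemia) and its healthy class "hem"
CLASS_ALIASES = {"all": "blast", "hem": "normal"}


@dataclass(frozen=True)
class SmearSpec:
    """Parameters of one rendered cell image.

    nucleus_ratio_* are the per-class Gaussian distributions of the
    nucleus-to-cell area ratio; irregularity_* the boundary perturbation
    amplitudes.  All colours are RGB in [0, 1].
    """

    image_size: int = 224
    class_label: str = "normal"                 # "normal" | "blast"
    nucleus_ratio_mean: dict = None
    nucleus_ratio_sd: dict = None
    irregularity: dict = None
    n_distractors: tuple = (4, 9)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "nucleus_ratio_mean",
                           self.nucleus_ratio_mean or {"normal": 0.35, "blast": 0.70})
        object.__setattr__(self, "nucleus_ratio_sd",
                           self.nucleus_ratio_sd or {"normal": 0.05, "blast": 0.08})
        object.__setattr__(self, "irregularity",
                           self.irregularity or {"normal": 0.03, "blast": 0.10})
        if self.class_label not in ("normal", "blast"):
            raise ValueError(f"class_label must be 'normal' or 'blast', got {self.class_label!r}")
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")


_PALETTE = {
    "background": np.array([0.94, 0.91, 0.88]),
    "rbc": np.array([0.86, 0.58, 0.56]),
    "cytoplasm": np.array([0.80, 0.76, 0.89]),
    "nucleus": np.array([0.40, 0.20, 0.52]),
}


def _perturbed_radius(theta: np.ndarray, base: float, amplitude: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Radius profile r(theta) with low-order Fourier boundary perturbation."""
    r = np.ones_like(theta)
    for k in range(2, 6):
        a = rng.normal(0.0, amplitude / np.sqrt(k))
        phase = rng.uniform(0, 2 * np.pi)
        r += a * np.cos(k * theta + phase)
    return base * np.clip(r, 0.3, 1.7)


def render_cell_image(spec: SmearSpec):
    """Render one cell image; returns (image, ground_truth dict).

    Deterministic under ``spec.seed``.  The ground truth records the class
    label and the realised nucleus-to-cell pixel-area ratio.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.image_size
    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    img = np.empty((S, S, 3))
    img[:] = _PALETTE["background"]
    img += rng.normal(0.0, 0.01, size=(S, S, 1))          # faint illumination texture

    # red-blood-cell distractors (no nucleus, partly transparent)
    for _ in range(rng.integers(*spec.n_distractors)):
        cx, cy = rng.uniform(0, S, size=2)
        r = rng.uniform(0.06, 0.11) * S
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = d2 <= r * r
        alpha = rng.uniform(0.35, 0.6)
        img[mask] = (1 - alpha) * img[mask] + alpha * _PALETTE["rbc"]
        # pale RBC centre
        inner = d2 <= (0.45 * r) ** 2
        img[inner] = 0.6 * img[inner] + 0.4 * _PALETTE["background"]

    # central white cell
    cell_r = rng.uniform(0.22, 0.30) * S
    if 2 * cell_r >= S:
        raise ValueError(f"cell (radius {cell_r:.1f}) larger than image {S}")
    cx = S / 2 + rng.uniform(-0.04, 0.04) * S
    cy = S / 2 + rng.uniform(-0.04, 0.04) * S
    theta = np.arctan2(yy - cy, xx - cx)
    radial = np.hypot(xx - cx, yy - cy)
    irr = spec.irregularity[spec.class_label]
    cell_mask = radial <= _perturbed_radius(theta, cell_r, irr, rng)
    img[cell_mask] = 0.15 * img[cell_mask] + 0.85 * _PALETTE["cytoplasm"]

    ratio = rng.normal(spec.nucleus_ratio_mean[spec.class_label],
                       spec.nucleus_ratio_sd[spec.class_label])
    ratio = float(np.clip(ratio, 0.05, 0.92))
    nucleus_r = np.sqrt(ratio) * cell_r
    ncx = cx + rng.uniform(-0.05, 0.05) * cell_r
    ncy = cy + rng.uniform(-0.05, 0.05) * cell_r
    ntheta = np.arctan2(yy - ncy, xx - ncx)
    nradial = np.hypot(xx - ncx, yy - ncy)
    nucleus_mask = (nradial <= _perturbed_radius(ntheta, nucleus_r, irr, rng)) & cell_mask
    img[nucleus_mask] = 0.1 * img[nucleus_mask] + 0.9 * _PALETTE["nucleus"]
    # chromatin texture inside the nucleus
    img[nucleus_mask] += rng.normal(0.0, 0.03, size=(int(nucleus_mask.sum()), 3))

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = {
        "class_label": spec.class_label,
        "nucleus_ratio": float(nucleus_mask.sum() / max(1, cell_mask.sum())),
        "cell_radius_px": float(cell_r),
        "seed": spec.seed,
    }
    return img, truth


def synthetic_dataset(n_normal: int, n_blast: int, image_size: int = 224,
                      seed: int = 0):
    """In-memory dataset: (images (N,S,S,3), labels (N,), truths list).

    Label convention: blast (the positive class) = 1, normal = 0.
    """
    images, labels, truths = [], [], []
    for i, (label_name, n) in enumerate((("normal", n_normal), ("blast", n_blast))):
        for j in range(n):
            spec = SmearSpec(image_size=image_size, class_label=label_name,
                             seed=seed * 1_000_003 % (2**31) + i * 500_000 + j)
            img, truth = render_cell_image(spec)
            images.append(img)
            labels.append(i)
            truths.append(truth)
    return np.stack(images), np.array(labels), truths


def generate_dataset(n_per_class: dict, out_dir: str | os.PathLike, seed: int = 0,
                     image_size: int = 224, force: bool = False) -> pd.DataFrame:
    """Write a class-subfolder PNG dataset and return its manifest.

    ``n_per_class`` maps class names ("normal"/"blast") to counts; imbalanced
    counts are allowed (they exercise the inverse-frequency class weights).
    Refuses to write into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    rows = []
    for ci, (label, n) in enumerate(sorted(n_per_class.items())):
        cls_dir = out / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        for j in range(n):
            s = seed * 1_000_003 % (2**31) + ci * 500_000 + j
            img, truth = render_cell_image(
                SmearSpec(image_size=image_size, class_label=label, seed=s))
            path = cls_dir / f"{label}_{j:05d}.png"
            save_image(img, path)
            rows.append({"path": str(path), "label": label, "seed": s,
                         "nucleus_ratio": truth["nucleus_ratio"]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


class FolderDataset:
    """Lazy reader for a one-subfolder-per-class image directory.

    Class names are canonicalised through :data:`CLASS_ALIASES` and ordered
    alphabetically; ``labels`` are indices into ``classes``.  Images are
    resized to ``size`` x ``size`` on read.  Non-image files are skipped with
    a warning.
    """

    def __init__(self, root: str | os.PathLike, size: int = 224):
        self.root = Path(root)
        self.size = size
        entries = {}
        for sub in sorted(p for p in self.root.iterdir() if p.is_dir()):
            cls = CLASS_ALIASES.get(sub.name.lower(), sub.name.lower())
            files = []
            for f in sorted(sub.iterdir()):
                if f.suffix.lower() in IMAGE_EXTENSIONS:
                    files.append(f)
                elif f.is_file():
                    warnings.warn(f"skipping non-image file {f}", stacklevel=2)
            if not files:
                raise ValueError(f"class folder {sub.name!r} contains no images")
            entries.setdefault(cls, []).extend(files)
        if not entries:
            raise ValueError(f"{self.root} contains no class subfolders")
        self.classes = sorted(entries)
        self.paths = []
        self.labels = []
        for ci, cls in enumerate(self.classes):
            for f in entries[cls]:
                self.paths.append(f)
                self.labels.append(ci)
        self.labels = np.array(self.labels)

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        for path, label in zip(self.paths, self.labels):
            yield load_image(path, size=self.size), int(label)

    def load_all(self):
        """Materialise the whole folder as (images, labels) arrays."""
        images = np.stack([img for img, _ in self])
        return images, self.labels.copy()


def load_image_folder(root: str | os.PathLike, size: int = 224) -> FolderDataset:
    return FolderDataset(root, size=size)
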