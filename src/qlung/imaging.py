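"""Image I/O, preprocessing and the synthetic paired CXR/CT phantom generator.

The pipeline consumes paired grayscale chest images: a projection radiograph
(CXR) and a tomography slice (CT) of the same subject. Pixels live on the
1-255 gray scale; a zero from an 8-bit file is floored to 1 rather than
rejected so ordinary PNGs remain loadable.

The phantom generator stands in for real datasets in every test. It draws a
per-subject lesion latent (positions, radii, intensity offsets) and renders
it twice: the CT as sharp disks on a quiet background, the CXR as the same
disks blurred over a rib-stripe background. Classes are separated by
construction — malignant lesions are larger and brighter than benign,
normal subjects carry none — so the generator's job is statistical
structure, not radiological realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import IOErrorWithPath, ValidationError
from .seeding import stage_rng

__all__ = [
    "CLASSES",
    "DEFAULT_RESIZE",
    "ImageSample",
    "Lesion",
    "LesionLatent",
    "PhantomConfig",
    "load_grayscale",
    "save_png",
    "resize",
    "draw_latent",
    "generate_phantom_pair",
    "generate_dataset",
]

#: Canonical label ordering used throughout the package.
CLASSES = ("normal", "benign", "malignant")

#: Default preprocessing target: images are resized to 1024x1024 pixels.
DEFAULT_RESIZE = 1024

PIXEL_MIN, PIXEL_MAX = 1, 255


@dataclass
class ImageSample:
    """A single grayscale chest image with its provenance.

    ``pixels`` is a 2-D uint8 array with values in [1, 255]; ``modality`` is
    ``"CXR"`` or ``"CT"``; ``label`` is one of :data:`CLASSES` or ``None``
    when unknown.
    """

    pixels: np.ndarray
    modality: str = "CXR"
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("image must be a non-empty 2-D pixel grid")
        if self.pixels.min() < PIXEL_MIN or self.pixels.max() > PIXEL_MAX:
            raise ValidationError(
                f"pixel values must lie in [{PIXEL_MIN}, {PIXEL_MAX}]"
            )
        if self.modality not in ("CXR", "CT"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.label is not None and self.label not in CLASSES:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_grayscale(
    path, modality: str = "CXR", subject_id: str = "", label: str | None = None
) -> ImageSample:
    """Load a PNG (or any PIL-readable image) as a 1-255 grayscale sample.

    RGB input is collapsed to luminance. File values of 0 are floored to 1,
    the bottom of the working gray range.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except FileNotFoundError:
        raise IOErrorWithPath(path, "image file not found")
    except OSError:
        raise IOErrorWithPath(path, "unreadable image file")
    if arr.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    pixels = np.clip(arr, PIXEL_MIN, PIXEL_MAX).astype(np.uint8)
    return ImageSample(pixels, modality=modality, subject_id=subject_id, label=label)


def save_png(sample: ImageSample, path) -> Path:
    """Write the sample as an 8-bit grayscale PNG; round-trips exactly."""
    path = Path(path)
    try:
        Image.fromarray(sample.pixels.astype(np.uint8), mode="L").save(path)
    except OSError:
        raise IOErrorWithPath(path, "cannot write image file")
    return path


def resize(sample: ImageSample, target: int = DEFAULT_RESIZE) -> ImageSample:
    """Bilinear resize to ``target`` x ``target`` pixels, re-clamped to [1, 255]."""
    if target < 8:
        raise ValidationError(f"resize target must be >= 8, got {target}")
    if sample.pixels.shape == (target, target):
        pixels = sample.pixels.copy()
    else:
        im = Image.fromarray(sample.pixels.astype(np.uint8), mode="L")
        out = im.resize((target, target), Image.BILINEAR)
        pixels = np.clip(np.asarray(out), PIXEL_MIN, PIXEL_MAX).astype(np.uint8)
    return ImageSample(
        pixels, modality=sample.modality, subject_id=sample.subject_id, label=sample.label
    )


# --------------------------------------------------------------------------
# Phantom generation


@dataclass
class ClassLesionParams:
    """Lesion sampling ranges for one class (counts and radii in pixels)."""

    count_range: tuple[int, int]
    radius_range: tuple[float, float]
    intensity_range: tuple[float, float]


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic paired-modality dataset.

    Defaults mirror a screening-style class mix (half malignant, the rest
    split between benign and normal) with class-ordered lesion geometry:
    malignant lesions are drawn larger and brighter than benign, and normal
    subjects have none. ``class_proportions`` follows the canonical
    (normal, benign, malignant) label order.
    """

    n_subjects: int = 300
    image_size: int = 64
    class_proportions: tuple[float, float, float] = (0.25, 0.25, 0.5)
    lesion_params: dict = field(
        default_factory=lambda: {
            "normal": ClassLesionParams((0, 0), (0.0, 0.0), (0.0, 0.0)),
            "benign": ClassLesionParams((1, 2), (3.0, 5.0), (30.0, 50.0)),
            "malignant": ClassLesionParams((2, 4), (8.0, 12.0), (60.0, 90.0)),
        }
    )
    noise_sd: float = 4.0
    cxr_blur_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (3,) or (props < 0).any():
            raise ValidationError("class_proportions must be 3 nonnegative reals")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValidationError("class_proportions must sum to 1 within 1e-9")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")
        lp = self.lesion_params["normal"]
        if lp.count_range != (0, 0):
            raise ValidationError("normal class must have zero lesions")

    def class_counts(self) -> dict[str, int]:
        """Exact per-class subject counts by largest-remainder rounding."""
        props = np.asarray(self.class_proportions, dtype=float)
        raw = props * self.n_subjects
        counts = np.floor(raw).astype(int)
        remainder = self.n_subjects - counts.sum()
        order = np.argsort(-(raw - counts), kind="stable")
        for i in range(remainder):
            counts[order[i]] += 1
        return dict(zip(CLASSES, counts.tolist()))


@dataclass
class Lesion:
    """One lesion blob: center (row, col), radius and intensity offset."""

    cy: float
    cx: float
    radius: float
    intensity: float


@dataclass
class LesionLatent:
    """The per-subject draw shared by both rendered modalities."""

    subject_id: str
    label: str
    lesions: list[Lesion]


def draw_latent(
    subject_id: str, label: str, config: PhantomConfig, rng: np.random.Generator
) -> LesionLatent:
    """Sample lesion count, centers, radii and intensities for one subject."""
    params: ClassLesionParams = config.lesion_params[label]
    lo, hi = params.count_range
    n = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    size = config.image_size
    margin = max(params.radius_range[1], 1.0) + 2.0
    lesions = []
    for _ in range(n):
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        r = rng.uniform(*params.radius_range)
        inten = rng.uniform(*params.intensity_range)
        lesions.append(Lesion(cy=cy, cx=cx, radius=r, intensity=inten))
    return LesionLatent(subject_id=subject_id, label=label, lesions=lesions)


def _lesion_field(latent: LesionLatent, size: int) -> np.ndarray:
    """Additive intensity field of sharp lesion disks."""
    field_ = np.zeros((size, size), dtype=float)
    if latent.lesions:
        yy, xx = np.mgrid[0:size, 0:size]
        for les in latent.lesions:
            mask = (yy - les.cy) ** 2 + (xx - les.cx) ** 2 <= les.radius**2
            field_[mask] += les.intensity
    return field_


def generate_phantom_pair(
    latent: LesionLatent, config: PhantomConfig, rng: np.random.Generator
) -> tuple[ImageSample, ImageSample]:
    """Render one subject's latent as a (CXR, CT) image pair.

    Both modalities share the lesion latent exactly. The CT shows sharp
    lesion edges over a quiet dark background; the CXR shows the same
    lesions Gaussian-blurred (projection-like) over horizontal rib stripes
    with heavier noise.
    """
    size = config.image_size
    field_ = _lesion_field(latent, size)

    # CT: dark uniform background, sharp disks, low noise.
    ct = 60.0 + field_ + rng.normal(0.0, config.noise_sd * 0.5, (size, size))

    # CXR: brighter background with rib stripes, blurred disks, full noise.
    rows = np.arange(size, dtype=float)[:, None]
    stripes = 15.0 * np.sin(2.0 * math.pi * rows / 9.0)
    blurred = ndimage.gaussian_filter(field_, sigma=config.cxr_blur_sigma)
    cxr = 120.0 + stripes + 0.8 * blurred + rng.normal(0.0, config.noise_sd, (size, size))

    def finish(arr: np.ndarray, modality: str) -> ImageSample:
        pixels = np.clip(np.rint(arr), PIXEL_MIN, PIXEL_MAX).astype(np.uint8)
        return ImageSample(
            pixels, modality=modality, subject_id=latent.subject_id, label=latent.label
        )

    return finish(cxr, "CXR"), finish(ct, "CT")


def generate_dataset(config: PhantomConfig, out_dir) -> pd.DataFrame:
    """Write a full paired phantom dataset and return its manifest.

    Produces ``2 * n_subjects`` PNGs under ``out_dir/images``, a
    ``manifest.csv`` (columns subject_id, modality, label, path) and a
    ``latents.json`` record of every subject's lesion draw so tests can
    assert cross-modality pairing. Bit-reproducible for a fixed seed.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    try:
        img_dir.mkdir(parents=True, exist_ok=True)
    except OSError:
        raise IOErrorWithPath(out_dir, "cannot create output directory")

    counts = config.class_counts()
    labels = [c for c in CLASSES for _ in range(counts[c])]
    rng = stage_rng(config.seed, "phantom")

    rows = []
    latents_json = []
    for i, label in enumerate(labels):
        sid = f"S{i:04d}"
        latent = draw_latent(sid, label, config, rng)
        cxr, ct = generate_phantom_pair(latent, config, rng)
        for sample in (cxr, ct):
            fname = f"{sid}_{sample.modality}.png"
            save_png(sample, img_dir / fname)
            rows.append(
                {
                    "subject_id": sid,
                    "modality": sample.modality,
                    "label": label,
                    "path": str(Path("images") / fname),
                }
            )
        latents_json.append(asdict(latent))

    manifest = pd.DataFrame(rows, columns=["subject_id", "modality", "label", "path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "latents.json", "w") as fh:
        json.dump(latents_json, fh, indent=1)
    return manifest


def load_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV, validating the required columns."""
    path = Path(path)
    if not path.exists():
        raise IOErrorWithPath(path, "manifest not found")
    df = pd.read_csv(path)
    required = {"subject_id", "modality", "label", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    return df
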