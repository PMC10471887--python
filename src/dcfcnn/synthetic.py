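"""Seeded synthetic H&E-like scene generator and dataset manifests.

The generator emulates the composition of a bile-duct histopathology scene
collection: three scene categories (no cancer, partial cancer coverage,
full cancer coverage) merged into a benign/malignant binary label, with
per-patient grouping. Images are eosin-pink multi-octave value-noise
backgrounds overlaid with anti-aliased hematoxylin-purple elliptical blob
clusters whose coverage, contrast and spread differ by category.

A single ``separability`` knob in [0, 1] linearly interpolates every
category-specific blob parameter between a common midpoint (separability 0:
all categories draw from identical distributions) and fully distinct
category profiles (separability 1). Class contrast is therefore monotone in
the knob by construction.

Each scene derives its own random stream from ``(seed, scene_id)``, so the
content of a scene never depends on generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import ConfigError, DataError, InvalidCategoryError

__all__ = [
    "CATEGORIES",
    "LABELS",
    "ImageSample",
    "DatasetManifest",
    "SynthConfig",
    "merge_labels",
    "generate_scene",
    "build_manifest",
    "render_manifest",
    "write_dataset",
    "load_manifest",
    "scene_rng",
    "make_arrays",
]

CATEGORIES = ("no_cancer", "partial_cancer", "full_cancer")
LABELS = ("benign", "malignant")

# stain-inspired base colours (RGB, 0-255)
_EOSIN = np.array([236.0, 187.0, 211.0])
_HEMATOXYLIN = np.array([94.0, 58.0, 138.0])


@dataclass
class ImageSample:
    """One RGB scene with its label, category and provenance ids."""

    scene_id: str
    patient_id: str
    category: str
    label: str
    pixels: np.ndarray | None = None
    path: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InvalidCategoryError(f"unknown category {self.category!r}")
        if self.label != merge_labels(self.category):
            raise DataError(
                f"label {self.label!r} inconsistent with category {self.category!r}")
        if not self.patient_id:
            raise DataError("patient_id must be non-empty")


@dataclass
class DatasetManifest:
    """Ordered sample collection with per-category counts and the seed used."""

    samples: list[ImageSample]
    seed: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            self.counts = {c: sum(s.category == c for s in self.samples)
                           for c in CATEGORIES}
        if sum(self.counts.values()) != len(self.samples):
            raise DataError("category counts do not sum to the number of samples")
        ids = [s.scene_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DataError("scene ids must be unique")

    def __len__(self):
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([s.patient_id for s in self.samples])

    def label_counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scene_id": [s.scene_id for s in self.samples],
                "patient_id": [s.patient_id for s in self.samples],
                "category": [s.category for s in self.samples],
                "label": [s.label for s in self.samples],
                "path": [s.path or "" for s in self.samples],
            }
        )


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults mirror the published collection: 690 partial-cancer scenes from
    125 patients, 48 full-cancer scenes from 14 patients and 142 cancer-free
    scenes from 35 patients (880 scenes in total). The default canvas is
    576x432, a quarter of the source material's 2304x1728, to keep
    generation desk-fast; full resolution is a configuration choice.
    """

    n_no_cancer: int = 142
    n_partial: int = 690
    n_full: int = 48
    image_height: int = 576
    image_width: int = 432
    n_patients_no_cancer: int = 35
    n_patients_partial: int = 125
    n_patients_full: int = 14
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_no_cancer", "n_partial", "n_full"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.separability <= 1.0:
            raise ConfigError("separability must lie in [0, 1]")
        if self.image_height < 16 or self.image_width < 16:
            raise ConfigError("image dimensions must be >= 16 pixels")

    def count(self, category: str) -> int:
        return {"no_cancer": self.n_no_cancer, "partial_cancer": self.n_partial,
                "full_cancer": self.n_full}[category]

    def n_patients(self, category: str) -> int:
        return {"no_cancer": self.n_patients_no_cancer,
                "partial_cancer": self.n_patients_partial,
                "full_cancer": self.n_patients_full}[category]


def merge_labels(category: str) -> str:
    """Binary label merge: any cancer coverage is malignant."""
    if category == "no_cancer":
        return "benign"
    if category in ("partial_cancer", "full_cancer"):
        return "malignant"
    raise InvalidCategoryError(f"unknown category {category!r}")


def scene_rng(seed: int, scene_id: str) -> np.random.Generator:
    """Per-scene stream derived from ``(seed, crc32(scene_id))``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(scene_id.encode())]))


# ---------------------------------------------------------------------------
# scene synthesis
# ---------------------------------------------------------------------------

# blob profiles at separability 1: (coverage_lo, coverage_hi, spread_frac,
# alpha, blob_radius_lo, blob_radius_hi) -- coverage is the target fraction
# of the canvas occupied by blob interiors, spread the std of blob centres
# around the cluster centre as a fraction of the canvas diagonal, alpha the
# compositing opacity, radii fractions of min(H, W).
_PROFILES = {
    "no_cancer": (0.010, 0.040, 0.45, 0.40, 0.015, 0.035),
    "partial_cancer": (0.20, 0.55, 0.16, 0.85, 0.030, 0.060),
    "full_cancer": (0.90, 0.96, 1.20, 0.90, 0.045, 0.080),
}
# common midpoint used at separability 0 (identical across categories)
_MIDPOINT = (0.25, 0.45, 0.45, 0.65, 0.030, 0.055)


def _value_noise(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Multi-octave value noise in [-1, 1]."""
    acc = np.zeros((h, w), dtype=np.float32)
    amp, total = 1.0, 0.0
    for cells in (6, 12, 24, 48):
        gh, gw = max(2, min(cells, h)), max(2, min(cells, w))
        grid = rng.random((gh, gw)).astype(np.float32)
        img = Image.fromarray(grid, mode="F").resize((w, h), Image.BILINEAR)
        acc += amp * np.asarray(img, dtype=np.float32)
        total += amp
        amp *= 0.5
    acc = acc / total
    return (acc - 0.5) * 2.0


def _draw_blob(canvas, cover, rng, cy, cx, r, alpha):
    h, w = cover.shape
    ax = r * rng.uniform(0.7, 1.3)
    ay = r * rng.uniform(0.7, 1.3)
    theta = rng.uniform(0.0, np.pi)
    colour = _HEMATOXYLIN + rng.normal(0.0, 10.0, size=3)
    extent = max(ax, ay)
    y0, y1 = int(max(0, cy - extent - 2)), int(min(h, cy + extent + 3))
    x0, x1 = int(max(0, cx - extent - 2)), int(min(w, cx + extent + 3))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / ax
    v = (-st * dx + ct * dy) / ay
    q = u * u + v * v
    # smooth anti-aliased edge over q in [1 - delta, 1]
    m = np.clip((1.0 - q) / 0.15, 0.0, 1.0)
    a = (alpha * m)[..., None]
    canvas[y0:y1, x0:x1] = (1.0 - a) * canvas[y0:y1, x0:x1] + a * colour
    cover[y0:y1, x0:x1] |= q < 1.0


def generate_scene(category: str, cfg: SynthConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one scene of the given category as a (H, W, 3) uint8 array.

    Deterministic given ``(category, cfg, rng state)``; at
    ``cfg.separability == 0`` all categories consume identical blob
    parameters and are therefore identically distributed.
    """
    if category not in CATEGORIES:
        raise InvalidCategoryError(f"unknown category {category!r}")
    h, w = cfg.image_height, cfg.image_width
    s = cfg.separability
    prof = tuple((1.0 - s) * m + s * p
                 for m, p in zip(_MIDPOINT, _PROFILES[category]))
    cov_lo, cov_hi, spread_frac, alpha, r_lo, r_hi = prof

    noise = _value_noise(rng, h, w)
    canvas = _EOSIN[None, None, :] + noise[..., None] * np.array([14.0, 18.0, 12.0])

    target = rng.uniform(cov_lo, cov_hi)
    diag = float(np.hypot(h, w))
    spread = spread_frac * diag
    cy0, cx0 = rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w)
    cover = np.zeros((h, w), dtype=bool)
    rmin = min(h, w)
    max_blobs = 4000
    check_every = 4
    for i in range(max_blobs):
        cy = np.clip(cy0 + rng.normal(0.0, spread), 0, h - 1)
        cx = np.clip(cx0 + rng.normal(0.0, spread), 0, w - 1)
        r = rng.uniform(r_lo, r_hi) * rmin
        _draw_blob(canvas, cover, rng, cy, cx, r, alpha)
        if (i + 1) % check_every == 0 and cover.mean() >= target:
            break
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

_SHORT = {"no_cancer": "none", "partial_cancer": "part", "full_cancer": "full"}


def build_manifest(cfg: SynthConfig) -> DatasetManifest:
    """Metadata-only manifest with the requested per-category composition.

    Patients are private to their category (a patient never straddles
    categories) and scenes are assigned to patients round-robin, so the
    layout is deterministic and independent of the pixel seed.
    """
    samples = []
    for category in CATEGORIES:
        n = cfg.count(category)
        n_pat = max(1, min(cfg.n_patients(category), n)) if n else 0
        short = _SHORT[category]
        for i in range(n):
            patient = f"P_{short}_{i % n_pat:03d}"
            samples.append(ImageSample(
                scene_id=f"{short}_{i:05d}",
                patient_id=patient,
                category=category,
                label=merge_labels(category),
            ))
    return DatasetManifest(samples=samples, seed=cfg.seed)


def render_manifest(manifest: DatasetManifest, cfg: SynthConfig):
    """Yield ``(sample, pixels)`` pairs, rendering each scene on demand."""
    for s in manifest.samples:
        rng = scene_rng(cfg.seed, s.scene_id)
        yield s, generate_scene(s.category, cfg, rng)


def make_arrays(cfg: SynthConfig):
    """Render the whole manifest into memory.

    Returns ``(X, y, manifest)`` with ``X`` a (N, H, W, 3) uint8 stack and
    ``y`` integer labels (0 = benign, 1 = malignant).
    """
    manifest = build_manifest(cfg)
    xs, ys = [], []
    for s, px in render_manifest(manifest, cfg):
        xs.append(px)
        ys.append(LABELS.index(s.label))
    x = (np.stack(xs) if xs
         else np.zeros((0, cfg.image_height, cfg.image_width, 3), np.uint8))
    return x, np.array(ys, dtype=np.int64), manifest


def write_dataset(cfg: SynthConfig, out_dir) -> DatasetManifest:
    """Render all scenes to PNG files plus a ``manifest.csv``."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    manifest = build_manifest(cfg)
    for s, px in render_manifest(manifest, cfg):
        rel = f"images/{s.scene_id}.png"
        Image.fromarray(px).save(out / rel)
        s.path = rel
    manifest.to_frame().to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(csv_path) -> DatasetManifest:
    """Reload a manifest written by :func:`write_dataset`."""
    path = Path(csv_path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    df = pd.read_csv(path, keep_default_na=False)
    required = {"scene_id", "patient_id", "category", "label", "path"}
    if not required.issubset(df.columns):
        raise DataError(f"manifest must have columns {sorted(required)}")
    samples = [ImageSample(scene_id=str(r.scene_id), patient_id=str(r.patient_id),
                           category=str(r.category), label=str(r.label),
                           path=str(r.path) or None)
               for r in df.itertuples()]
    return DatasetManifest(samples=samples, seed=0)


def load_images(manifest: DatasetManifest, root) -> np.ndarray:
    """Read the PNG pixel data referenced by a manifest."""
    root = Path(root)
    out = []
    for s in manifest.samples:
        if not s.path:
            raise DataError(f"sample {s.scene_id} has no stored image path")
        out.append(np.asarray(Image.open(root / s.path).convert("RGB")))
    return np.stack(out)
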