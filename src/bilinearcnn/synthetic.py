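"""Synthetic microscopy-texture image generator.

Emulates the statistical structure that makes orderless (bilinear) pooling
the right inductive bias for histopathology-style imagery: class identity
is carried by *small local texture motifs scattered at uniformly random
positions*, not by where anything sits in the frame, and the same tissue
can be imaged at several "magnifications" that rescale the motifs.

Images are dark-field (fluorescence-style): bright stained motifs — round
blobs ("cells"), rings, oriented bars — on a near-black background.  The
default class set contains a *fine-grained pair* alongside two easy
classes: "mixstain" images hold two fluorophore populations (half green,
half red blobs) while "purestain" images hold a single population whose
color is drawn per image.  The two classes match exactly in first-order
statistics (any spatially averaged feature of a mixed image is the
midpoint of the pure class's two modes), so an average-pooling head
cannot linearly separate them; the second-order statistics that bilinear
pooling retains can.  Motif centers are uniform over the image, which is
what makes the translation-invariance properties of the pooled descriptor
testable.

The generator is deterministic: one seed yields byte-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .data import MAGNIFICATIONS, DatasetManifest

__all__ = [
    "MotifSpec",
    "SyntheticConfig",
    "default_motifs",
    "render_image",
    "generate_arrays",
    "generate_synthetic_dataset",
]


@dataclass(frozen=True)
class MotifSpec:
    """Parametric texture motif for one class.

    ``kind`` is ``blob`` (filled disc), ``ring`` (annulus), ``bar``
    (oriented rectangle; instances cycle through ``orientations``) or
    ``cross`` (all ``orientations`` drawn co-located at one center);
    sizes are pixels at scale 1.0; ``count`` is the number of motif
    instances per image (the density knob).

    ``colors`` (stain-like RGB values in [0, 1]) and multi-element
    ``orientations`` define motif *variants*.  With
    ``arrangement="mixed"`` the variants alternate within every image;
    with ``arrangement="pure"`` one variant is drawn per image and used
    for all its motifs.  A mixed class and its pure counterpart then
    contain the same motifs in the same total amount, so every spatially
    averaged (first-order) feature of a mixed image sits at the midpoint
    of the pure class's variant modes — linearly inseparable for an
    average-pooling head — while second-order statistics of the feature
    map separate the pair.  This is the fine-grained structure
    orderless bilinear pooling is designed to capture.
    """

    name: str
    kind: str
    count: int
    radius: float = 2.2                     # blob/ring radius
    thickness: float = 1.3                  # ring wall
    length: float = 9.0                     # bar long side
    width: float = 2.2                      # bar short side
    orientations: tuple[float, ...] = (0.0,)  # bar/cross angles (deg)
    colors: tuple[tuple[float, float, float], ...] | None = None
    arrangement: str = "mixed"              # mixed | pure (see below)

    def __post_init__(self) -> None:
        # normalize sequence fields so YAML round-trips compare equal
        object.__setattr__(self, "orientations", tuple(self.orientations))
        if self.colors is not None:
            object.__setattr__(
                self, "colors", tuple(tuple(c) for c in self.colors)
            )
        if self.kind not in ("blob", "ring", "bar", "cross"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.count < 1:
            raise ValueError("count must be positive")
        if self.kind == "cross" and len(self.orientations) < 2:
            raise ValueError("cross needs at least two orientations")
        if self.arrangement not in ("mixed", "pure"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")


def default_motifs(n_classes: int) -> list[MotifSpec]:
    """The stock motif families, pairwise distinct by construction.

    The first four classes form two fine-grained pairs built on the same
    oriented segments: a *mixed* class scatters bars of two orientations
    within every image, while its *pure* counterpart uses one orientation
    per image (chosen at random per image).  Any spatially pooled mean
    feature of a mixed image is the midpoint of the pure class's two
    modes, so first-order (average-pooled) descriptors cannot linearly
    separate the pair; second-order orientation-energy statistics can.
    """
    green, red = (0.20, 0.85, 0.30), (0.85, 0.25, 0.20)
    yellow, cyan = (0.80, 0.72, 0.25), (0.25, 0.70, 0.80)
    stock = [
        MotifSpec("mixstain", "blob", count=12, radius=2.5,
                  colors=(green, red), arrangement="mixed"),
        MotifSpec("purestain", "blob", count=12, radius=2.5,
                  colors=(green, red), arrangement="pure"),
        MotifSpec("rings", "ring", count=8, radius=4.0, thickness=1.3,
                  colors=(yellow,)),
        MotifSpec("hvbars", "bar", count=10, orientations=(0.0, 90.0),
                  colors=(cyan,)),
        MotifSpec("bigblobs", "blob", count=7, radius=3.6,
                  colors=(yellow,)),
        MotifSpec("smallrings", "ring", count=12, radius=2.5,
                  thickness=1.1, colors=(cyan,)),
        MotifSpec("mixbars", "bar", count=10, orientations=(45.0, 135.0),
                  colors=(green, red), arrangement="mixed"),
        MotifSpec("purebars", "bar", count=10, orientations=(45.0, 135.0),
                  colors=(green, red), arrangement="pure"),
    ]
    if not (2 <= n_classes <= len(stock)):
        raise ValueError(f"n_classes must be in [2, {len(stock)}]")
    return stock[:n_classes]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    ``scales`` are pseudo-magnifications: a motif's linear size is
    multiplied by the scale, emulating the same tissue imaged at different
    magnification factors.  All classes share ``motif_color`` (hematoxylin
    purple) on a pink background so that first-order statistics carry as
    little class signal as possible; ``color_jitter`` perturbs both per
    image.
    """

    n_classes: int = 4
    images_per_class: int = 40
    image_size: int = 64
    scales: tuple[float, ...] = (1.0, 1.5, 2.0)
    seed: int = 0
    motifs: list[MotifSpec] | None = None
    background: tuple[float, float, float] = (0.05, 0.04, 0.08)
    motif_color: tuple[float, float, float] = (0.20, 0.85, 0.30)
    color_jitter: float = 0.04
    noise_std: float = 0.02
    opacity: float = 0.85

    def __post_init__(self) -> None:
        if self.motifs is None:
            self.motifs = default_motifs(self.n_classes)
        if len(self.motifs) != self.n_classes:
            raise ValueError("need one motif definition per class")
        if len({asdict_frozen(m) for m in self.motifs}) != self.n_classes:
            raise ValueError("motif definitions must be pairwise distinct")
        if not (1 <= len(self.scales) <= len(MAGNIFICATIONS)):
            raise ValueError(
                f"at most {len(MAGNIFICATIONS)} scales supported"
            )

    @property
    def class_names(self) -> list[str]:
        return [m.name for m in self.motifs]

    def scale_magnification(self, scale_index: int) -> int:
        """Pseudo-magnification label for a scale (40x, 100x, ...)."""
        return MAGNIFICATIONS[scale_index]

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["motifs"] = [asdict(m) for m in self.motifs]
        doc["scales"] = list(self.scales)
        doc["background"] = list(self.background)
        doc["motif_color"] = list(self.motif_color)
        Path(path).write_text(yaml.safe_dump(doc))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if doc.get("motifs"):
            doc["motifs"] = [MotifSpec(**m) for m in doc["motifs"]]
        for key in ("scales", "background", "motif_color"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def asdict_frozen(m: MotifSpec) -> tuple:
    return tuple(sorted(asdict(m).items()))


def _bar_alpha(yy, xx, cy, cx, length, width, angle_deg) -> np.ndarray:
    theta = np.deg2rad(angle_deg)
    dy = yy - cy
    dx = xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    au = np.clip(length / 2 + 0.5 - np.abs(u), 0.0, 1.0)
    av = np.clip(width / 2 + 0.5 - np.abs(v), 0.0, 1.0)
    return au * av


def _motif_alpha(kind: str, yy, xx, cy, cx, m: MotifSpec, scale: float,
                 angle: float | None = None) -> np.ndarray:
    """Soft-edged coverage mask of one motif instance over the pixel grid."""
    if kind == "blob":
        dist = np.hypot(yy - cy, xx - cx)
        return np.clip(m.radius * scale + 0.5 - dist, 0.0, 1.0)
    if kind == "ring":
        dist = np.hypot(yy - cy, xx - cx)
        return np.clip(
            m.thickness * scale / 2 + 0.5 - np.abs(dist - m.radius * scale),
            0.0, 1.0,
        )
    if kind == "bar":
        return _bar_alpha(yy, xx, cy, cx, m.length * scale,
                          m.width * scale, angle)
    # cross: all orientations co-located; arm length stretched by width/2
    # so total covered area matches the separate-bars counterpart.
    arm = (m.length + m.width / 2) * scale
    alpha = np.zeros_like(yy)
    for a in m.orientations:
        alpha = np.maximum(
            alpha, _bar_alpha(yy, xx, cy, cx, arm, m.width * scale, a)
        )
    return alpha


def render_image(cfg: SyntheticConfig, class_index: int, scale: float,
                 rng: np.random.Generator):
    """Render one image; returns ``(image, centers)``.

    ``image`` is ``(size, size, 3)`` float in [0, 1]; ``centers`` the
    ``(count, 2)`` array of motif centers in (row, col) pixels, drawn
    uniformly over the full image.
    """
    size = cfg.image_size
    motif = cfg.motifs[class_index]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    bg = np.asarray(cfg.background) + rng.normal(0, cfg.color_jitter, 3)
    img = np.broadcast_to(bg, (size, size, 3)).copy()
    img += rng.normal(0, cfg.noise_std, img.shape)
    centers = rng.uniform(0, size, size=(motif.count, 2))
    # Variants (orientation and/or stain color): with "mixed" they
    # alternate within the image; with "pure" one variant is drawn per
    # image and used for all of its motifs.
    n_orient = len(motif.orientations) if motif.kind == "bar" else 1
    n_color = len(motif.colors) if motif.colors else 1
    n_variants = max(n_orient, n_color)
    if motif.arrangement == "pure" and n_variants > 1:
        fixed = int(rng.integers(n_variants))
        variants = [fixed] * motif.count
    else:
        variants = [i % n_variants for i in range(motif.count)]
    for (cy, cx), vi in zip(centers, variants):
        angle = motif.orientations[vi % n_orient] if motif.kind == "bar" \
            else None
        color = np.asarray(motif.colors[vi % n_color]) if motif.colors \
            else np.asarray(cfg.motif_color)
        alpha = _motif_alpha(motif.kind, yy, xx, cy, cx, motif, scale,
                             angle)
        alpha = alpha * cfg.opacity
        jitter = rng.normal(0, cfg.color_jitter, 3)
        img = img * (1 - alpha[:, :, None]) + (color + jitter) * alpha[:, :, None]
    return np.clip(img, 0.0, 1.0), centers


def generate_arrays(cfg: SyntheticConfig):
    """Generate the full dataset in memory.

    Returns a dict with ``images`` ``(N, size, size, 3)``, integer
    ``labels``, ``class_names``, per-image ``scales`` and
    ``scale_index``, and ``centers`` (list of per-image motif-center
    arrays).  Scales cycle per class so every class is balanced across
    pseudo-magnifications.
    """
    rng = np.random.default_rng(cfg.seed)
    images, labels, scales, scale_idx, centers = [], [], [], [], []
    for ci in range(cfg.n_classes):
        for j in range(cfg.images_per_class):
            si = j % len(cfg.scales)
            img, ctr = render_image(cfg, ci, cfg.scales[si], rng)
            images.append(img)
            labels.append(ci)
            scales.append(cfg.scales[si])
            scale_idx.append(si)
            centers.append(ctr)
    return {
        "images": np.stack(images),
        "labels": np.asarray(labels),
        "class_names": cfg.class_names,
        "scales": np.asarray(scales),
        "scale_index": np.asarray(scale_idx),
        "centers": centers,
    }


def generate_synthetic_dataset(cfg: SyntheticConfig,
                               out_dir) -> DatasetManifest:
    """Write the dataset as PNGs in the scannable layout plus a CSV.

    Layout: ``<class>/<class>/<mag>X/<class>_<index>.png`` where the
    pseudo-magnification encodes the scale; the manifest CSV mirrors
    :class:`~bilinearcnn.data.DatasetManifest` columns.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"cannot write to {out}")
    ds = generate_arrays(cfg)
    rows = []
    per_class_counter: dict[str, int] = {}
    for img, label, si in zip(ds["images"], ds["labels"],
                              ds["scale_index"]):
        name = ds["class_names"][label]
        idx = per_class_counter.get(name, 0)
        per_class_counter[name] = idx + 1
        mag = cfg.scale_magnification(si)
        dest = out / name / name / f"{mag}X"
        dest.mkdir(parents=True, exist_ok=True)
        path = dest / f"{name}_{idx:04d}.png"
        Image.fromarray(
            (img * 255).round().astype(np.uint8), mode="RGB"
        ).save(path)
        rows.append(
            {"path": str(path), "class_label": name, "subclass": name,
             "magnification": mag, "slide_id": f"{name}_{idx:04d}"}
        )
    df = pd.DataFrame(rows, columns=DatasetManifest.COLUMNS)
    manifest = DatasetManifest(df, task="fine_grained")
    manifest.to_csv(out / "manifest.csv")
    return manifest
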