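"""Dataset manifests, cross-validation folds, oversampling, preprocessing.

The on-disk input is a directory tree of RGB histology images laid out as
``<class>/<subclass>/<magnification>X/<image>`` (the layout used by the
BreaKHis breast-cancer dataset, possibly with extra intermediate slide
directories).  A :class:`DatasetManifest` is a thin wrapper over a pandas
DataFrame with one row per image: path, class label (benign/malignant),
subclass (the eight tumor subtypes), magnification factor, slide id and,
once assigned, a cross-validation fold index.

Splits are stratified by the task label at the image level (mirroring
random image-level division; a slide-grouped split is available for
leakage-safe evaluation).  Class imbalance is handled by oversampling:
minority classes are duplicated by sampling with replacement until every
class matches the majority count — applied to training folds only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold

__all__ = [
    "BENIGN_SUBCLASSES",
    "MALIGNANT_SUBCLASSES",
    "SUBCLASS_TO_CLASS",
    "TABLE1_COUNTS_40X",
    "MAGNIFICATIONS",
    "ImageRecord",
    "DatasetManifest",
    "AugmentParams",
    "scan_layout",
    "make_folds",
    "oversample",
    "augment",
    "preprocess",
    "load_images",
]

BENIGN_SUBCLASSES = (
    "adenosis",
    "fibroadenoma",
    "phyllodes_tumor",
    "tubular_adenoma",
)
MALIGNANT_SUBCLASSES = (
    "ductal_carcinoma",
    "lobular_carcinoma",
    "mucinous_carcinoma",
    "papillary_carcinoma",
)
SUBCLASS_TO_CLASS = {
    **{s: "benign" for s in BENIGN_SUBCLASSES},
    **{s: "malignant" for s in MALIGNANT_SUBCLASSES},
}

#: Per-subclass image counts at 40x magnification in BreaKHis.
TABLE1_COUNTS_40X = {
    "adenosis": 114,
    "fibroadenoma": 253,
    "phyllodes_tumor": 149,
    "tubular_adenoma": 109,
    "ductal_carcinoma": 864,
    "lobular_carcinoma": 156,
    "mucinous_carcinoma": 205,
    "papillary_carcinoma": 145,
}

MAGNIFICATIONS = (40, 100, 200, 400)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}
_MAG_DIR_RE = re.compile(r"^(\d+)\s*[xX]$")
# BreaKHis filename convention, e.g. SOB_B_A-14-22549AB-40-001.png
_BREAKHIS_NAME_RE = re.compile(
    r"^SOB_([BM])_([A-Z]+)[-_](\d+-[0-9A-Za-z]+)-(\d+)-(\d+)$"
)


@dataclass
class ImageRecord:
    """One image: its path and the labels parsed from the layout."""

    path: str
    class_label: str
    subclass: str
    magnification: int
    slide_id: str

    def validate_taxonomy(self) -> None:
        """Check benign/malignant consistency for the BreaKHis taxonomy."""
        expected = SUBCLASS_TO_CLASS.get(self.subclass)
        if expected is not None and expected != self.class_label:
            raise ValueError(
                f"subclass {self.subclass!r} belongs to {expected!r}, "
                f"not {self.class_label!r} ({self.path})"
            )


class DatasetManifest:
    """Ordered table of image records for one classification task.

    ``task`` selects the label set: ``"binary"`` uses the two-way
    class column, ``"fine_grained"`` the eight-way subclass column.
    """

    COLUMNS = ["path", "class_label", "subclass", "magnification", "slide_id"]

    def __init__(self, df: pd.DataFrame, task: str = "fine_grained",
                 magnification_filter: int | None = None,
                 errors: list[str] | None = None):
        if task not in ("binary", "fine_grained"):
            raise ValueError(f"unknown task {task!r}")
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if magnification_filter is not None:
            df = df[df["magnification"] == int(magnification_filter)]
        if len(df) == 0:
            raise ValueError("manifest is empty")
        self.df = df.reset_index(drop=True)
        self.task = task
        self.magnification_filter = magnification_filter
        self.errors = list(errors or [])

    def __len__(self) -> int:
        return len(self.df)

    @property
    def label_column(self) -> str:
        return "class_label" if self.task == "binary" else "subclass"

    def labels(self) -> np.ndarray:
        return self.df[self.label_column].to_numpy()

    def classes(self) -> list[str]:
        return sorted(self.df[self.label_column].unique())

    def with_folds(self, fold_index: np.ndarray) -> "DatasetManifest":
        df = self.df.copy()
        df["fold"] = np.asarray(fold_index, dtype=int)
        out = DatasetManifest(df, task=self.task, errors=self.errors)
        out.magnification_filter = self.magnification_filter
        return out

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, task: str = "fine_grained",
                 magnification_filter: int | None = None
                 ) -> "DatasetManifest":
        return cls(pd.read_csv(path), task=task,
                   magnification_filter=magnification_filter)


def _parse_image_path(path: Path, root: Path):
    """Extract (class, subclass, magnification, slide_id) from a path.

    Primary source is the directory structure
    ``class/subclass/<mag>X/...``; the BreaKHis filename convention is the
    fallback for magnification and slide id.
    """
    rel_parts = path.relative_to(root).parts
    mag = None
    mag_idx = None
    for i, part in enumerate(rel_parts[:-1]):
        m = _MAG_DIR_RE.match(part)
        if m:
            mag, mag_idx = int(m.group(1)), i
    name_match = _BREAKHIS_NAME_RE.match(path.stem)
    slide_id = name_match.group(3) if name_match else path.stem
    if mag is None and name_match:
        mag = int(name_match.group(4))
    if mag is None:
        raise ValueError("no magnification directory or filename tag")
    if mag_idx is not None and mag_idx >= 2:
        subclass = rel_parts[mag_idx - 1]
        # BreaKHis trees interpose slide directories between subclass and
        # magnification; recover the taxonomy level when so.
        if subclass not in SUBCLASS_TO_CLASS and mag_idx >= 3:
            if name_match is None:
                slide_id = rel_parts[mag_idx - 1]
            subclass = rel_parts[mag_idx - 2]
            if subclass not in SUBCLASS_TO_CLASS:
                subclass = rel_parts[1]
        class_label = rel_parts[0]
    elif mag_idx == 1:
        subclass = class_label = rel_parts[0]
    else:
        raise ValueError("cannot infer class/subclass from layout")
    # derive benign/malignant only when the top directory is not already a
    # class name (synthetic layouts use <class>/<class>/<mag>X)
    if class_label not in ("benign", "malignant"):
        class_label = SUBCLASS_TO_CLASS.get(subclass, class_label)
    return class_label, subclass, mag, slide_id


def scan_layout(root, task: str = "fine_grained",
                magnification_filter: int | None = None) -> DatasetManifest:
    """Build a manifest from a directory tree of images.

    One record per PNG/JPEG file, ordered lexicographically by path.
    Entries whose class/subclass/magnification cannot be parsed are
    collected on ``manifest.errors`` (with the reason), never silently
    dropped.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    rows = []
    errors: list[str] = []
    paths = sorted(
        p for p in root.rglob("*")
        if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES
    )
    for p in paths:
        try:
            class_label, subclass, mag, slide_id = _parse_image_path(p, root)
            rec = ImageRecord(str(p), class_label, subclass, mag, slide_id)
            rec.validate_taxonomy()
        except ValueError as exc:
            errors.append(f"{p}: {exc}")
            continue
        rows.append(
            {"path": rec.path, "class_label": rec.class_label,
             "subclass": rec.subclass, "magnification": rec.magnification,
             "slide_id": rec.slide_id}
        )
    if not rows:
        detail = f" ({len(errors)} unparseable entries)" if errors else ""
        raise ValueError(f"no images found under {root}{detail}")
    df = pd.DataFrame(rows, columns=DatasetManifest.COLUMNS)
    return DatasetManifest(df, task=task,
                           magnification_filter=magnification_filter,
                           errors=errors)


def make_folds(manifest: DatasetManifest, k: int = 5, seed: int = 0,
               group_by_slide: bool = False) -> np.ndarray:
    """Assign each record a fold index in ``[0, k)``.

    Folds partition the manifest and are stratified by the task label:
    per-fold class counts differ from perfect stratification by at most
    one.  ``group_by_slide`` keeps all images of a slide in one fold
    (leakage-safe variant; off by default to mirror image-level
    randomization).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels = manifest.labels()
    counts = pd.Series(labels).value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise ValueError(
            f"classes smaller than k={k}: {too_small.to_dict()}"
        )
    fold_index = np.full(len(labels), -1, dtype=int)
    if group_by_slide:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        splits = splitter.split(np.zeros(len(labels)), labels,
                                groups=manifest.df["slide_id"])
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
        splits = splitter.split(np.zeros(len(labels)), labels)
    for fold, (_, test_idx) in enumerate(splits):
        fold_index[test_idx] = fold
    assert (fold_index >= 0).all()
    return fold_index


def oversample(df: pd.DataFrame, label_column: str,
               seed: int = 0) -> pd.DataFrame:
    """Balance class frequencies by duplication with replacement.

    Every original row is kept; minority classes gain rows sampled with
    replacement from themselves until each class count equals the current
    majority count.  Intended for training folds only.
    """
    if label_column not in df.columns:
        raise ValueError(f"no column {label_column!r}")
    counts = df[label_column].value_counts()
    if (counts == 0).any() or len(counts) == 0:
        raise ValueError("every class must have at least one record")
    majority = counts.max()
    rng = np.random.default_rng(seed)
    extras = []
    for label, count in counts.items():
        deficit = int(majority - count)
        if deficit > 0:
            pool = df[df[label_column] == label]
            pick = rng.integers(0, len(pool), size=deficit)
            extras.append(pool.iloc[pick])
    if not extras:
        return df.reset_index(drop=True)
    return pd.concat([df, *extras], ignore_index=True)


@dataclass
class AugmentParams:
    """Ranges for the stochastic training-time transforms.

    Flips are applied with probability 0.5 when enabled; shifts are drawn
    uniformly from ``±shift_fraction`` of the image side per axis;
    rotation angle uniformly from ``±rotation_degrees``.
    """

    h_flip: bool = True
    v_flip: bool = True
    shift_fraction: float = 0.1
    rotation_degrees: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shift_fraction < 1.0):
            raise ValueError("shift_fraction must be in [0, 1)")
        if self.rotation_degrees < 0:
            raise ValueError("rotation_degrees must be >= 0")


def augment(image: np.ndarray, params: AugmentParams,
            rng: np.random.Generator) -> np.ndarray:
    """Randomly flip, translate and rotate an ``(H, W, 3)`` float image.

    The composition is fully determined by the generator state; shape and
    value range are preserved (nearest-edge fill, bilinear resampling).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image; got {img.shape}")
    lo, hi = float(img.min()), float(img.max())
    if params.h_flip and rng.random() < 0.5:
        img = img[:, ::-1]
    if params.v_flip and rng.random() < 0.5:
        img = img[::-1]
    if params.shift_fraction > 0:
        h, w = img.shape[:2]
        dy = rng.uniform(-params.shift_fraction, params.shift_fraction) * h
        dx = rng.uniform(-params.shift_fraction, params.shift_fraction) * w
        img = ndimage.shift(img, (dy, dx, 0), order=1, mode="nearest")
    if params.rotation_degrees > 0:
        angle = rng.uniform(-params.rotation_degrees,
                            params.rotation_degrees)
        img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False,
                             order=1, mode="nearest")
    return np.clip(np.ascontiguousarray(img), lo, hi)


def preprocess(image, size: int = 224) -> np.ndarray:
    """Decode, resize and scale an image to ``(size, size, 3)`` in [0, 1].

    Accepts a file path or an array/PIL image; grayscale inputs are
    promoted to three identical channels; resizing is bilinear.
    """
    if isinstance(image, (str, Path)):
        path = Path(image)
        try:
            with Image.open(path) as im:
                pil = im.convert("RGB")
        except Exception as exc:
            raise ValueError(f"cannot decode image {path}: {exc}") from exc
    elif isinstance(image, Image.Image):
        pil = image.convert("RGB")
    else:
        arr = np.asarray(image)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        if arr.dtype != np.uint8:
            arr = np.clip(arr, 0.0, 1.0)
            arr = (arr * 255).round().astype(np.uint8)
        pil = Image.fromarray(arr, mode="RGB")
    if pil.size != (size, size):
        pil = pil.resize((size, size), Image.BILINEAR)
    return np.asarray(pil, dtype=np.float64) / 255.0


def load_images(paths, size: int = 224) -> np.ndarray:
    """Stack preprocessed images into an ``(N, size, size, 3)`` batch."""
    return np.stack([preprocess(p, size=size) for p in paths])
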