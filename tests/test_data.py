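"""Manifest scanning, fold assignment, oversampling, preprocessing."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from bilinearcnn.data import (
    AugmentParams,
    DatasetManifest,
    SUBCLASS_TO_CLASS,
    TABLE1_COUNTS_40X,
    augment,
    make_folds,
    oversample,
    preprocess,
    scan_layout,
)


def _write_png(path: Path, size=(16, 16), value=120):
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.full(size + (3,), value, dtype=np.uint8)
    Image.fromarray(arr).save(path)


@pytest.fixture
def breakhis_tree(tmp_path):
    for i in range(2):
        _write_png(tmp_path / "benign" / "adenosis" / "40X" / f"img_{i}.png")
    _write_png(tmp_path / "malignant" / "ductal_carcinoma" / "400X"
               / "img_0.png")
    return tmp_path


class TestScanLayout:
    def test_parses_class_subclass_magnification(self, breakhis_tree):
        m = scan_layout(breakhis_tree)
        adeno = m.df[m.df.subclass == "adenosis"]
        assert len(adeno) == 2
        assert set(adeno.class_label) == {"benign"}
        assert set(adeno.magnification) == {40}

    def test_lexicographic_order_and_columns(self, breakhis_tree):
        m = scan_layout(breakhis_tree)
        assert list(m.df.path) == sorted(m.df.path)
        assert list(m.df.columns) == DatasetManifest.COLUMNS

    def test_empty_directory_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="no images"):
            scan_layout(tmp_path)

    def test_magnification_filter(self, breakhis_tree):
        m = scan_layout(breakhis_tree, magnification_filter=400)
        assert set(m.df.magnification) == {400}
        assert len(m) == 1

    def test_unparseable_entries_reported_not_dropped(self, tmp_path):
        _write_png(tmp_path / "benign" / "adenosis" / "40X" / "ok.png")
        _write_png(tmp_path / "stray.png")
        m = scan_layout(tmp_path)
        assert len(m) == 1
        assert len(m.errors) == 1 and "stray.png" in m.errors[0]

    def test_breakhis_slide_directories_supported(self, tmp_path):
        p = (tmp_path / "benign" / "adenosis" / "SOB_B_A_14-22549AB"
             / "40X" / "SOB_B_A-14-22549AB-40-001.png")
        _write_png(p)
        m = scan_layout(tmp_path)
        rec = m.df.iloc[0]
        assert rec.subclass == "adenosis"
        assert rec.magnification == 40
        assert rec.slide_id == "14-22549AB"

    def test_taxonomy_mismatch_collected_as_error(self, tmp_path):
        _write_png(tmp_path / "benign" / "ductal_carcinoma" / "40X" / "x.png")
        _write_png(tmp_path / "benign" / "adenosis" / "40X" / "ok.png")
        m = scan_layout(tmp_path)
        assert len(m) == 1
        assert any("ductal_carcinoma" in e for e in m.errors)


def random_manifest(rng, n_classes=3, n_per_class=None):
    rows = []
    for c in range(n_classes):
        count = (n_per_class if n_per_class is not None
                 else int(rng.integers(6, 20)))
        for i in range(count):
            rows.append({
                "path": f"/fake/c{c}_{i}.png", "class_label": f"class{c}",
                "subclass": f"class{c}", "magnification": 40,
                "slide_id": f"s{c}_{i % 3}",
            })
    return DatasetManifest(pd.DataFrame(rows))


class TestMakeFolds:
    def test_exact_divisibility_gives_one_per_class_per_fold(self, rng):
        m = random_manifest(rng, n_classes=2, n_per_class=5)
        folds = make_folds(m, k=5, seed=0)
        labels = m.labels()
        for f in range(5):
            mask = folds == f
            assert mask.sum() == 2
            assert len(set(labels[mask])) == 2

    def test_partition_and_stratification_bounds(self, rng):
        for trial in range(5):
            m = random_manifest(rng)
            k = 4
            folds = make_folds(m, k=k, seed=trial)
            assert len(folds) == len(m)
            assert set(folds) == set(range(k))
            labels = m.labels()
            for cls in np.unique(labels):
                per_fold = np.bincount(folds[labels == cls], minlength=k)
                assert per_fold.max() - per_fold.min() <= 1

    def test_same_seed_reproducible(self, rng):
        m = random_manifest(rng)
        np.testing.assert_array_equal(make_folds(m, k=5, seed=3),
                                      make_folds(m, k=5, seed=3))

    def test_class_smaller_than_k_rejected(self, rng):
        m = random_manifest(rng, n_classes=2, n_per_class=3)
        with pytest.raises(ValueError, match="smaller than k"):
            make_folds(m, k=5, seed=0)

    def test_group_by_slide_keeps_slides_together(self, rng):
        m = random_manifest(rng, n_classes=2, n_per_class=12)
        folds = make_folds(m, k=3, seed=0, group_by_slide=True)
        df = m.df.assign(fold=folds)
        assert (df.groupby("slide_id").fold.nunique() == 1).all()


class TestOversample:
    def test_minority_duplicated_to_majority(self, rng):
        df = pd.DataFrame({
            "path": [f"p{i}" for i in range(10)],
            "label": ["benign"] * 3 + ["malignant"] * 7,
        })
        out = oversample(df, "label", seed=0)
        counts = out.label.value_counts()
        assert counts["benign"] == 7 and counts["malignant"] == 7

    def test_balanced_input_unchanged(self):
        df = pd.DataFrame({"path": list("abcd"), "label": list("xxyy")})
        out = oversample(df, "label", seed=0)
        assert sorted(out.path) == sorted(df.path)

    def test_never_discards_originals(self, rng):
        df = pd.DataFrame({
            "path": [f"p{i}" for i in range(12)],
            "label": ["a"] * 2 + ["b"] * 10,
        })
        out = oversample(df, "label", seed=1)
        assert set(df.path) <= set(out.path)

    def test_breakhis_40x_counts_equalize_to_majority(self):
        rows = []
        for sub, n in TABLE1_COUNTS_40X.items():
            for i in range(n):
                rows.append({"path": f"{sub}/{i}.png",
                             "class_label": SUBCLASS_TO_CLASS[sub],
                             "subclass": sub})
        df = pd.DataFrame(rows)
        out = oversample(df, "subclass", seed=0)
        counts = out.subclass.value_counts()
        assert set(counts) == {864}
        assert len(out) == 864 * 8


class TestAugment:
    def test_disabled_transforms_are_identity(self, rng):
        img = rng.uniform(size=(20, 20, 3))
        params = AugmentParams(h_flip=False, v_flip=False,
                               shift_fraction=0.0, rotation_degrees=0.0)
        np.testing.assert_array_equal(augment(img, params, rng), img)

    def test_horizontal_flip_is_involution(self, rng):
        img = rng.uniform(size=(16, 16, 3))
        params = AugmentParams(h_flip=True, v_flip=False, shift_fraction=0.0,
                               rotation_degrees=0.0)
        # same generator state both times -> same flip decision
        out1 = augment(img, params, np.random.default_rng(99))
        out2 = augment(out1, params, np.random.default_rng(99))
        np.testing.assert_array_equal(out2, img)

    def test_fixed_seed_bitwise_reproducible(self, rng):
        img = rng.uniform(size=(24, 24, 3))
        params = AugmentParams()
        a = augment(img, params, np.random.default_rng(5))
        b = augment(img, params, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_shape_and_range_preserved(self, rng):
        img = rng.uniform(size=(32, 32, 3))
        out = augment(img, AugmentParams(), np.random.default_rng(1))
        assert out.shape == img.shape
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            AugmentParams(shift_fraction=1.5)
        with pytest.raises(ValueError):
            AugmentParams(rotation_degrees=-5)


class TestPreprocess:
    def test_resize_to_target(self, tmp_path):
        path = tmp_path / "img.png"
        arr = np.random.default_rng(0).integers(0, 255, (460, 700, 3))
        Image.fromarray(arr.astype(np.uint8)).save(path)
        out = preprocess(path, size=224)
        assert out.shape == (224, 224, 3)
        assert 0.0 <= out.min() and out.max() <= 1.0

    def test_native_resolution_passthrough(self, tmp_path):
        path = tmp_path / "img.png"
        arr = np.random.default_rng(1).integers(0, 255, (32, 32, 3))
        Image.fromarray(arr.astype(np.uint8)).save(path)
        out = preprocess(path, size=32)
        np.testing.assert_allclose(out, arr / 255.0)

    def test_grayscale_promoted_to_three_channels(self, tmp_path):
        path = tmp_path / "gray.png"
        arr = np.random.default_rng(2).integers(0, 255, (20, 20))
        Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
        out = preprocess(path, size=20)
        assert out.shape == (20, 20, 3)
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 1])

    def test_corrupt_file_error_names_path(self, tmp_path):
        path = tmp_path / "broken.png"
        path.write_bytes(b"not a png")
        with pytest.raises(ValueError, match="broken.png"):
            preprocess(path)
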