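import numpy as np
import pytest
from PIL import Image

from histoclust import (
    BENIGN,
    MALIGNANT,
    LabeledDataset,
    SyntheticParams,
    generate_synthetic_dataset,
    load_image_directory,
    save_dataset,
    stratified_split,
)
from histoclust.data import pixel_mean_threshold_accuracy


class TestSyntheticGenerator:
    def test_imbalanced_prevalence_reproducible(self):
        """Labels follow a seeded Bernoulli draw at ~70% malignant prevalence."""
        ds = generate_synthetic_dataset(
            SyntheticParams(n_images=100, malignant_fraction=0.686, seed=7)
        )
        assert len(ds) == 100
        # binomial draw, frozen for this seed; close to the 68.6% prevalence
        assert ds.n_malignant == 74

    def test_pixels_in_unit_range_even_without_noise(self):
        ds = generate_synthetic_dataset(
            SyntheticParams(n_images=10, malignant_fraction=0.5, noise_sd=0.0, seed=1)
        )
        assert len(ds) == 10
        assert ds.images.shape == (10, 32, 32, 3)
        assert ds.images.min() >= 0.0 and ds.images.max() <= 1.0

    def test_identical_params_give_bitwise_identical_datasets(self):
        p = SyntheticParams(n_images=30, seed=5)
        a = generate_synthetic_dataset(p)
        b = generate_synthetic_dataset(p)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.labels, b.labels)

    def test_both_classes_always_present(self):
        ds = generate_synthetic_dataset(
            SyntheticParams(n_images=5, malignant_fraction=0.99, seed=0)
        )
        assert ds.n_benign >= 1 and ds.n_malignant >= 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"malignant_fraction": 0.0},
            {"malignant_fraction": 1.0},
            {"n_images": 0},
            {"nucleus_radius_range": (0.5, 3.0)},
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticParams(**kwargs)

    def test_separability_dial(self, separable_ds):
        """Noise-free classes with disjoint colour means: a pixel-mean
        threshold classifier is perfect, so the data are separable."""
        assert pixel_mean_threshold_accuracy(separable_ds) == 100.0

    def test_malignant_tiles_are_darker_and_busier(self, separable_ds):
        mal = separable_ds.images[separable_ds.labels == MALIGNANT]
        ben = separable_ds.images[separable_ds.labels == BENIGN]
        assert mal.mean() < ben.mean()


class TestDirectoryLoading:
    def _write_png(self, path, size=(40, 30), value=128, mode="RGB"):
        arr = np.full((size[1], size[0], 3), value, dtype=np.uint8)
        img = Image.fromarray(arr).convert(mode)
        img.save(path)

    def test_flat_layout_counts_and_labels(self, tmp_path):
        (tmp_path / "benign").mkdir()
        (tmp_path / "malignant").mkdir()
        for i in range(2):
            self._write_png(tmp_path / "benign" / f"b{i}.png", value=200)
        for i in range(3):
            self._write_png(tmp_path / "malignant" / f"m{i}.png", value=60)
        ds = load_image_directory(tmp_path)
        assert len(ds) == 5
        assert ds.n_benign == 2 and ds.n_malignant == 3

    def test_full_size_slide_tile_resized_to_32(self, tmp_path):
        (tmp_path / "benign").mkdir()
        (tmp_path / "malignant").mkdir()
        self._write_png(tmp_path / "benign" / "big.png", size=(760, 460))
        self._write_png(tmp_path / "benign" / "b2.png")
        self._write_png(tmp_path / "malignant" / "m.png")
        ds = load_image_directory(tmp_path)
        assert ds.images.shape[1:] == (32, 32, 3)

    def test_grayscale_replicated_to_three_channels(self, tmp_path):
        (tmp_path / "benign").mkdir()
        (tmp_path / "malignant").mkdir()
        self._write_png(tmp_path / "benign" / "g.png", mode="L", value=100)
        self._write_png(tmp_path / "malignant" / "m.png")
        ds = load_image_directory(tmp_path)
        gray = ds.images[0]
        assert np.array_equal(gray[..., 0], gray[..., 1])
        assert np.array_equal(gray[..., 1], gray[..., 2])

    def test_unreadable_file_skipped_with_warning(self, tmp_path, caplog):
        (tmp_path / "benign").mkdir()
        (tmp_path / "malignant").mkdir()
        self._write_png(tmp_path / "benign" / "ok.png")
        (tmp_path / "benign" / "broken.png").write_text("not an image")
        self._write_png(tmp_path / "malignant" / "m.png")
        with caplog.at_level("WARNING"):
            ds = load_image_directory(tmp_path)
        assert len(ds) == 2
        assert any("skipping unreadable" in r.message for r in caplog.records)

    def test_empty_class_is_an_error(self, tmp_path):
        (tmp_path / "benign").mkdir()
        self._write_png(tmp_path / "benign" / "b.png")
        with pytest.raises(ValueError, match="malignant"):
            load_image_directory(tmp_path)

    def test_breakhis_layout_selects_magnification(self, tmp_path):
        for cls in ("benign", "malignant"):
            for mag in ("40x", "100x"):
                d = tmp_path / cls / mag
                d.mkdir(parents=True)
                self._write_png(d / f"{cls}_{mag}.png")
        ds = load_image_directory(tmp_path, layout="breakhis", magnification="40x")
        assert len(ds) == 2
        assert ds.magnification_tag == "40x"
        with pytest.raises(ValueError):
            load_image_directory(tmp_path, layout="breakhis")

    def test_save_then_load_roundtrip(self, tmp_path):
        ds = generate_synthetic_dataset(SyntheticParams(n_images=6, seed=3))
        out = tmp_path / "tiles"
        manifest = save_dataset(ds, out)
        assert manifest.exists()
        loaded = load_image_directory(out)
        assert len(loaded) == len(ds)
        assert loaded.n_benign == ds.n_benign
        # 8-bit PNG round trip keeps intensities to within 1/255
        assert abs(loaded.images.mean() - ds.images.mean()) <= 1.0 / 255


class TestStratifiedSplit:
    def test_proportional_counts(self):
        labels = np.array([MALIGNANT] * 70 + [BENIGN] * 30)
        ds = LabeledDataset(np.zeros((100, 32, 32, 3)), labels)
        train, test = stratified_split(ds, 0.3, seed=0)
        assert len(test) == 30 and len(train) == 70
        assert test.n_malignant == 21 and test.n_benign == 9

    def test_even_split_of_balanced_data(self):
        ds = LabeledDataset(np.zeros((8, 32, 32, 3)), np.array([0, 1] * 4))
        train, test = stratified_split(ds, 0.5, seed=1)
        assert train.n_benign == train.n_malignant == 2
        assert test.n_benign == test.n_malignant == 2

    def test_disjoint_and_exhaustive(self, separable_ds):
        ds = separable_ds
        marker = np.arange(len(ds), dtype=float)
        tagged = LabeledDataset(
            np.broadcast_to(marker[:, None, None, None] / len(ds),
                            ds.images.shape).copy(),
            ds.labels,
        )
        train, test = stratified_split(tagged, 0.3, seed=2)
        ids_train = set(np.round(train.images[:, 0, 0, 0] * len(ds)).astype(int))
        ids_test = set(np.round(test.images[:, 0, 0, 0] * len(ds)).astype(int))
        assert ids_train.isdisjoint(ids_test)
        assert len(ids_train | ids_test) == len(ds)

    def test_seed_determinism(self, separable_ds):
        a = stratified_split(separable_ds, 0.3, seed=9)
        b = stratified_split(separable_ds, 0.3, seed=9)
        assert np.array_equal(a[0].images, b[0].images)
        assert np.array_equal(a[1].labels, b[1].labels)

    def test_tiny_class_rejected(self):
        ds = LabeledDataset(np.zeros((5, 32, 32, 3)), np.array([0, 1, 1, 1, 1]))
        with pytest.raises(ValueError, match="benign"):
            stratified_split(ds, 0.4, seed=0)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_bad_fraction_rejected(self, frac):
        ds = LabeledDataset(np.zeros((8, 32, 32, 3)), np.array([0, 1] * 4))
        with pytest.raises(ValueError):
            stratified_split(ds, frac, seed=0)
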