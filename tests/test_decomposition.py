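"""Material-decomposition network: bookkeeping, training, application."""

import numpy as np
import pytest

from pcct.decomposition import (
    MLPModel,
    ModelFormatError,
    TrainingConfig,
    TrainingSet,
    decompose,
    extract_training_set,
    load_model,
    save_model,
    train,
)
from pcct.phantoms import ROISpec


def _square_rois(n_rois, materials=None, concs=None, spacing_mm=12.0):
    rois = []
    for i in range(n_rois):
        mat = materials[i] if materials else None
        conc = concs[i] if concs else None
        rois.append(ROISpec(f"roi{i}", ((i - n_rois / 2) * spacing_mm, 0.0),
                            5.0, role="training-material", material=mat,
                            concentration_mg_ml=conc))
    return rois


def _images(n_bins, n=625, pixel_mm=0.4, seed=0):
    rng = np.random.default_rng(seed)
    return [rng.normal(50.0, 5.0, size=(n, n)) for _ in range(n_bins)]


class TestExtraction:
    def test_canonical_nine_roi_count(self):
        """9 ROIs x 25x25 px x 3 bins = 16,875 scalar training units."""
        ts = extract_training_set(
            _images(3), _square_rois(9, ["iodine"] * 9, [1.0] * 9))
        assert ts.n_scalar_units == 16875
        assert ts.n_samples == 5625
        assert ts.n_bins == 3

    def test_single_roi_single_bin(self):
        ts = extract_training_set(_images(1), _square_rois(1, ["iodine"],
                                                           [1.0]))
        assert ts.n_scalar_units == 625

    def test_water_roi_maps_to_zero_vector(self):
        ts = extract_training_set(
            _images(3), _square_rois(2, ["water", "iodine"], [None, 5.0]))
        assert np.all(ts.labels[:625] == 0.0)

    def test_concentration_scaled_targets(self):
        """Solute targets scale with concentration relative to the max."""
        rois = _square_rois(3, ["iodine"] * 3, [2.0, 5.0, 10.0])
        ts = extract_training_set(_images(3), rois)
        iod = ts.labels[:, 0].reshape(3, 625)
        np.testing.assert_allclose(iod.mean(axis=1), [0.2, 0.5, 1.0])

    def test_roi_outside_image_rejected(self):
        roi = ROISpec("out", (200.0, 0.0), 5.0, material="iodine")
        with pytest.raises(ValueError, match="outside"):
            extract_training_set(_images(3, n=64), [roi])


class TestTraining:
    def _separable_set(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal([10.0, 5.0, 1.0], 0.5, size=(n, 3))
        b = rng.normal([1.0, 5.0, 10.0], 0.5, size=(n, 3))
        X = np.concatenate([a, b])
        Y = np.zeros((2 * n, 4))
        Y[:n, 0] = 1.0
        Y[n:, 1] = 1.0
        return TrainingSet(X, Y)

    def test_loss_decreases(self):
        ts = self._separable_set()
        _, loss = train(ts, TrainingConfig(epochs=300, hidden_width=8))
        assert loss[-1] < loss[0]

    def test_zero_learning_rate_freezes_weights(self):
        ts = self._separable_set()
        m0, loss0 = train(ts, TrainingConfig(learning_rate=0.0, epochs=5,
                                             hidden_width=8, seed=3))
        m1, _ = train(ts, TrainingConfig(learning_rate=0.0, epochs=1,
                                         hidden_width=8, seed=3))
        for W0, W1 in zip(m0.weights, m1.weights):
            np.testing.assert_array_equal(W0, W1)
        assert np.ptp(loss0) == 0.0

    def test_deterministic_given_seed(self):
        ts = self._separable_set()
        cfg = TrainingConfig(epochs=50, hidden_width=8, seed=11)
        m0, l0 = train(ts, cfg)
        m1, l1 = train(ts, cfg)
        np.testing.assert_array_equal(l0, l1)
        for W0, W1 in zip(m0.weights, m1.weights):
            np.testing.assert_array_equal(W0, W1)

    def test_linearly_realizable_map_fits_tightly(self):
        """Targets that are a linear function of the features are learned
        to near-zero MSE."""
        rng = np.random.default_rng(5)
        X = rng.normal(0.0, 1.0, size=(400, 3))
        A = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, -0.5]])
        Y = X @ A
        ts = TrainingSet(X, Y, materials=("iodine", "calcium"))
        _, loss = train(ts, TrainingConfig(learning_rate=0.002, epochs=800,
                                           hidden_width=16, seed=1))
        assert loss[-1] < 1e-3

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(100, 3))
        Y = np.zeros((100, 4))
        with pytest.raises(ValueError, match="degenerate"):
            train(TrainingSet(X, Y), TrainingConfig(epochs=1))


class TestDecompose:
    def test_output_shape_625_by_625_by_4(self):
        rng = np.random.default_rng(2)
        model, _ = train(TestTraining()._separable_set(),
                         TrainingConfig(epochs=20, hidden_width=8))
        maps = decompose([rng.normal(size=(625, 625)) for _ in range(3)],
                         model)
        assert maps.scores.shape == (625, 625, 4)

    def test_zero_input_zero_bias_gives_zero_maps(self):
        rng = np.random.default_rng(0)
        widths = [3, 8, 8, 8, 8, 8, 8, 8, 8, 4]
        Ws = tuple(rng.normal(size=(a, b))
                   for a, b in zip(widths[:-1], widths[1:]))
        bs = tuple(np.zeros(b) for b in widths[1:])
        model = MLPModel(Ws, bs, feat_mean=np.zeros(3), feat_std=np.ones(3))
        maps = decompose([np.zeros((16, 16))] * 3, model)
        np.testing.assert_array_equal(maps.scores, 0.0)

    def test_bin_count_mismatch_rejected(self):
        model, _ = train(TestTraining()._separable_set(),
                         TrainingConfig(epochs=5, hidden_width=8))
        with pytest.raises(ValueError, match="bins"):
            decompose([np.zeros((8, 8))] * 2, model)

    def test_training_roi_argmax_closure(self, noiseless_insert_run):
        """Applied back to its own noiseless training pixels, the model's
        argmax channel matches the ROI's material almost everywhere."""
        from pcct.decomposition import ROI_SIDE, _roi_square_slices

        info = noiseless_insert_run
        maps = decompose(
            [info["images"][f"bin{b}"] for b in (1, 2, 3)], info["model"])
        am = maps.argmax_map()
        correct = total = 0
        for roi in info["rois"]:
            if roi.material in (None, "water"):
                continue
            rs, cs = _roi_square_slices(am.shape, roi,
                                        maps.pixel_mm, ROI_SIDE)
            idx = maps.materials.index(roi.material)
            correct += (am[rs, cs] == idx).sum()
            total += am[rs, cs].size
        assert correct / total >= 0.99

    def test_iodine_score_monotone_in_concentration(self,
                                                    noiseless_insert_run):
        """Mean iodine score rises strictly with true concentration."""
        from pcct.decomposition import ROI_SIDE, _roi_square_slices

        info = noiseless_insert_run
        maps = decompose(
            [info["images"][f"bin{b}"] for b in (1, 2, 3)], info["model"])
        iod = maps.iodine_map
        means = []
        for roi in sorted(
            (r for r in info["rois"] if r.material == "iodine"),
            key=lambda r: r.concentration_mg_ml,
        ):
            rs, cs = _roi_square_slices(iod.shape, roi, maps.pixel_mm,
                                        ROI_SIDE)
            means.append(iod[rs, cs].mean())
        assert len(means) >= 3
        assert all(a < b for a, b in zip(means, means[1:])), means


class TestPersistence:
    def test_save_load_forward_identical(self, tmp_path):
        ts = TestTraining()._separable_set()
        model, _ = train(ts, TrainingConfig(epochs=30, hidden_width=8))
        path = tmp_path / "model.h5"
        save_model(model, path)
        back = load_model(path)
        X = np.random.default_rng(1).normal(size=(50, 3))
        np.testing.assert_array_equal(back.forward(X), model.forward(X))
        assert back.materials == model.materials

    def test_reloaded_model_reproduces_heldout_loss(self, tmp_path):
        ts = TestTraining()._separable_set(seed=0)
        held = TestTraining()._separable_set(seed=9)
        model, _ = train(ts, TrainingConfig(epochs=30, hidden_width=8,
                                            seed=4))
        save_model(model, tmp_path / "m.h5")
        back = load_model(tmp_path / "m.h5")
        loss_a = np.mean((model.forward(held.features) - held.labels) ** 2)
        loss_b = np.mean((back.forward(held.features) - held.labels) ** 2)
        assert loss_a == loss_b

    def test_corrupted_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.h5"
        bad.write_bytes(b"this is not an HDF5 model file")
        with pytest.raises(ModelFormatError):
            load_model(bad)
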