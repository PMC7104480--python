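import numpy as np
import pytest

from epitensor import EpiTensorModel, ModelConfig, TrainingConfig
from epitensor.grid import GenomicGrid
from epitensor import training
from epitensor.training import (Adam, TrackSet, fit_new_entity, fit_stage1,
                                fit_stage2, initialize, make_track_folds,
                                sample_epoch, train_step)


def _param_bytes(model, keys):
    return {k: model.params[k].tobytes() for k in keys}


class TestSampleEpoch:
    def test_each_bin_exactly_once(self):
        rng = np.random.default_rng(0)
        chrom_ids, bins, tracks, names = sample_epoch(
            [("c", 0, 4)], [("x", "y")], rng)
        assert sorted(bins) == [0, 1, 2, 3]
        assert len(tracks) == 4

    def test_track_frequencies_uniform(self):
        rng = np.random.default_rng(1)
        counts = np.zeros(2)
        for _ in range(10_000):
            _, _, t, _ = sample_epoch([("c", 0, 1)], ["t0", "t1"], rng)
            counts[t[0]] += 1
        assert counts[0] / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_deterministic_given_seed(self):
        out1 = sample_epoch([("c", 0, 100)], ["a", "b"],
                            np.random.default_rng(7))
        out2 = sample_epoch([("c", 0, 100)], ["a", "b"],
                            np.random.default_rng(7))
        np.testing.assert_array_equal(out1[1], out2[1])
        np.testing.assert_array_equal(out1[2], out2[2])

    def test_empty_track_set(self):
        with pytest.raises(ValueError):
            sample_epoch([("c", 0, 4)], [], np.random.default_rng(0))


class TestAdam:
    def test_first_step_is_lr_times_sign(self):
        cfg = TrainingConfig(seed=0)
        adam = Adam(cfg)
        params = {"p": np.array([1.0], dtype=np.float32)}
        grads = {"p": np.array([2.0], dtype=np.float32)}  # d(p^2)/dp at 1
        adam.step(params, grads, {"p"})
        assert params["p"][0] == pytest.approx(1.0 - cfg.learning_rate,
                                               rel=1e-3)

    def test_zero_learning_rate_is_noop(self):
        adam = Adam(TrainingConfig(seed=0))
        adam.lr = 0.0
        params = {"p": np.array([1.0], dtype=np.float32)}
        adam.step(params, {"p": np.array([5.0], dtype=np.float32)}, {"p"})
        assert params["p"][0] == 1.0

    def test_untrainable_keys_untouched(self):
        adam = Adam(TrainingConfig(seed=0))
        params = {"p": np.array([1.0], dtype=np.float32),
                  "q": np.array([1.0], dtype=np.float32)}
        grads = {"p": np.array([1.0], dtype=np.float32),
                 "q": np.array([1.0], dtype=np.float32)}
        before = params["q"].tobytes()
        adam.step(params, grads, {"p"})
        assert params["q"].tobytes() == before
        assert params["p"][0] != 1.0


class TestInitialize:
    def test_embedding_range_and_mean(self, grid):
        cfg = ModelConfig(n_cell_factors=64, n_assay_factors=64, n_g25=64,
                          n_g250=8, n_g5k=8, n_hidden_units=8)
        model = EpiTensorModel(cfg, grid, [f"c{i}" for i in range(40)], ["a"])
        initialize(model, seed=3)
        emb = model.params[("g25", "chr1")]
        assert emb.min() >= -0.5 and emb.max() <= 0.5
        draws = np.concatenate([model.params[("g25", c)].ravel()
                                for c in grid.chrom_names])
        assert abs(draws.mean()) < 3 * 0.2887 / np.sqrt(draws.size) * 3

    def test_biases_zero_and_reproducible(self, grid):
        cfg = ModelConfig(n_cell_factors=2, n_assay_factors=2, n_g25=2,
                          n_g250=2, n_g5k=2, n_hidden_units=4)
        m1 = initialize(EpiTensorModel(cfg, grid, ["a"], ["b"]), seed=9)
        m2 = initialize(EpiTensorModel(cfg, grid, ["a"], ["b"]), seed=9)
        assert np.all(m1.params["b1"] == 0)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_glorot_limit(self, tiny_model):
        W1 = tiny_model.params["W1"]
        limit = np.sqrt(6.0 / sum(W1.shape))
        assert np.abs(W1).max() <= limit


class TestTrainStep:
    def test_masked_parameters_bit_identical(self, tiny_model):
        trainable = {"cell"}
        frozen_keys = [k for k in tiny_model.params if k != "cell"]
        before = _param_bytes(tiny_model, frozen_keys)
        adam = Adam(TrainingConfig(seed=0))
        batch = ("chr1", np.array([0, 1]), np.array([0, 1]),
                 np.array([3, 7]))
        train_step(tiny_model, batch, np.array([1.0, 2.0]), adam, trainable)
        after = _param_bytes(tiny_model, frozen_keys)
        assert before == after
        assert tiny_model.params["cell"].tobytes() != 0

    def test_empty_trainable_is_noop(self, tiny_model):
        before = _param_bytes(tiny_model, list(tiny_model.params))
        adam = Adam(TrainingConfig(seed=0))
        batch = ("chr1", np.array([0]), np.array([0]), np.array([3]))
        train_step(tiny_model, batch, np.array([1.0]), adam, set())
        assert _param_bytes(tiny_model, list(tiny_model.params)) == before

    def test_loss_decreases_on_repeated_steps(self, tiny_model):
        adam = Adam(TrainingConfig(seed=0))
        batch = ("chr1", np.array([0, 1, 0]), np.array([0, 1, 2]),
                 np.array([3, 7, 11]))
        targets = np.array([1.0, 2.0, 0.5])
        trainable = set(tiny_model.params)
        losses = [train_step(tiny_model, batch, targets, adam, trainable)
                  for _ in range(50)]
        assert losses[-1] < losses[0]


class TestTrackFolds:
    def test_sizes_and_partition(self):
        tracks = [(f"c{i}", "a") for i in range(10)]
        folds = make_track_folds(tracks, k=5, seed=0)
        assert all(len(f) == 2 for f in folds)
        flat = [t for f in folds for t in f]
        assert sorted(flat) == sorted(tracks)

    def test_same_seed_same_split(self):
        tracks = [(f"c{i}", "a") for i in range(13)]
        assert make_track_folds(tracks, 5, seed=4) == \
            make_track_folds(tracks, 5, seed=4)

    def test_k_exceeds_tracks(self):
        with pytest.raises(ValueError):
            make_track_folds([("a", "b")], k=5, seed=0)


@pytest.fixture
def micro_setup():
    """2 cells x 2 assays x 200 bins, fully observed."""
    grid = GenomicGrid(("c",), (200 * 25,))
    rng = np.random.default_rng(0)
    ts = TrackSet(grid)
    base = rng.uniform(0, 2, 200)
    for ci in range(2):
        for ai in range(2):
            ts.add(f"c{ci}", f"a{ai}", "c",
                   base * (1 + 0.3 * ci) * (1 + 0.2 * ai))
    cfg = ModelConfig(n_cell_factors=4, n_assay_factors=4, n_g25=4,
                      n_g250=2, n_g5k=2, n_hidden_units=16)
    model = initialize(EpiTensorModel(cfg, grid, ts.cells, ts.assays), seed=1)
    return ts, model


class TestStages:
    def test_stage1_descends_and_reproducible(self, micro_setup):
        ts, model = micro_setup
        tc = TrainingConfig(epochs_stage1=40, batch_size=200, seed=2)
        hist = fit_stage1(ts, [("c", 0, 200)], model, tc)
        assert hist[-1] < hist[0]
        model2 = initialize(EpiTensorModel(model.config, model.grid,
                                           ts.cells, ts.assays), seed=1)
        hist2 = fit_stage1(ts, [("c", 0, 200)], model2, tc)
        assert hist == hist2

    def test_stage1_changes_every_parameter_group(self, micro_setup):
        ts, model = micro_setup
        before = {k: v.copy() for k, v in model.params.items()}
        fit_stage1(ts, [("c", 0, 200)], model,
                   TrainingConfig(epochs_stage1=10, batch_size=200, seed=2))
        for key in ("cell", "assay", ("g25", "c"), "W1", "Wout"):
            assert not np.array_equal(model.params[key], before[key])

    def test_stage2_freeze_is_byte_exact(self, micro_setup):
        ts, model = micro_setup
        tc = TrainingConfig(epochs_stage1=10, epochs_stage2=10,
                            batch_size=200, seed=2)
        fit_stage1(ts, [("c", 0, 100)], model, tc)
        frozen = ["cell", "assay"] + model.dnn_keys()
        before = _param_bytes(model, frozen)
        hist = fit_stage2(ts, "c", model, tc)
        assert _param_bytes(model, frozen) == before
        assert len(hist) == 10

    def test_stage2_improves_reconstruction(self, micro_setup):
        ts, model = micro_setup
        tc = TrainingConfig(epochs_stage1=60, epochs_stage2=60,
                            batch_size=200, seed=2)
        fit_stage1(ts, [("c", 0, 100)], model, tc)

        def recon_mse():
            bins = np.arange(200)
            errs = []
            for c, a in ts.tracks():
                pred = model.predict(c, a, "c", bins)
                errs.append(np.mean((pred - ts.values(c, a, "c")) ** 2))
            return np.mean(errs)

        before = recon_mse()
        fit_stage2(ts, "c", model, tc)
        assert recon_mse() < before

    def test_unknown_chromosome(self, micro_setup):
        ts, model = micro_setup
        with pytest.raises(KeyError):
            fit_stage2(ts, "chrNope", model, TrainingConfig(seed=0))

    def test_region_outside_grid(self, micro_setup):
        ts, model = micro_setup
        with pytest.raises(ValueError):
            fit_stage1(ts, [("c", 0, 500)], model, TrainingConfig(seed=0))

    def test_chromosome_order_commutes(self):
        grid = GenomicGrid(("cA", "cB"), (100 * 25, 120 * 25))
        rng = np.random.default_rng(3)
        ts = TrackSet(grid)
        for ci in range(2):
            for chrom, n in (("cA", 100), ("cB", 120)):
                ts.add(f"c{ci}", "a0", chrom, rng.uniform(0, 2, n))
        cfg = ModelConfig(n_cell_factors=2, n_assay_factors=2, n_g25=2,
                          n_g250=2, n_g5k=2, n_hidden_units=8)
        tc = TrainingConfig(epochs_stage1=5, epochs_stage2=5,
                            batch_size=64, seed=4)

        def run(order):
            m = initialize(EpiTensorModel(cfg, grid, ts.cells, ts.assays),
                           seed=5)
            fit_stage1(ts, [("cA", 0, 50)], m, tc)
            for chrom in order:
                fit_stage2(ts, chrom, m, tc)
            return m

        m1, m2 = run(["cA", "cB"]), run(["cB", "cA"])
        for key in m1.params:
            np.testing.assert_array_equal(m1.params[key], m2.params[key])


class TestFitNewEntity:
    def test_twin_cell_recovers_predictions(self, small_compendium,
                                            trained_model):
        comp = small_compendium
        twin_ts = TrackSet(comp.grid)
        source = comp.cells[0]
        for assay in comp.assays[:2]:
            twin_ts.add("TWIN", assay, "chrS",
                        comp.tracks.values(source, assay, "chrS"))
        tc = TrainingConfig(batch_size=10_000, epochs_stage2=100, seed=8)
        extended = fit_new_entity(trained_model, "cell", "TWIN", twin_ts, tc)
        bins = np.arange(comp.grid.n_bins_25("chrS"))
        for assay in comp.assays:
            orig = extended.predict(source, assay, "chrS", bins)
            twin = extended.predict("TWIN", assay, "chrS", bins)
            assert np.mean((orig - twin) ** 2) < 0.1 * np.var(orig) + 0.01

    def test_existing_parameters_and_predictions_unchanged(
            self, small_compendium, trained_model):
        comp = small_compendium
        ts = TrackSet(comp.grid)
        ts.add("NEW", comp.assays[0], "chrS",
               comp.tracks.values(comp.cells[1], comp.assays[0], "chrS"))
        before = trained_model.predict(comp.cells[0], comp.assays[0], "chrS",
                                       np.arange(100))
        extended = fit_new_entity(trained_model, "cell", "NEW", ts,
                                  TrainingConfig(batch_size=10_000,
                                                 epochs_stage2=5, seed=8))
        np.testing.assert_array_equal(
            extended.params["cell"][:-1], trained_model.params["cell"])
        for key in extended.params:
            if key == "cell":
                continue
            assert extended.params[key].tobytes() == \
                trained_model.params[key].tobytes()
        after = extended.predict(comp.cells[0], comp.assays[0], "chrS",
                                 np.arange(100))
        np.testing.assert_array_equal(np.asarray(before), np.asarray(after))

    def test_single_track_suffices(self, small_compendium, trained_model):
        comp = small_compendium
        ts = TrackSet(comp.grid)
        ts.add("SOLO", comp.assays[0], "chrS",
               comp.tracks.values(comp.cells[2], comp.assays[0], "chrS"))
        extended = fit_new_entity(trained_model, "cell", "SOLO", ts,
                                  TrainingConfig(batch_size=10_000,
                                                 epochs_stage2=50, seed=8))
        assert "SOLO" in extended.cell_index

    def test_rejects_registered_entity(self, small_compendium, trained_model):
        comp = small_compendium
        ts = TrackSet(comp.grid)
        ts.add(comp.cells[0], comp.assays[0], "chrS",
               comp.tracks.values(comp.cells[0], comp.assays[0], "chrS"))
        with pytest.raises(ValueError, match="already"):
            fit_new_entity(trained_model, "cell", comp.cells[0], ts,
                           TrainingConfig(seed=0))
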