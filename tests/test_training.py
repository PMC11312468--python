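import numpy as np
import pytest
from scipy import stats

from cytosummary import (
    AugmentConfig,
    ModelDims,
    SampleSet,
    SupConBatch,
    TrainConfig,
    WellKey,
    aggregate_table,
    init_model,
    make_epoch_batches,
    replicate_retrieval_map,
    sample_cell_view,
    supcon_loss,
    supcon_loss_and_grad,
    train,
)
from cytosummary.preprocess import model_input_table
from cytosummary.simulate import SimulationConfig, moment_benchmark
from cytosummary.training import group_wells_by_compound


def supcon_oracle(V, labels, tau, variant):
    """Naive O(B^2) double-loop reference for the supervised contrastive loss."""
    U = V / np.linalg.norm(V, axis=1, keepdims=True)
    B = len(labels)
    total = 0.0
    for i in range(B):
        pos = [j for j in range(B) if j != i and labels[j] == labels[i]]
        if variant == "supcon_standard":
            den_idx = [j for j in range(B) if j != i]
        else:
            den_idx = [j for j in range(B) if labels[j] != labels[i]]
        for p in pos:
            num = np.exp(U[i] @ U[p] / tau)
            den = sum(np.exp(U[i] @ U[a] / tau) for a in den_idx)
            total += -(1.0 / len(pos)) * np.log(num / den)
    return total


ONE_HOT_V = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
ONE_HOT_LABELS = np.array(["A", "A", "B", "B"])


class TestSupConLoss:
    def test_hand_derived_one_hot_values(self):
        batch = SupConBatch(ONE_HOT_V, ONE_HOT_LABELS, temperature=1.0)
        assert supcon_loss(batch, "supcon_standard") == pytest.approx(
            4 * np.log(1 + 2 / np.e), abs=1e-12
        )
        assert supcon_loss(batch, "paper_literal") == pytest.approx(
            4 * (np.log(2) - 1), abs=1e-12
        )

    @pytest.mark.parametrize("variant", ["supcon_standard", "paper_literal"])
    def test_matches_double_loop_oracle_on_random_batches(self, variant):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_lab = rng.integers(2, 5)
            reps = rng.integers(2, 4, size=n_lab)
            labels = np.repeat(np.arange(n_lab), reps)
            if len(labels) < 4 or len(labels) > 16:
                labels = np.repeat(np.arange(2), 2)
            L = int(rng.integers(2, 9))
            V = rng.normal(size=(len(labels), L))
            tau = float(rng.uniform(0.05, 1.0))
            batch = SupConBatch(V, labels, temperature=tau)
            assert supcon_loss(batch, variant) == pytest.approx(
                supcon_oracle(V, labels, tau, variant), abs=1e-6, rel=1e-6
            )

    @pytest.mark.parametrize("variant", ["supcon_standard", "paper_literal"])
    def test_identical_embeddings_finite_and_match_oracle(self, variant):
        V = np.ones((6, 4))
        labels = np.array([0, 0, 0, 1, 1, 1])
        batch = SupConBatch(V, labels, temperature=0.5)
        got = supcon_loss(batch, variant)
        assert np.isfinite(got)
        assert got == pytest.approx(supcon_oracle(V, labels, 0.5, variant), abs=1e-9)

    def test_invariant_to_common_rotation(self, rng):
        V = rng.normal(size=(8, 5))
        labels = np.repeat([0, 1, 2, 3], 2)
        Q = stats.ortho_group.rvs(5, random_state=rng)
        l1 = supcon_loss(SupConBatch(V, labels))
        l2 = supcon_loss(SupConBatch(V @ Q, labels))
        assert l1 == pytest.approx(l2, rel=1e-10)

    def test_gradient_norm_grows_as_temperature_drops(self, rng):
        V = rng.normal(size=(8, 6))
        labels = np.repeat([0, 1, 2, 3], 2)
        norms = []
        for tau in (1.0, 0.5, 0.2, 0.1, 0.05):
            _, dV = supcon_loss_and_grad(SupConBatch(V, labels, temperature=tau))
            norms.append(np.linalg.norm(dV))
        assert all(b >= a for a, b in zip(norms, norms[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        V = rng.normal(size=(6, 4))
        labels = np.array([0, 0, 1, 1, 2, 2])
        batch = SupConBatch(V, labels, temperature=0.3)
        loss, dV = supcon_loss_and_grad(batch, "supcon_standard")
        eps = 1e-6
        for i, j in ((0, 0), (2, 3), (5, 1)):
            Vp, Vm = V.copy(), V.copy()
            Vp[i, j] += eps
            Vm[i, j] -= eps
            fd = (
                supcon_loss(SupConBatch(Vp, labels, temperature=0.3))
                - supcon_loss(SupConBatch(Vm, labels, temperature=0.3))
            ) / (2 * eps)
            assert dV[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_singleton_label_rejected(self):
        with pytest.raises(ValueError, match="2 occurrences"):
            SupConBatch(np.eye(4), np.array([0, 0, 1, 2]))

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            SupConBatch(ONE_HOT_V, ONE_HOT_LABELS, temperature=0.0)


def _wells(rng, n_wells=3, cells=10, D=4, compound="c1"):
    return [
        SampleSet(WellKey("P1", f"W{i}", compound), rng.normal(size=(cells, D)))
        for i in range(n_wells)
    ]


class TestSampleCellView:
    def test_degenerate_gaussian_gives_exact_count(self, rng):
        cfg = AugmentConfig(count_mean=100, count_sd=0.0, min_count=1)
        view = sample_cell_view(_wells(rng), cfg, np.random.default_rng(0))
        assert view.n_cells == 100

    def test_oversampling_small_well_replicates_cells(self, rng):
        wells = _wells(rng, n_wells=1, cells=10)
        cfg = AugmentConfig(count_mean=100, count_sd=0.0, min_count=1,
                            mix_probability=0.0)
        view = sample_cell_view(wells, cfg, np.random.default_rng(0))
        assert view.n_cells == 100
        pool_rows = {tuple(r) for r in wells[0].X}
        assert all(tuple(r) in pool_rows for r in view.X)

    def test_fixed_seed_reproduces_view(self, rng):
        wells = _wells(rng)
        cfg = AugmentConfig(count_mean=30, count_sd=5, min_count=1)
        v1 = sample_cell_view(wells, cfg, np.random.default_rng(9))
        v2 = sample_cell_view(wells, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(v1.X, v2.X)

    def test_single_well_compound_mix_falls_back(self, rng):
        wells = _wells(rng, n_wells=1)
        cfg = AugmentConfig(count_mean=20, count_sd=0, min_count=1, mix_probability=1.0)
        assert sample_cell_view(wells, cfg, np.random.default_rng(0)).n_cells == 20

    def test_empty_well_list_rejected(self):
        with pytest.raises(ValueError):
            sample_cell_view([], AugmentConfig(), np.random.default_rng(0))


class TestMakeEpochBatches:
    def _grouped(self, rng, n_compounds=10):
        return {
            f"c{k}": _wells(rng, n_wells=2, compound=f"c{k}")
            for k in range(n_compounds)
        }

    def test_ten_compounds_two_batches_of_ten_views(self, rng):
        cfg = AugmentConfig(count_mean=15, count_sd=0, min_count=1, views_per_compound=2)
        batches = make_epoch_batches(self._grouped(rng), cfg, 5, np.random.default_rng(1))
        assert len(batches) == 2
        assert all(len(b) == 10 for b in batches)

    def test_every_compound_covered_each_epoch(self, rng):
        cfg = AugmentConfig(count_mean=15, count_sd=0, min_count=1)
        batches = make_epoch_batches(self._grouped(rng), cfg, 4, np.random.default_rng(1))
        seen = {lab for b in batches for _, lab in b}
        assert seen == {f"c{k}" for k in range(10)}

    def test_single_view_per_compound_rejected(self):
        with pytest.raises(ValueError, match="views_per_compound"):
            AugmentConfig(views_per_compound=1)

    def test_fixed_seed_identical_schedule(self, rng):
        grouped = self._grouped(rng)
        cfg = AugmentConfig(count_mean=15, count_sd=0, min_count=1)
        b1 = make_epoch_batches(grouped, cfg, 5, np.random.default_rng(3))
        b2 = make_epoch_batches(grouped, cfg, 5, np.random.default_rng(3))
        assert [[lab for _, lab in b] for b in b1] == [[lab for _, lab in b] for b in b2]
        np.testing.assert_array_equal(b1[0][0][0].X, b2[0][0][0].X)

    def test_fewer_than_two_compounds_rejected(self, rng):
        with pytest.raises(ValueError):
            make_epoch_batches(
                {"c0": _wells(rng)}, AugmentConfig(), 4, np.random.default_rng(0)
            )


def _mean_benchmark_tables(seed=2):
    # modest mean shift: leaves headroom above an untrained random projection
    cfg = SimulationConfig(
        n_compounds=8, cells_per_well_mean=60, cells_per_well_min=10,
        D=10, effect_mode="mean", effect_size=0.1, seed=seed,
    )
    table, _ = moment_benchmark("mean", cfg)
    table = model_input_table(table)
    comps = sorted({k.compound_id for k in table.well_keys()})
    train_mask = table.meta["compound_id"].isin(comps[:5]).to_numpy()
    return table.subset_rows(train_mask), table.subset_rows(~train_mask)


SMALL_DIMS = ModelDims(D=10, N=32, H=16, L=32)
FAST_AUG = AugmentConfig(count_mean=40, count_sd=10, min_count=5)


class TestTrain:
    def test_learning_improves_validation_map(self):
        train_t, val_t = _mean_benchmark_tables()
        model = init_model(10, SMALL_DIMS, seed=0)
        untrained = replicate_retrieval_map(aggregate_table(model, val_t)).map
        cfg = TrainConfig(epochs=10, compounds_per_batch=5, seed=0)
        best, hist = train(model, train_t, val_t, cfg, FAST_AUG)
        trained = replicate_retrieval_map(aggregate_table(best, val_t)).map
        assert trained > untrained
        smoothed = hist["train_loss"].rolling(4, min_periods=1).mean()
        assert smoothed.iloc[-1] < smoothed.iloc[0]

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        train_t, val_t = _mean_benchmark_tables()
        model = init_model(10, SMALL_DIMS, seed=0)
        before = {k: v.copy() for k, v in model.params.items()}
        untrained = replicate_retrieval_map(aggregate_table(model, val_t)).map
        cfg = TrainConfig(epochs=2, learning_rate=0.0, weight_decay=0.0,
                          compounds_per_batch=5, seed=0)
        best, hist = train(model, train_t, val_t, cfg, FAST_AUG)
        for k in before:
            np.testing.assert_array_equal(best.params[k], before[k])
        assert hist["val_map"].iloc[-1] == pytest.approx(untrained)

    def test_same_seed_identical_history(self):
        train_t, val_t = _mean_benchmark_tables()
        cfg = TrainConfig(epochs=3, compounds_per_batch=5, seed=4)
        runs = []
        for _ in range(2):
            model = init_model(10, SMALL_DIMS, seed=4)
            _, hist = train(model, train_t, val_t, cfg, FAST_AUG)
            runs.append(hist)
        np.testing.assert_array_equal(
            runs[0][["train_loss", "val_map"]].to_numpy(),
            runs[1][["train_loss", "val_map"]].to_numpy(),
        )

    def test_no_validation_set_warns_and_returns_final(self):
        train_t, _ = _mean_benchmark_tables()
        model = init_model(10, SMALL_DIMS, seed=0)
        cfg = TrainConfig(epochs=2, compounds_per_batch=5, seed=0)
        with pytest.warns(UserWarning, match="no validation"):
            best, hist = train(model, train_t, None, cfg, FAST_AUG)
        assert len(hist) == 2
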