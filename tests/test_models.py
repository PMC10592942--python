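import numpy as np
import pytest
from scipy.stats import spearmanr

from epiedit import features, models
from epiedit.models import ModelConfig, CNNConfig, ModelError


def make_dataset(n, marks=2, W=33, seed=0, y=None, cts=1, chroms=2):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 2, (n, marks, W))
    if y is None:
        y = rng.normal(1, 1, n)
    per = n // cts
    return features.Dataset(
        X, np.asarray(y, float),
        np.array([f"g{i % per:04d}" for i in range(n)]),
        np.array([f"ct{i // per}" for i in range(n)]),
        np.array([f"chr{(i % per) % chroms + 1}" for i in range(n)]),
        marks=tuple(f"m{k}" for k in range(marks)),
    )


class TestRidge:
    def test_huge_penalty_predicts_target_mean(self):
        ds = make_dataset(60, seed=1)
        m = models.train_ridge(ds, ModelConfig(ridge_alphas=(1e12,)))
        pred = m.predict(ds.X)
        assert np.allclose(pred, ds.y.mean(), atol=1e-3)

    def test_zero_penalty_is_ols_on_tall_design(self):
        ds = make_dataset(80, marks=1, W=5, seed=2)
        m = models.train_ridge(ds, ModelConfig(ridge_alphas=(0.0,)))
        Xf = np.c_[ds.X.reshape(80, -1), np.ones(80)]
        w, *_ = np.linalg.lstsq(Xf, ds.y, rcond=None)
        assert np.allclose(m._ridge.coef_, w[:-1], atol=1e-8)

    def test_recovers_planted_linear_signal(self):
        rng = np.random.default_rng(3)
        n, p = 400, 2 * 33
        X = rng.uniform(0, 2, (n, 2, 33))
        w = rng.normal(0, 1, p)
        y = X.reshape(n, -1) @ w + rng.normal(0, 0.05, n)
        ds = make_dataset(n, seed=3, y=y)
        ds.X = X
        train, test = features.split_by_chromosome(ds, ["chr1"])
        m = models.train_ridge(train, ModelConfig())
        rho = spearmanr(test.y, m.predict(test.X)).statistic
        assert rho >= 0.9

    def test_too_few_rows_for_cv(self):
        ds = make_dataset(4)
        with pytest.raises(ModelError, match="5"):
            models.train_ridge(ds, ModelConfig())


class TestCNN:
    def cfg(self, **kw):
        base = dict(n_blocks=2, kernels=4, kernel_width=3, fc_units=4,
                    epochs=(3,), lrs=(1e-3,))
        base.update(kw)
        return ModelConfig(kind="cnn", cnn=CNNConfig(**base), seed=5)

    def test_default_shape_trace(self):
        """6 x 401 input through 5 pool-by-2 blocks flattens to 32*12=384."""
        from epiedit import _nn
        net, flat = _nn.build_cnn(6, 401, np.random.default_rng(0))
        assert flat == 384
        out = net.forward(np.zeros((2, 401, 6), dtype=np.float32), train=False)
        assert out.shape == (2, 1)

    def test_window_too_small_for_pooling(self):
        ds = make_dataset(20, W=15)
        cfg = self.cfg(n_blocks=5)
        with pytest.raises(ValueError, match="too small"):
            models.train_cnn(ds, cfg)

    def test_memorizes_tiny_training_set(self):
        """Overfit sanity: with regularization (dropout) off, a 10-row
        training set is memorized to near-zero error."""
        rng = np.random.default_rng(0)
        ds = make_dataset(10, marks=6, W=401, seed=0, y=rng.normal(2, 1, 10))
        cfg = ModelConfig(kind="cnn", seed=1,
                          cnn=CNNConfig(dropout=0.0, epochs=(200, 200)))
        m = models.train_cnn(ds, cfg)
        assert float(np.mean((m.predict(ds.X) - ds.y) ** 2)) < 1e-2

    def test_same_seed_bitwise_identical(self):
        ds = make_dataset(30)
        probe = make_dataset(8, seed=9).X
        p1 = models.train_cnn(ds, self.cfg()).predict(probe)
        p2 = models.train_cnn(ds, self.cfg()).predict(probe)
        assert np.array_equal(p1, p2)

    def test_different_seeds_differ(self):
        ds = make_dataset(30)
        probe = make_dataset(8, seed=9).X
        c2 = self.cfg()
        c2 = ModelConfig(kind="cnn", cnn=c2.cnn, seed=6)
        p1 = models.train_cnn(ds, self.cfg()).predict(probe)
        p2 = models.train_cnn(ds, c2).predict(probe)
        assert not np.array_equal(p1, p2)


class TestEnsemble:
    def test_single_model_identity(self):
        ds = make_dataset(40)
        m = models.train_ridge(ds, ModelConfig())
        assert np.array_equal(models.ensemble_predict([m], ds.X), m.predict(ds.X))

    def test_mean_of_constant_members(self):
        ds1 = make_dataset(40, y=np.ones(40))
        ds3 = make_dataset(40, y=3 * np.ones(40))
        m1 = models.train_ridge(ds1, ModelConfig(ridge_alphas=(1e12,)))
        m3 = models.train_ridge(ds3, ModelConfig(ridge_alphas=(1e12,)))
        pred = models.ensemble_predict([m1, m3], ds1.X)
        assert np.allclose(pred, 2.0, atol=1e-3)

    def test_empty_list_errors(self):
        with pytest.raises(ModelError, match="empty"):
            models.ensemble_predict([], np.zeros((1, 2, 33)))

    def test_default_ensemble_size_is_100(self):
        assert ModelConfig().ensemble_size == 100

    def test_averaging_contracts(self):
        """Ensemble MSE <= mean member MSE (Jensen) and ensemble prediction
        variance <= mean member prediction variance."""
        ds = make_dataset(60, seed=4)
        cfg = ModelConfig(kind="cnn", seed=0, ensemble_size=3,
                          cnn=CNNConfig(n_blocks=2, kernels=4, kernel_width=3,
                                        fc_units=4, epochs=(4,), lrs=(1e-3,)))
        ens = models.train_ensemble(ds, cfg)
        member_preds = np.array([m.predict(ds.X) for m in ens])
        mean_pred = member_preds.mean(axis=0)
        member_mse = np.mean((member_preds - ds.y) ** 2, axis=1)
        assert np.mean((mean_pred - ds.y) ** 2) <= member_mse.mean() + 1e-9
        assert mean_pred.var() <= member_preds.var(axis=1).mean() + 1e-9

    def test_replicates_use_distinct_seeds(self):
        ds = make_dataset(30)
        cfg = ModelConfig(kind="cnn", seed=10, ensemble_size=2,
                          cnn=CNNConfig(n_blocks=2, kernels=4, kernel_width=3,
                                        fc_units=4, epochs=(2,), lrs=(1e-3,)))
        ens = models.train_ensemble(ds, cfg)
        assert ens[0].config.seed == 10 and ens[1].config.seed == 11


class PerfectModel(models.ExpressionModel):
    """Oracle stub returning a fixed transform of the stored target map."""

    def __init__(self, shape, fn):
        super().__init__("ridge", ModelConfig(), shape, frozenset())
        self._fn = fn

    def predict(self, X):
        return self._fn(X)


class TestEvaluations:
    def test_perfect_predictions_rho_one(self):
        ds = make_dataset(40, cts=1)
        key = ds.X.sum(axis=(1, 2))
        order = np.argsort(np.argsort(key))
        ds.y = order.astype(float)  # targets are a rank transform of the key
        m = PerfectModel(ds.X.shape[1:], lambda X: X.sum(axis=(1, 2)))
        rho = models.evaluate_heldout_chromosomes([m], ds, ["chr1"])
        assert rho == 1.0

    def test_antiordered_predictions_rho_minus_one(self):
        ds = make_dataset(40, cts=1)
        ds.y = np.argsort(np.argsort(ds.X.sum(axis=(1, 2)))).astype(float)
        m = PerfectModel(ds.X.shape[1:], lambda X: -X.sum(axis=(1, 2)))
        assert models.evaluate_heldout_chromosomes([m], ds, ["chr1"]) == -1.0

    def test_rank_identity_example(self):
        rho = spearmanr([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.9]).statistic
        assert rho == 1.0

    def test_constant_predictions_raise(self):
        ds = make_dataset(40, cts=1)
        m = PerfectModel(ds.X.shape[1:], lambda X: np.zeros(X.shape[0]))
        with pytest.raises(ModelError, match="undefined"):
            models.evaluate_heldout_chromosomes([m], ds, ["chr1"])

    def test_heldout_celltype_on_identical_cell_types(self):
        """Duplicating one cell type's rows under a second label: held-out
        performance matches training-side performance."""
        rng = np.random.default_rng(8)
        n = 120
        X = rng.uniform(0, 2, (n, 2, 33))
        w = rng.normal(0, 1, 2 * 33)
        y = X.reshape(n, -1) @ w + rng.normal(0, 0.3, n)
        X2, y2 = np.concatenate([X, X]), np.concatenate([y, y])
        ds = features.Dataset(
            X2, y2,
            np.array([f"g{i:03d}" for i in range(n)] * 2),
            np.array(["ctA"] * n + ["ctB"] * n),
            np.array(["chr1"] * (2 * n)),
            marks=("m0", "m1"),
        )
        cfg = ModelConfig(ensemble_size=1)
        rho_held, ens = models.evaluate_heldout_celltype(ds, cfg, "ctB")
        mask = ds.cell_types == "ctA"
        rho_train = spearmanr(ds.y[mask],
                              models.ensemble_predict(ens, ds.X[mask])).statistic
        assert abs(rho_held - rho_train) < 0.05

    def test_heldout_celltype_errors(self):
        ds = make_dataset(40, cts=1)
        with pytest.raises(ModelError, match="absent"):
            models.evaluate_heldout_celltype(ds, ModelConfig(ensemble_size=1), "ctX")
        with pytest.raises(ModelError, match="single"):
            models.evaluate_heldout_celltype(ds, ModelConfig(ensemble_size=1), "ct0")

    def test_per_gene_cross_celltype(self):
        ds = make_dataset(120, cts=4)
        m = PerfectModel(ds.X.shape[1:], lambda X: X.sum(axis=(1, 2)))
        ds.y = m.predict(ds.X)  # observed equals predicted
        # plant one constant-expression gene: undefined rho, excluded
        g0 = ds.gene_ids == "g0000"
        ds.y[g0] = 1.0
        rhos, excluded = models.per_gene_cross_celltype_correlation([m], ds)
        assert excluded >= 1 and "g0000" not in rhos
        assert np.allclose(list(rhos.values()), 1.0)

    def test_per_gene_needs_three_cell_types(self):
        ds = make_dataset(40, cts=2)
        m = PerfectModel(ds.X.shape[1:], lambda X: X.sum(axis=(1, 2)))
        with pytest.raises(ModelError, match="3 cell types"):
            models.per_gene_cross_celltype_correlation([m], ds)


class TestNullSanity:
    def test_shuffled_features_give_no_signal(self):
        """Features shuffled against targets: all evaluation regimes near 0."""
        rng = np.random.default_rng(12)
        ds = make_dataset(1000, marks=2, W=33, seed=12, cts=4, chroms=5)
        ds.y = rng.normal(0, 1, 1000)  # independent of X by construction
        train, test = features.split_by_chromosome(ds, ["chr1"])
        rm = models.train_ridge(train, ModelConfig())
        assert abs(models.evaluate_heldout_chromosomes([rm], ds, ["chr1"])) < 0.1
        cfg = ModelConfig(kind="cnn", seed=0,
                          cnn=CNNConfig(n_blocks=2, kernels=4, kernel_width=3,
                                        fc_units=4, epochs=(3,), lrs=(1e-3,)))
        cm = models.train_cnn(train, cfg)
        assert abs(models.evaluate_heldout_chromosomes([cm], ds, ["chr1"])) < 0.1
        rhos, _ = models.per_gene_cross_celltype_correlation([rm], test)
        assert abs(np.median(list(rhos.values()))) < 0.35  # 4 points per gene


class TestSerialization:
    def test_ridge_round_trip(self, tmp_path):
        ds = make_dataset(40)
        m = models.train_ridge(ds, ModelConfig())
        m.save(tmp_path / "m")
        back = models.ExpressionModel.load(tmp_path / "m")
        assert np.allclose(back.predict(ds.X), m.predict(ds.X))
        assert back.training_genes == m.training_genes

    def test_cnn_round_trip(self, tmp_path):
        ds = make_dataset(30)
        cfg = ModelConfig(kind="cnn", seed=2,
                          cnn=CNNConfig(n_blocks=2, kernels=4, kernel_width=3,
                                        fc_units=4, epochs=(2,), lrs=(1e-3,)))
        m = models.train_cnn(ds, cfg)
        m.save(tmp_path / "m")
        back = models.ExpressionModel.load(tmp_path / "m")
        assert np.array_equal(back.predict(ds.X), m.predict(ds.X))
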