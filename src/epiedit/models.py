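"""Expression models: ridge regression and a TSS-window CNN, with ensembling.

Both model families map a (marks x W) log-compressed signal window to log
expression.  Ridge flattens the window and picks its L2 penalty by 5-fold
cross-validation; the CNN processes the window with convolutional blocks
(batchnorm -> ReLU -> conv(32, width 5) -> dropout 0.1 -> maxpool 2), a
16-unit dense layer and a linear output, trained with Adam under a staged
learning-rate schedule (0.001 for the first stage of epochs, 0.0005 for
the second).  Predictions are averaged over an ensemble of replicates
(default 100) that differ only in their seeds.

Three evaluation regimes are provided: pooled held-out chromosomes,
held-out cell type, and per-gene correlation across cell types.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import ConstantInputWarning, spearmanr
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from . import _nn
from .features import Dataset, split_by_chromosome

DEFAULT_RIDGE_GRID = tuple(10.0 ** (k / 2) for k in range(-6, 7))  # 1e-3 .. 1e3


class ModelError(ValueError):
    """Raised for invalid model configuration or degenerate evaluations."""


@dataclass
class CNNConfig:
    n_blocks: int = 5
    kernels: int = 32
    kernel_width: int = 5
    dropout: float = 0.1
    pool: int = 2
    fc_units: int = 16
    epochs: Tuple[int, int] = (50, 50)
    lrs: Tuple[float, float] = (0.001, 0.0005)
    batch_size: int = 64

    def __post_init__(self) -> None:
        if len(self.epochs) != len(self.lrs):
            raise ModelError("epochs and lrs must align stage by stage")

    @property
    def schedule(self) -> List[Tuple[int, float]]:
        return list(zip(self.epochs, self.lrs))


@dataclass
class ModelConfig:
    kind: str = "ridge"  # "ridge" | "cnn"
    cnn: CNNConfig = field(default_factory=CNNConfig)
    ridge_alphas: Tuple[float, ...] = DEFAULT_RIDGE_GRID
    seed: int = 0
    ensemble_size: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("ridge", "cnn"):
            raise ModelError(f"unknown model kind {self.kind!r}")
        if self.ensemble_size < 1:
            raise ModelError("ensemble_size must be >= 1")


@dataclass
class ExpressionModel:
    """A fitted model plus the fingerprint of the genes it was trained on."""

    kind: str
    config: ModelConfig
    shape: Tuple[int, int]  # (n_marks, W)
    training_genes: frozenset
    _ridge: Optional[Ridge] = None
    _net: Optional[_nn.Sequential] = None
    #: per-(mark, bin) standardization of CNN inputs, fitted on training data
    _x_mean: Optional[np.ndarray] = None
    _x_sd: Optional[np.ndarray] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict log expression for a (n, marks, W) log-scale tensor."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:  # a single window
            X = X[None]
        if X.shape[1:] != self.shape:
            raise ModelError(f"input shape {X.shape[1:]} != trained shape {self.shape}")
        if self.kind == "ridge":
            return self._ridge.predict(X.reshape(X.shape[0], -1))
        if self._x_mean is not None:
            X = (X - self._x_mean) / self._x_sd
        return _nn.predict(self._net, X)

    # -- serialization ------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": self.kind,
            "shape": list(self.shape),
            "training_genes": sorted(self.training_genes),
            "config": _config_dict(self.config),
        }
        (d / "model.json").write_text(json.dumps(meta, indent=1))
        if self.kind == "ridge":
            np.savez(d / "params.npz", coef=self._ridge.coef_,
                     intercept=np.atleast_1d(self._ridge.intercept_),
                     alpha=np.array([self._ridge.alpha]))
        else:
            np.savez(d / "params.npz", x_mean=self._x_mean, x_sd=self._x_sd,
                     **self._net.state())

    @classmethod
    def load(cls, directory) -> "ExpressionModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        config = _config_from_dict(meta["config"])
        shape = tuple(meta["shape"])
        params = np.load(d / "params.npz")
        model = cls(meta["kind"], config, shape, frozenset(meta["training_genes"]))
        if meta["kind"] == "ridge":
            ridge = Ridge(alpha=float(params["alpha"][0]))
            ridge.coef_ = params["coef"]
            ridge.intercept_ = params["intercept"][0]
            ridge.n_features_in_ = shape[0] * shape[1]
            model._ridge = ridge
        else:
            c = config.cnn
            net, _ = _nn.build_cnn(shape[0], shape[1], np.random.default_rng(0),
                                   c.n_blocks, c.kernels, c.kernel_width,
                                   c.dropout, c.pool, c.fc_units)
            net.load_state({k: params[k] for k in params.files
                            if k not in ("x_mean", "x_sd")})
            model._net = net
            model._x_mean = params["x_mean"]
            model._x_sd = params["x_sd"]
        return model


def _config_dict(cfg: ModelConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["ridge_alphas"] = list(cfg.ridge_alphas)
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    cnn = CNNConfig(**{**d["cnn"],
                       "epochs": tuple(d["cnn"]["epochs"]),
                       "lrs": tuple(d["cnn"]["lrs"])})
    return ModelConfig(kind=d["kind"], cnn=cnn,
                       ridge_alphas=tuple(d["ridge_alphas"]),
                       seed=d["seed"], ensemble_size=d["ensemble_size"])


def _cv5_mse(Xf: np.ndarray, y: np.ndarray, alphas: Sequence[float]) -> np.ndarray:
    """Mean held-out squared error of ridge per penalty, 5-fold CV.

    One Gram (or kernel, whichever side is smaller) factorization per
    (fold, alpha); centered features so the intercept is unpenalized.
    """
    errs = np.zeros(len(alphas))
    for tr_idx, va_idx in KFold(n_splits=5).split(Xf):
        Xtr, ytr = Xf[tr_idx], y[tr_idx]
        Xva, yva = Xf[va_idx], y[va_idx]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        Xc, yc = Xtr - xm, ytr - ym
        Xvc = Xva - xm
        n, p = Xc.shape
        if n >= p:  # primal: (X'X + aI) w = X'y
            G, b = Xc.T @ Xc, Xc.T @ yc
            for ai, a in enumerate(alphas):
                w = cho_solve(cho_factor(G + a * np.eye(p)), b)
                r = Xvc @ w + ym - yva
                errs[ai] += float(r @ r)
        else:  # dual: w = X' (XX' + aI)^{-1} y
            K = Xc @ Xc.T
            for ai, a in enumerate(alphas):
                dual = cho_solve(cho_factor(K + a * np.eye(n)), yc)
                r = Xvc @ (Xc.T @ dual) + ym - yva
                errs[ai] += float(r @ r)
    return errs / len(y)


def train_ridge(train: Dataset, config: ModelConfig) -> ExpressionModel:
    """Fit ridge regression on flattened windows; penalty by 5-fold CV."""
    n = len(train)
    if n < 5:
        raise ModelError(f"need at least 5 training rows for 5-fold CV, got {n}")
    Xf = train.X.reshape(n, -1)
    if len(config.ridge_alphas) > 1:
        errs = _cv5_mse(Xf, train.y, config.ridge_alphas)
        best = float(config.ridge_alphas[int(np.argmin(errs))])
    else:
        best = float(config.ridge_alphas[0])
    ridge = Ridge(alpha=best)
    ridge.fit(Xf, train.y)
    return ExpressionModel("ridge", config, train.X.shape[1:],
                           frozenset(train.gene_ids), _ridge=ridge)


def train_cnn(train: Dataset, config: ModelConfig) -> ExpressionModel:
    """Train one CNN replicate; all randomness flows from config.seed.

    Inputs are standardized per (mark, bin) on the training set before the
    network; the fitted mean/sd travel with the model and are applied at
    prediction time.
    """
    c = config.cnn
    n_marks, W = train.X.shape[1:]
    x_mean = train.X.mean(axis=0)
    x_sd = train.X.std(axis=0) + 1e-6
    rng = np.random.default_rng(config.seed)
    net, _ = _nn.build_cnn(n_marks, W, rng, c.n_blocks, c.kernels,
                           c.kernel_width, c.dropout, c.pool, c.fc_units)
    _nn.train_mse(net, (train.X - x_mean) / x_sd, train.y, rng,
                  c.schedule, c.batch_size)
    return ExpressionModel("cnn", config, (n_marks, W),
                           frozenset(train.gene_ids), _net=net,
                           _x_mean=x_mean, _x_sd=x_sd)


def train_ensemble(train: Dataset, config: ModelConfig) -> List[ExpressionModel]:
    """Train ``config.ensemble_size`` replicates; replicate i uses seed+i."""
    models = []
    for i in range(config.ensemble_size):
        cfg = dataclasses.replace(config, seed=config.seed + i)
        trainer = train_cnn if config.kind == "cnn" else train_ridge
        models.append(trainer(train, cfg))
    return models


def ensemble_predict(models: Sequence[ExpressionModel], X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of member predictions."""
    if len(models) == 0:
        raise ModelError("empty model list")
    kinds = {m.kind for m in models}
    if len(kinds) > 1:
        raise ModelError(f"mixed model kinds in ensemble: {sorted(kinds)}")
    return np.mean([m.predict(X) for m in models], axis=0)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantInputWarning)
        rho = spearmanr(a, b).statistic
    if not np.isfinite(rho):
        raise ModelError("Spearman correlation undefined (constant input)")
    return float(rho)


def evaluate_heldout_chromosomes(
    models: Sequence[ExpressionModel], dataset: Dataset, held_out_chroms: Sequence[str]
) -> float:
    """Pooled Spearman rho on all (gene, cell type) rows of held-out chromosomes."""
    _, test = split_by_chromosome(dataset, held_out_chroms)
    if len(test) < 3:
        raise ModelError("need at least 3 test rows")
    pred = ensemble_predict(models, test.X)
    return _spearman(test.y, pred)


def evaluate_heldout_celltype(
    dataset: Dataset, config: ModelConfig, held_out_cell_type: str
) -> Tuple[float, List[ExpressionModel]]:
    """Train on all other cell types (all chromosomes), test on the held-out one.

    Returns (rho, trained ensemble).
    """
    mask = dataset.cell_types == held_out_cell_type
    if not mask.any():
        raise ModelError(f"cell type {held_out_cell_type!r} absent from dataset")
    if mask.all():
        raise ModelError("dataset has a single cell type; nothing to train on")
    train, test = dataset.subset(~mask), dataset.subset(mask)
    models = train_ensemble(train, config)
    pred = ensemble_predict(models, test.X)
    return _spearman(test.y, pred), models


def per_gene_cross_celltype_correlation(
    models: Sequence[ExpressionModel], dataset: Dataset
) -> Tuple[Dict[str, float], int]:
    """Per-gene Spearman rho across cell types (the cross-cell-type regime).

    For every gene in ``dataset`` (typically the held-out chromosome rows),
    correlates observed and ensemble-predicted expression across its cell
    type columns.  Genes whose observed or predicted values are constant
    across cell types have an undefined rho and are excluded; the count of
    exclusions is returned alongside the rho map.
    """
    n_ct = len(np.unique(dataset.cell_types))
    if n_ct < 3:
        raise ModelError("need at least 3 cell types for per-gene correlations")
    pred = ensemble_predict(models, dataset.X)
    rhos: Dict[str, float] = {}
    excluded = 0
    for gid in np.unique(dataset.gene_ids):
        m = dataset.gene_ids == gid
        if m.sum() < 3:
            excluded += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConstantInputWarning)
            rho = spearmanr(dataset.y[m], pred[m]).statistic
        if np.isfinite(rho):
            rhos[gid] = float(rho)
        else:
            excluded += 1
    return rhos, excluded
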