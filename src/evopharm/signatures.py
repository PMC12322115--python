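"""Per-drug response-prediction models and feature-importance gene signatures.

A small feedforward regression network (ReLU hidden layers, Adam updates,
optional inverted dropout, L2 penalty) predicts drug AUC from per-gene
z-scored expression. Hyperparameters are chosen by grid search on k-fold
cross-validated RMSE; ties go to the earlier grid point in declared order.
Gene importance is permutation importance — the mean RMSE increase when one
gene's column is shuffled — which is model-agnostic and reproducible; the
drug gene signature is the top-K genes by importance (K=100 by default,
with an override to 500).

The permutation pass exploits the network shape: shuffling gene g only
shifts the first-layer pre-activations by an outer product, so each
gene x repeat evaluation is O(n_samples x width) instead of a full forward
pass over all genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from evopharm.io import ExpressionMatrix, ValidationError
from evopharm.pharmaco import DrugResponseTable


# ------------------------------------------------------------- the network

class FeedforwardNet:
    """Feedforward regression network trained with Adam on mean squared error.

    Deterministic given the seed: weight initialization, minibatch shuffling
    and dropout masks all come from one generator.
    """

    def __init__(
        self,
        hidden: Sequence[int] = (64,),
        l2: float = 1e-3,
        dropout: float = 0.0,
        epochs: int = 150,
        batch_size: int = 64,
        lr: float = 1e-2,
        seed: int = 0,
    ):
        if not 0 <= dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        self.hidden = tuple(int(h) for h in hidden)
        self.l2 = float(l2)
        self.dropout = float(dropout)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.lr = float(lr)
        self.seed = int(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []

    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = [n_features, *self.hidden, 1]
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeedforwardNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)
        self._y_mean = float(y.mean())
        self._y_std = float(y.std())
        if self._y_std == 0:
            # constant target: nothing to learn, predict the mean exactly
            self._y_std = 1.0
            self.weights[-1][:] = 0.0
            self.biases[-1][:] = 0.0
            return self
        yc = (y - self._y_mean) / self._y_std

        m = [np.zeros_like(w) for w in self.weights + self.biases]
        v = [np.zeros_like(w) for w in self.weights + self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], yc[idx]
                grads = self._backprop(xb, yb, rng)
                step += 1
                params = self.weights + self.biases
                for k, (p, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    p -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def _backprop(self, X, y, rng) -> list[np.ndarray]:
        acts = [X]
        masks = []
        a = X
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            if i < len(self.weights) - 1:
                a = np.maximum(z, 0.0)
                if self.dropout > 0:
                    mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z
            acts.append(a)
        pred = acts[-1].ravel()
        n = len(y)
        delta = (2.0 / n) * (pred - y)[:, None]
        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w.insert(0, acts[i].T @ delta + self.l2 * self.weights[i])
            grads_b.insert(0, delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return grads_w + grads_b

    def first_preactivation(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights[0] + self.biases[0]

    def forward_from_first(self, z1: np.ndarray) -> np.ndarray:
        """Predictions given first-layer pre-activations (for fast permutation)."""
        a = np.maximum(z1, 0.0)
        for i in range(1, len(self.weights)):
            z = a @ self.weights[i] + self.biases[i]
            a = np.maximum(z, 0.0) if i < len(self.weights) - 1 else z
        return a.ravel() * self._y_std + self._y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward_from_first(self.first_preactivation(np.asarray(X, float)))


# ------------------------------------------------------------- grid search

@dataclass
class ModelGrid:
    """Grid-search dimensions: hidden sizes, dropout, L2, epochs and folds."""

    hidden: list = field(default_factory=lambda: [(64,), (32, 16)])
    dropout: list = field(default_factory=lambda: [0.0])
    l2: list = field(default_factory=lambda: [1e-3])
    epochs: list = field(default_factory=lambda: [150])
    folds: int = 3

    def __post_init__(self) -> None:
        if not (self.hidden and self.dropout and self.l2 and self.epochs):
            raise ValidationError("grid dimensions must be non-empty")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        self.hidden = [tuple(h) for h in self.hidden]

    def points(self):
        """Grid points in lexicographic declared order (tie-break order)."""
        return itertools.product(self.hidden, self.dropout, self.l2, self.epochs)


@dataclass
class FittedDrugModel:
    drug: str
    hyperparams: dict
    cv_rmse: float
    net: FeedforwardNet
    genes: list[str]
    gene_mean: np.ndarray
    gene_std: np.ndarray

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.gene_mean) / self.gene_std

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict(self.standardize(X))


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _design(expr: ExpressionMatrix, auc, drug: str):
    """Align samples between expression and AUC; returns X (samples x genes), y."""
    if isinstance(auc, DrugResponseTable):
        y_all = auc.values[drug]
    else:
        y_all = pd.Series(auc)
    common = [s for s in expr.samples if s in y_all.index and np.isfinite(y_all[s])]
    if len(common) < 20:
        raise ValidationError(
            f"need >= 20 samples with expression and AUC; found {len(common)}"
        )
    X = expr.df[common].to_numpy(dtype=float).T
    y = y_all.loc[common].to_numpy(dtype=float)
    return X, y, list(expr.genes)


def grid_search_fit(
    expr: ExpressionMatrix,
    auc,
    drug: str,
    grid: ModelGrid = ModelGrid(),
    seed: int = 0,
    batch_size: int = 64,
    lr: float = 1e-2,
) -> FittedDrugModel:
    """Select hyperparameters by k-fold CV RMSE, then refit on all samples.

    Expression is z-scored per gene internally (zero-variance genes get unit
    scale); an all-zero-variance matrix is rejected. Fully deterministic
    given the seed.
    """
    X, y, genes = _design(expr, auc, drug)
    if X.shape[0] < grid.folds:
        raise ValidationError("fewer samples than folds")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if (std == 0).all():
        raise ValidationError("all genes have zero variance")
    std = np.where(std == 0, 1.0, std)
    Xs = (X - mean) / std

    best = None
    folds = KFold(n_splits=grid.folds, shuffle=True, random_state=seed % (2**31))
    splits = list(folds.split(Xs))
    for hidden, dropout, l2, epochs in grid.points():
        rmses = []
        for train_idx, test_idx in splits:
            net = FeedforwardNet(hidden, l2, dropout, epochs,
                                 batch_size=batch_size, lr=lr, seed=seed)
            net.fit(Xs[train_idx], y[train_idx])
            rmses.append(_rmse(y[test_idx], net.predict(Xs[test_idx])))
        cv_rmse = float(np.mean(rmses))
        if best is None or cv_rmse < best[0]:  # strict < keeps earlier grid point
            best = (cv_rmse, {"hidden": hidden, "dropout": dropout,
                              "l2": l2, "epochs": epochs})
    cv_rmse, params = best
    net = FeedforwardNet(params["hidden"], params["l2"], params["dropout"],
                         params["epochs"], batch_size=batch_size, lr=lr, seed=seed)
    net.fit(Xs, y)
    return FittedDrugModel(drug, params, cv_rmse, net, genes, mean, std)


def fit_drug_model(
    expr: ExpressionMatrix,
    auc,
    drug: str,
    hidden: Sequence[int] = (64,),
    l2: float = 1e-3,
    dropout: float = 0.0,
    epochs: int = 150,
    seed: int = 0,
    batch_size: int = 64,
    lr: float = 1e-2,
) -> FittedDrugModel:
    """Fit one model at fixed hyperparameters (no cross-validation).

    Same preprocessing as `grid_search_fit`; the reported RMSE is the
    training RMSE. Used where the hyperparameters are already chosen.
    """
    X, y, genes = _design(expr, auc, drug)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if (std == 0).all():
        raise ValidationError("all genes have zero variance")
    std = np.where(std == 0, 1.0, std)
    Xs = (X - mean) / std
    net = FeedforwardNet(hidden, l2, dropout, epochs,
                         batch_size=batch_size, lr=lr, seed=seed)
    net.fit(Xs, y)
    params = {"hidden": tuple(hidden), "dropout": dropout, "l2": l2,
              "epochs": epochs}
    return FittedDrugModel(drug, params, _rmse(y, net.predict(Xs)), net,
                           genes, mean, std)


# ------------------------------------------------------------- importances

def feature_importance(
    model: FittedDrugModel,
    expr: ExpressionMatrix,
    auc,
    n_repeats: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance per gene, floored at zero.

    importance(g) = mean over repeats of RMSE(with column g shuffled) minus
    the baseline RMSE. Genes present in `expr` but absent from the model's
    input get importance 0. Deterministic given the seed.
    """
    if isinstance(auc, DrugResponseTable):
        y_all = auc.values[model.drug]
    else:
        y_all = pd.Series(auc)
    common = [s for s in expr.samples if s in y_all.index and np.isfinite(y_all[s])]
    sub = expr.df.loc[expr.df.index.intersection(model.genes), common]
    sub = sub.reindex(model.genes).fillna(0.0)
    X = sub.to_numpy(dtype=float).T
    y = y_all.loc[common].to_numpy(dtype=float)
    Xs = model.standardize(X)
    net = model.net

    z1 = net.first_preactivation(Xs)
    baseline = _rmse(y, net.forward_from_first(z1))
    rng = np.random.default_rng(seed)
    w1 = net.weights[0]
    imp = np.zeros(len(model.genes))
    for j in range(len(model.genes)):
        col = Xs[:, j]
        deltas = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(col))
            shifted = z1 + np.outer(col[perm] - col, w1[j])
            deltas.append(_rmse(y, net.forward_from_first(shifted)) - baseline)
        imp[j] = max(0.0, float(np.mean(deltas)))
    series = pd.Series(imp, index=model.genes, name=model.drug)
    extra = [g for g in expr.genes if g not in series.index]
    if extra:
        series = pd.concat([series, pd.Series(0.0, index=extra, name=model.drug)])
    return series


@dataclass
class DrugGeneSignature:
    """Ranked genes by model feature importance, truncated to top-K."""

    drug: str
    table: pd.DataFrame  # columns: rank, gene, importance

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def extract_signature(
    importances: pd.Series, drug: str = "", k: int = 100
) -> DrugGeneSignature:
    """Top-K genes by importance; ties broken by gene symbol order."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if (importances < 0).any():
        raise ValidationError("importances must be non-negative")
    frame = importances.rename("importance").rename_axis("gene").reset_index()
    frame = frame.sort_values(
        ["importance", "gene"], ascending=[False, True], kind="mergesort"
    ).head(k)
    frame.insert(0, "rank", range(1, len(frame) + 1))
    return DrugGeneSignature(drug or str(importances.name or ""), frame.reset_index(drop=True))
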