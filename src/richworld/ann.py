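"""Feed-forward richness model: a small rectifier network trained with
momentum SGD.

The regression maps 0-1 scaled environmental features to the 0-1 scaled
ln(x+1) richness response.  The default architecture is 3 hidden layers of
10 rectified-linear units with 0.2 (inverted) dropout, trained with plain
momentum SGD (momentum 0.9, batch size 128) under a mean-squared-error
loss.  Training uses an 80/20 train/test split; hyperparameters can be
selected by 5-fold cross-validation on the training rows (minimum mean
fold RMSE, ties broken by fold-RMSE variance, then by smaller model).

Everything is implemented on numpy arrays; with a fixed seed a training
run is bit-reproducible on one platform, and inference (dropout off) is
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import FeatureTable
from .grids import GridSpec, InvalidInputError, RasterLayer


@dataclass
class AnnConfig:
    """Architecture and optimisation settings of the richness network."""

    hidden_layers: int = 3
    nodes_per_layer: int = 10
    activation: str = "relu"
    dropout: float = 0.2
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 10
    learning_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise InvalidInputError("dropout must lie in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise InvalidInputError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning_rate must be positive")
        if self.activation != "relu":
            raise InvalidInputError("only the rectifier activation is supported")

    @property
    def n_parameters_per_input(self) -> int:
        return self.hidden_layers * self.nodes_per_layer


@dataclass
class SplitSpec:
    """Disjoint train/test row-index sets covering the table."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices)
        te = np.asarray(self.test_indices)
        if np.intersect1d(tr, te).size:
            raise InvalidInputError("train and test indices overlap")
        self.train_indices, self.test_indices = tr, te


@dataclass
class FitMetrics:
    r2: float
    rmse: float
    scope: str
    n: int


@dataclass
class TrainedRichnessModel:
    """Frozen network weights plus the metadata needed to reproduce predictions."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: AnnConfig
    feature_names: list[str]
    provenance: dict
    split: SplitSpec | None = None
    train_loss: list[float] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "provenance": self.provenance,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "train_loss": self.train_loss,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TrainedRichnessModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=[np.asarray(w) for w in payload["weights"]],
            biases=[np.asarray(b) for b in payload["biases"]],
            config=AnnConfig(**payload["config"]),
            feature_names=list(payload["feature_names"]),
            provenance=payload["provenance"],
            train_loss=list(payload.get("train_loss", [])),
        )


# ---------------------------------------------------------------------------
# core network


def _init_params(n_in: int, config: AnnConfig, rng: np.random.Generator):
    """Fan-in scaled uniform initialisation, seeded."""
    sizes = [n_in] + [config.nodes_per_layer] * config.hidden_layers + [1]
    weights, biases = [], []
    for a, b in zip(sizes[:-1], sizes[1:]):
        bound = 1.0 / np.sqrt(a)
        weights.append(rng.uniform(-bound, bound, size=(a, b)))
        biases.append(np.zeros(b))
    return weights, biases


def _forward(X, weights, biases, dropout=0.0, rng=None):
    """Forward pass; returns predictions and the per-layer caches for backprop.

    Dropout is inverted (activations scaled by 1/keep at train time), so
    inference uses the weights unchanged.
    """
    caches = []
    h = X
    n_layers = len(weights)
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = h @ W + b
        if i < n_layers - 1:
            a = np.maximum(z, 0.0)
            if dropout > 0.0:
                keep = 1.0 - dropout
                mask = (rng.random(a.shape) < keep) / keep
                a = a * mask
            else:
                mask = None
            caches.append((h, z, mask))
            h = a
        else:
            caches.append((h, z, None))
            h = z
    return h[:, 0], caches


def _backward(y_pred, y_true, weights, caches):
    """Backprop through the ReLU/dropout stack (MSE loss, mean over batch)."""
    n = y_true.shape[0]
    grad_w = [None] * len(weights)
    grad_b = [None] * len(weights)
    delta = (2.0 / n) * (y_pred - y_true)[:, None]
    for i in range(len(weights) - 1, -1, -1):
        h_in, _z, _mask = caches[i]
        grad_w[i] = h_in.T @ delta
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            prev_z, prev_mask = caches[i - 1][1], caches[i - 1][2]
            delta = delta @ weights[i].T
            if prev_mask is not None:
                delta = delta * prev_mask
            delta = delta * (prev_z > 0)
    return grad_w, grad_b


def split_train_test(table: FeatureTable, fraction: float = 0.8, seed: int = 0) -> SplitSpec:
    """Uniform random row split, reproducible under the seed."""
    if not (0.0 < fraction < 1.0):
        raise InvalidInputError("fraction must lie in (0, 1)")
    n = table.n_rows
    if n < 10:
        raise InvalidInputError("need at least 10 rows to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fraction * n))
    return SplitSpec(np.sort(perm[:n_train]), np.sort(perm[n_train:]), fraction, seed)


def train_ann(
    table: FeatureTable,
    config: AnnConfig,
    split: SplitSpec | None = None,
    row_indices: np.ndarray | None = None,
) -> TrainedRichnessModel:
    """Train the network on the split's training rows (or ``row_indices``).

    Mini-batch gradient descent with momentum over shuffled training rows;
    inverted dropout on the hidden activations; loss is mean squared error.
    Raises on a non-finite loss, naming the epoch and batch.
    """
    X_all, y_all = table.X, table.y
    if not np.all(np.isfinite(y_all)):
        raise InvalidInputError("response contains non-finite values")
    if row_indices is not None:
        idx = np.asarray(row_indices)
    elif split is not None:
        idx = split.train_indices
    else:
        idx = np.arange(table.n_rows)
    X, y = X_all[idx], y_all[idx]

    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(X.shape[1], config, rng)
    velocity_w = [np.zeros_like(w) for w in weights]
    velocity_b = [np.zeros_like(b) for b in biases]
    losses = []
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for bi, start in enumerate(range(0, n, config.batch_size)):
            batch = order[start : start + config.batch_size]
            y_pred, caches = _forward(
                X[batch], weights, biases, dropout=config.dropout, rng=rng
            )
            loss = float(np.mean((y_pred - y[batch]) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}"
                )
            epoch_loss += loss * batch.size
            grad_w, grad_b = _backward(y_pred, y[batch], weights, caches)
            for i in range(len(weights)):
                velocity_w[i] = config.momentum * velocity_w[i] - config.learning_rate * grad_w[i]
                velocity_b[i] = config.momentum * velocity_b[i] - config.learning_rate * grad_b[i]
                weights[i] = weights[i] + velocity_w[i]
                biases[i] = biases[i] + velocity_b[i]
        losses.append(epoch_loss / n)
    return TrainedRichnessModel(
        weights=weights,
        biases=biases,
        config=config,
        feature_names=list(table.feature_names),
        provenance=table.provenance,
        split=split,
        train_loss=losses,
    )


def predict(model: TrainedRichnessModel, features: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout disabled)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise InvalidInputError(
            f"feature arity {X.shape[1]} != model arity {model.n_features}"
        )
    y, _ = _forward(X, model.weights, model.biases, dropout=0.0)
    return y


def evaluate(
    model: TrainedRichnessModel, table: FeatureTable, scope: str = "test"
) -> FitMetrics:
    """R^2 (1 - SSE/SST) and RMSE on the scaled response for the given scope."""
    if scope == "train" and model.split is not None:
        idx = model.split.train_indices
    elif scope == "test" and model.split is not None:
        idx = model.split.test_indices
    elif scope == "all" or model.split is None:
        idx = np.arange(table.n_rows)
    else:
        raise InvalidInputError(f"unknown scope {scope!r}")
    if idx.size == 0:
        raise InvalidInputError(f"scope {scope!r} has no rows")
    y = table.y[idx]
    y_hat = predict(model, table.X[idx])
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise InvalidInputError("zero-variance response: R^2 undefined")
    sse = float(np.sum((y - y_hat) ** 2))
    return FitMetrics(
        r2=1.0 - sse / sst,
        rmse=float(np.sqrt(np.mean((y - y_hat) ** 2))),
        scope=scope,
        n=int(idx.size),
    )


def cross_validate(
    table: FeatureTable,
    candidate_configs: list[AnnConfig],
    k: int = 5,
    split: SplitSpec | None = None,
    seed: int = 0,
):
    """Select a config by k-fold cross-validation on the training rows.

    Folds partition the training rows exactly.  Selection: smallest mean
    fold RMSE; ties broken by smaller fold-RMSE variance, then by fewer
    nodes, then by candidate order.  Returns (selected config, fold table).
    """
    import pandas as pd

    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if not candidate_configs:
        raise InvalidInputError("no candidate configs")
    rows = split.train_indices if split is not None else np.arange(table.n_rows)
    if rows.size < k:
        raise InvalidInputError("fewer training rows than folds")
    perm = np.random.default_rng(seed).permutation(rows)
    folds = np.array_split(perm, k)

    records = []
    scores = []
    for ci, config in enumerate(candidate_configs):
        fold_rmse = []
        for fi in range(k):
            val_idx = folds[fi]
            train_idx = np.concatenate([folds[j] for j in range(k) if j != fi])
            model = train_ann(table, config, row_indices=train_idx)
            y_hat = predict(model, table.X[val_idx])
            rmse = float(np.sqrt(np.mean((table.y[val_idx] - y_hat) ** 2)))
            fold_rmse.append(rmse)
            records.append({"config": ci, "fold": fi, "rmse": rmse})
        mean_rmse = float(np.mean(fold_rmse))
        var_rmse = float(np.var(fold_rmse, ddof=1))
        size = config.hidden_layers * config.nodes_per_layer
        scores.append((mean_rmse, var_rmse, size, ci))
    best = min(scores)
    fold_table = pd.DataFrame(records)
    fold_table["selected"] = fold_table["config"] == best[3]
    return candidate_configs[best[3]], fold_table


def predict_surface(
    model: TrainedRichnessModel, table: FeatureTable, grid: GridSpec | None = None
) -> RasterLayer:
    """Write predictions back onto the grid (NaN outside the table's cells)."""
    grid = grid or table.grid
    if grid is None:
        raise InvalidInputError("no grid attached to the feature table")
    values = np.full(grid.n_cells, np.nan)
    cell_ids = table.data["cell_id"].to_numpy(dtype=int)
    values[cell_ids] = predict(model, table.X)
    return RasterLayer(grid, values.reshape(grid.shape), "predicted_response")
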