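"""Pointwise MLP surrogate of optimal implant density fields.

The network maps the eleven min-max-scaled inputs (nine design variables
plus the evaluation point's x, y) to the local optimal gyroid volume
fraction, replacing the iterative remodeling optimization with a single
forward pass.  ``DensityMLP`` is a scikit-learn style estimator (it wraps
``MLPRegressor`` but drives training epoch by epoch so that early stopping
monitors the *instance-held-out* validation split with patience 5 and the
best-epoch weights are restored).  Hyperparameters (1-5 hidden layers,
32-256 neurons, tanh/relu/sigmoid activations, batch 32-256) are searched
with a sequential model-based (Gaussian-process) strategy, each candidate
trained for 10 epochs, selecting the lowest validation MAE.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .dataset import Corpus, ScalerParams
from .geometry import DesignVariables, QuadMesh, Region
from .remodeling import DensityField

__all__ = ["MlpSpec", "DensityMLP", "activation", "losses", "tune",
           "train_final", "predict_field", "save_model", "load_model"]

_ACTIVATIONS = ("tanh", "relu", "sigmoid")
_SK_NAMES = {"tanh": "tanh", "relu": "relu", "sigmoid": "logistic"}


def activation(name: str, x):
    """Evaluate a supported hidden-layer activation function."""
    x = np.asarray(x, dtype=float)
    if name == "tanh":
        return np.tanh(x)
    if name == "relu":
        return np.maximum(0.0, x)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown activation {name!r}")


def losses(pred, target) -> tuple[float, float]:
    """(MSE, MAE) between predictions and targets."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("prediction/target length mismatch")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    err = pred - target
    return float(np.mean(err ** 2)), float(np.mean(np.abs(err)))


@dataclass(frozen=True)
class MlpSpec:
    """One point of the hyperparameter search space."""

    n_hidden_layers: int = 5
    neurons_per_layer: int = 128
    activation: str = "relu"
    batch_size: int = 128

    def __post_init__(self) -> None:
        if not 1 <= self.n_hidden_layers <= 5:
            raise ValueError("n_hidden_layers must be 1..5")
        if not 32 <= self.neurons_per_layer <= 256:
            raise ValueError("neurons_per_layer must be 32..256")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if not 32 <= self.batch_size <= 256:
            raise ValueError("batch_size must be 32..256")


class DensityMLP(BaseEstimator, RegressorMixin):
    """MLP regressor with validation-monitored early stopping.

    Parameters mirror :class:`MlpSpec`; the output layer is a single linear
    neuron and training minimizes MSE with Adam (learning rate 1e-3).
    ``fit(X, y, X_val=..., y_val=...)`` monitors the supplied validation set:
    training stops once the validation loss has not decreased for
    ``patience`` consecutive epochs, and the best-epoch weights are
    restored.  Without a validation set it runs all ``max_epochs``.

    Fitted attributes: ``model_`` (the underlying network), ``history_``
    (per-epoch losses), ``best_epoch_``, ``n_epochs_``.
    """

    def __init__(self, n_hidden_layers: int = 5, neurons_per_layer: int = 128,
                 activation: str = "relu", batch_size: int = 128,
                 max_epochs: int = 100, patience: Optional[int] = 5,
                 learning_rate: float = 1e-3, random_state: Optional[int] = None):
        self.n_hidden_layers = n_hidden_layers
        self.neurons_per_layer = neurons_per_layer
        self.activation = activation
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.learning_rate = learning_rate
        self.random_state = random_state

    @property
    def spec(self) -> MlpSpec:
        return MlpSpec(self.n_hidden_layers, self.neurons_per_layer,
                       self.activation, self.batch_size)

    def fit(self, X, y, X_val=None, y_val=None) -> "DensityMLP":
        self.spec  # validates ranges
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        mlp = MLPRegressor(
            hidden_layer_sizes=(self.neurons_per_layer,) * self.n_hidden_layers,
            activation=_SK_NAMES[self.activation],
            solver="adam",
            learning_rate_init=self.learning_rate,
            batch_size=min(self.batch_size, len(y)),
            shuffle=True,
            random_state=self.random_state,
        )
        best_val = np.inf
        best_state = None
        best_epoch = -1
        stall = 0
        rows = []
        for epoch in range(self.max_epochs):
            mlp.partial_fit(X, y)
            train_loss = float(mlp.loss_)
            if not np.isfinite(train_loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            row = dict(epoch=epoch, train_loss=train_loss)
            if X_val is not None:
                val_mse, val_mae = losses(mlp.predict(X_val), y_val)
                row.update(val_loss=val_mse, val_mae=val_mae)
                if val_mse < best_val - 1e-12:
                    best_val, best_epoch, stall = val_mse, epoch, 0
                    best_state = (copy.deepcopy(mlp.coefs_),
                                  copy.deepcopy(mlp.intercepts_))
                else:
                    stall += 1
            rows.append(row)
            if X_val is not None and self.patience is not None and stall >= self.patience:
                break
        if best_state is not None:
            mlp.coefs_, mlp.intercepts_ = best_state
        self.model_ = mlp
        self.history_ = pd.DataFrame(rows)
        self.best_epoch_ = best_epoch if best_epoch >= 0 else len(rows) - 1
        self.n_epochs_ = len(rows)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))


def _encode(spec: MlpSpec) -> np.ndarray:
    onehot = [float(spec.activation == a) for a in _ACTIVATIONS]
    return np.array([
        (spec.n_hidden_layers - 1) / 4.0,
        (spec.neurons_per_layer - 32) / 224.0,
        (spec.batch_size - 32) / 224.0,
        *onehot,
    ])


def _random_spec(rng: np.random.Generator) -> MlpSpec:
    return MlpSpec(
        n_hidden_layers=int(rng.integers(1, 6)),
        neurons_per_layer=int(rng.integers(32, 257)),
        activation=str(rng.choice(_ACTIVATIONS)),
        batch_size=int(rng.integers(32, 257)),
    )


def tune(corpus: Corpus, search_budget: int, seed: int = 0, epochs: int = 10,
         strategy: str = "bayes") -> tuple[MlpSpec, pd.DataFrame]:
    """Hyperparameter search minimizing validation MAE.

    Each candidate trains for ``epochs`` (default 10) epochs.  The "bayes"
    strategy is sequential model-based: after a random warm-up, a Gaussian
    process fitted to (encoded spec -> val MAE) proposes the
    expected-improvement maximizer among random candidates; "random" draws
    every candidate uniformly.  Returns the winning spec and the trial log.
    """
    if search_budget < 1:
        raise ValueError("search budget must be at least 1")
    if strategy not in ("bayes", "random"):
        raise ValueError("strategy must be 'bayes' or 'random'")
    rng = np.random.default_rng(seed)
    X_tr, y_tr = corpus.xy("train")
    X_va, y_va = corpus.xy("val")

    tried: list[MlpSpec] = []
    scores: list[float] = []

    def evaluate(spec: MlpSpec) -> float:
        est = DensityMLP(**spec.__dict__, max_epochs=epochs, patience=None,
                         random_state=int(rng.integers(2 ** 31)))
        est.fit(X_tr, y_tr, X_va, y_va)
        _, mae = losses(est.predict(X_va), y_va)
        tried.append(spec)
        scores.append(mae)
        return mae

    n_warmup = min(search_budget, 4) if strategy == "bayes" else search_budget
    seen = set()
    while len(tried) < n_warmup:
        spec = _random_spec(rng)
        if spec not in seen:
            seen.add(spec)
            evaluate(spec)

    if strategy == "bayes":
        from scipy.stats import norm
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern, WhiteKernel

        while len(tried) < search_budget:
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5) + WhiteKernel(1e-4),
                normalize_y=True, random_state=0)
            gp.fit(np.stack([_encode(s) for s in tried]), np.array(scores))
            pool = [s for s in (_random_spec(rng) for _ in range(256))
                    if s not in seen]
            mu, sd = gp.predict(np.stack([_encode(s) for s in pool]), return_std=True)
            best = min(scores)
            sd = np.maximum(sd, 1e-12)
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            spec = pool[int(np.argmax(ei))]
            seen.add(spec)
            evaluate(spec)

    trials = pd.DataFrame([{**s.__dict__, "val_mae": v} for s, v in zip(tried, scores)])
    return tried[int(np.argmin(scores))], trials


def train_final(corpus: Corpus, spec: MlpSpec, seed: int = 0,
                max_epochs: int = 100, patience: int = 5) -> DensityMLP:
    """Train the selected spec to convergence (early stop, best weights kept).

    The fitted estimator carries the corpus scalers (``scalers_``) so it can
    predict whole fields for new designs.
    """
    X_tr, y_tr = corpus.xy("train")
    X_va, y_va = corpus.xy("val")
    est = DensityMLP(**spec.__dict__, max_epochs=max_epochs, patience=patience,
                     random_state=seed)
    est.fit(X_tr, y_tr, X_va, y_va)
    est.scalers_ = corpus.scalers
    return est


def save_model(model: DensityMLP, prefix) -> None:
    """Persist a trained surrogate: JSON header + npz weight arrays.

    ``prefix`` is a path stem; writes ``<prefix>.json`` (spec, scalers) and
    ``<prefix>.npz`` (per-layer weights/biases).
    """
    import json
    from pathlib import Path

    check_is_fitted(model, "model_")
    header = {
        "params": model.get_params(),
        "scalers": ({"minima": model.scalers_.minima, "maxima": model.scalers_.maxima}
                    if getattr(model, "scalers_", None) else None),
        "n_layers": len(model.model_.coefs_),
    }
    Path(str(prefix) + ".json").write_text(json.dumps(header, indent=1))
    arrays = {}
    for i, (W, b) in enumerate(zip(model.model_.coefs_, model.model_.intercepts_)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(str(prefix) + ".npz", **arrays)


def load_model(prefix) -> DensityMLP:
    """Load a surrogate saved by :func:`save_model`."""
    import json
    from pathlib import Path

    header = json.loads(Path(str(prefix) + ".json").read_text())
    data = np.load(str(prefix) + ".npz")
    est = DensityMLP(**header["params"])
    # rebuild the inner network with a one-sample fit, then restore weights
    n_in = data["W0"].shape[0]
    seed_X = np.zeros((2, n_in))
    seed_y = np.zeros(2)
    mlp = MLPRegressor(
        hidden_layer_sizes=(est.neurons_per_layer,) * est.n_hidden_layers,
        activation=_SK_NAMES[est.activation], solver="adam",
        batch_size=2, random_state=0)
    mlp.partial_fit(seed_X, seed_y)
    mlp.coefs_ = [data[f"W{i}"] for i in range(header["n_layers"])]
    mlp.intercepts_ = [data[f"b{i}"] for i in range(header["n_layers"])]
    est.model_ = mlp
    est.history_ = pd.DataFrame()
    est.best_epoch_ = -1
    est.n_epochs_ = 0
    if header["scalers"]:
        est.scalers_ = ScalerParams(minima=header["scalers"]["minima"],
                                    maxima=header["scalers"]["maxima"])
    return est


def predict_field(model: DensityMLP, dv: DesignVariables, mesh: QuadMesh,
                  vf_min: float = 0.1) -> DensityField:
    """Predict the optimal density field of a design, pointwise.

    Every remodeling-band integration point is evaluated with the training
    scalers; predictions are clamped to [vf_min, 1] and solid regions are
    forced fully dense.
    """
    scalers: ScalerParams = getattr(model, "scalers_", None)
    if scalers is None:
        raise ValueError("model has no attached scalers; train via train_final "
                         "or set model.scalers_")
    band = mesh.ip_region == Region.REMODEL
    frame = pd.DataFrame({
        **{k: getattr(dv, k) for k in DesignVariables.names()},
        "x": mesh.ip_coords[band, 0],
        "y": mesh.ip_coords[band, 1],
    })
    pred = model.predict(scalers.transform(frame))
    vf = np.ones(mesh.n_ip)
    vf[band] = np.clip(pred, vf_min, 1.0)
    return DensityField(vf=vf, mesh=mesh, vf_min=vf_min)
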