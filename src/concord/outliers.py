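"""Outlier detectors for constraint cleaning.

Four families score candidate noisy constraints: Isolation Forest,
one-class SVM and Local Outlier Factor (standard library detectors fitted
on the 7-dimensional pair features), and feed-forward autoencoders whose
per-row reconstruction error is the noise score.  Autoencoders come in a
compressing form (widths shrink to a bottleneck and expand back) and an
L1-sparse form (constant width 7, an L1 penalty on the bottleneck
activations).  The encoder half can also serve as an embedding for a
traditional detector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import LocalOutlierFactor
from sklearn.svm import OneClassSVM

__all__ = [
    "OutlierModelSpec",
    "Autoencoder",
    "ARCHITECTURES",
    "TRAINING_REGIMES",
    "make_detector",
    "fit_and_flag",
    "select_clean_by_error",
    "save_autoencoder",
    "load_autoencoder",
]

#: Named autoencoder architectures: AE1-AE3 compress toward a bottleneck,
#: the _L1 variants keep constant width 7 and rely on the sparsity penalty.
ARCHITECTURES: dict[str, tuple[int, ...]] = {
    "AE1": (7, 3, 7),
    "AE1_L1": (7, 7, 7),
    "AE2": (7, 5, 3, 5, 7),
    "AE2_L1": (7, 7, 7, 7, 7),
    "AE3": (7, 6, 5, 3, 5, 6, 7),
    "AE3_L1": (7, 7, 7, 7, 7, 7, 7),
}

#: Epochs and learning rate per network-size regime (batch size 256 both).
TRAINING_REGIMES: dict[str, dict[str, float]] = {
    "small": {"epochs": 100, "learning_rate": 0.01},
    "large": {"epochs": 30, "learning_rate": 0.001},
}

L1_WEIGHT_DEFAULT = 1e-3


@dataclass
class OutlierModelSpec:
    """Configuration of a traditional detector family.

    ``contamination`` is the assumed outlier fraction used to set the
    flagging threshold (0.1 throughout, matching the noise level the
    oracle injects).
    """

    family: str = "isolation_forest"  # isolation_forest | ocsvm | lof
    contamination: float = 0.1
    nu: float = 0.5
    n_neighbors: int = 20
    n_estimators: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.contamination < 0.5):
            raise ValueError("contamination must lie in (0, 0.5)")
        if self.family not in ("isolation_forest", "ocsvm", "lof"):
            raise ValueError(f"unknown detector family {self.family!r}")


def make_detector(spec: OutlierModelSpec, seed: int | None = None):
    """Instantiate the configured sklearn detector."""
    if spec.family == "isolation_forest":
        return IsolationForest(
            n_estimators=spec.n_estimators,
            contamination=spec.contamination,
            random_state=seed,
        )
    if spec.family == "ocsvm":
        return OneClassSVM(kernel="rbf", nu=spec.nu, gamma="scale")
    return LocalOutlierFactor(
        n_neighbors=spec.n_neighbors, contamination=spec.contamination
    )


def fit_and_flag(
    spec: OutlierModelSpec, X: np.ndarray, seed: int | None = None
) -> tuple[object, np.ndarray, np.ndarray]:
    """Fit a detector on X; return (fitted model, outlier flags, scores).

    Flags are boolean (True = outlier).  Scores are oriented so that
    *larger means more anomalous*, suitable for ranking and AUC.
    """
    n = len(X)
    min_rows = max(10, spec.n_neighbors + 1 if spec.family == "lof" else 10)
    if n < min_rows:
        raise ValueError(
            f"{spec.family} needs at least {min_rows} rows, got {n}; "
            "accumulate more constraints before cleaning"
        )
    det = make_detector(spec, seed=seed)
    if spec.family == "lof":
        labels = det.fit_predict(X)
        scores = -det.negative_outlier_factor_
    else:
        labels = det.fit_predict(X)
        scores = -det.score_samples(X)
    return det, labels == -1, scores


def select_clean_by_error(errors: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Boolean keep-mask over rows: the ceil(keep_fraction * n) rows with
    the lowest error, ties broken toward the lower original index."""
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    n = len(errors)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    k = int(np.ceil(keep_fraction * n))
    order = np.lexsort((np.arange(n), errors))  # stable: error, then index
    mask[order[:k]] = True
    return mask


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class Autoencoder(BaseEstimator):
    """Feed-forward autoencoder trained to reconstruct [0, 1]-scaled rows.

    Hidden layers use rectifier activations, the output layer a logistic
    activation (inputs are min-max scaled).  Training minimises the mean
    squared reconstruction error — optionally plus an L1 penalty
    ``l1_weight * sum|h|`` on the bottleneck activations (the sparse
    variant) — by mini-batch Adam at the configured learning rate.
    Reproducible from ``random_state``.

    Parameters
    ----------
    layer_dims : symmetric tuple of widths, first == last == n_features.
    l1_weight : sparsity weight lambda (0 disables the penalty).
    epochs, learning_rate, batch_size : the optimisation schedule.

    Attributes (after fit)
    ----------------------
    weights_, biases_ : per-layer parameters.
    loss_history_ : mean training loss per epoch.
    """

    def __init__(
        self,
        layer_dims: tuple[int, ...] = (7, 3, 7),
        l1_weight: float = 0.0,
        epochs: int = 100,
        learning_rate: float = 0.01,
        batch_size: int = 256,
        random_state: int | None = 0,
    ):
        self.layer_dims = layer_dims
        self.l1_weight = l1_weight
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _validate_arch(self, n_features: int) -> None:
        dims = tuple(self.layer_dims)
        if dims[0] != dims[-1]:
            raise ValueError("layer_dims must start and end with the input width")
        if dims != dims[::-1]:
            raise ValueError("layer_dims must be symmetric about the bottleneck")
        if dims[0] != n_features:
            raise ValueError(
                f"architecture expects {dims[0]} features, data has {n_features}"
            )
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be >= 0")

    @property
    def bottleneck_index_(self) -> int:
        return (len(self.layer_dims) - 1) // 2

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer; layer 0 is the input."""
        acts = [X]
        a = X
        L = len(self.weights_)
        for l, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = a @ W + b
            a = _sigmoid(z) if l == L - 1 else _relu(z)
            acts.append(a)
        return acts

    # -- sklearn-style surface --------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "Autoencoder":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self._validate_arch(X.shape[1])
        rng = np.random.default_rng(self.random_state)
        dims = tuple(self.layer_dims)
        self.weights_ = []
        self.biases_ = []
        for din, dout in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (din + dout))  # Glorot uniform
            self.weights_.append(rng.uniform(-limit, limit, size=(din, dout)))
            self.biases_.append(np.zeros(dout))

        n = len(X)
        bidx = self.bottleneck_index_
        L = len(self.weights_)
        # Adam state (beta1=0.9, beta2=0.999); the configured learning
        # rates presume an adaptive optimiser to reach near-zero
        # reconstruction error within the epoch budget
        mW = [np.zeros_like(W) for W in self.weights_]
        vW = [np.zeros_like(W) for W in self.weights_]
        mb = [np.zeros_like(b) for b in self.biases_]
        vb = [np.zeros_like(b) for b in self.biases_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                batch = X[order[start: start + self.batch_size]]
                m = len(batch)
                acts = self._forward(batch)
                recon = acts[-1]
                diff = recon - batch
                loss = float(np.mean(diff**2))
                if self.l1_weight > 0:
                    loss += self.l1_weight * float(
                        np.sum(np.abs(acts[bidx])) / m
                    )
                epoch_loss += loss * m
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                # backprop; dL/drecon for mean over batch and features
                grad = 2.0 * diff / diff.size
                grad = grad * recon * (1.0 - recon)  # logistic output layer
                step += 1
                for l in range(L - 1, -1, -1):
                    a_prev = acts[l]
                    gW = a_prev.T @ grad
                    gb = grad.sum(axis=0)
                    if l > 0:
                        grad = grad @ self.weights_[l].T
                        if self.l1_weight > 0 and l == bidx:
                            grad = grad + self.l1_weight * np.sign(acts[l]) / m
                        grad = grad * (acts[l] > 0)  # rectifier derivative
                    mW[l] = b1 * mW[l] + (1 - b1) * gW
                    vW[l] = b2 * vW[l] + (1 - b2) * gW**2
                    mb[l] = b1 * mb[l] + (1 - b1) * gb
                    vb[l] = b2 * vb[l] + (1 - b2) * gb**2
                    c1, c2 = 1 - b1**step, 1 - b2**step
                    self.weights_[l] -= self.learning_rate * (mW[l] / c1) / (
                        np.sqrt(vW[l] / c2) + eps
                    )
                    self.biases_[l] -= self.learning_rate * (mb[l] / c1) / (
                        np.sqrt(vb[l] / c2) + eps
                    )
            self.loss_history_.append(epoch_loss / n)
        self._warn_on_divergence()
        return self

    def _warn_on_divergence(self) -> None:
        h = self.loss_history_
        if len(h) >= 10 and h[-1] > 1.5 * min(h):
            warnings.warn(
                "autoencoder training loss increased substantially; "
                "consider a smaller learning rate"
            )

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Bottleneck (encoder) representation of X."""
        acts = self._forward(np.asarray(X, dtype=float))
        return acts[self.bottleneck_index_]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1]

    def reconstruction_errors(self, X: np.ndarray) -> np.ndarray:
        """Per-row mean squared error between input and reconstruction —
        the noise score (large error = likely outlier)."""
        X = np.asarray(X, dtype=float)
        recon = self.reconstruct(X)
        return np.mean((X - recon) ** 2, axis=1)


def save_autoencoder(model: Autoencoder, path) -> None:
    """Persist a fitted autoencoder (architecture, schedule, seed and
    weights) as JSON so a cleaning run can be audited or replayed."""
    payload = {
        "params": model.get_params(),
        "weights": [W.tolist() for W in model.weights_],
        "biases": [b.tolist() for b in model.biases_],
        "loss_history": list(model.loss_history_),
    }
    payload["params"]["layer_dims"] = list(payload["params"]["layer_dims"])
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_autoencoder(path) -> Autoencoder:
    with open(path) as fh:
        payload = json.load(fh)
    params = payload["params"]
    params["layer_dims"] = tuple(params["layer_dims"])
    model = Autoencoder(**params)
    model.weights_ = [np.asarray(W) for W in payload["weights"]]
    model.biases_ = [np.asarray(b) for b in payload["biases"]]
    model.loss_history_ = payload["loss_history"]
    return model


def make_autoencoder(
    name: str,
    regime: str = "small",
    l1_weight: float | None = None,
    random_state: int | None = 0,
) -> Autoencoder:
    """Autoencoder by architecture name ('AE1'...'AE3_L1') and size regime."""
    dims = ARCHITECTURES[name]
    sched = TRAINING_REGIMES[regime]
    if l1_weight is None:
        l1_weight = L1_WEIGHT_DEFAULT if name.endswith("_L1") else 0.0
    return Autoencoder(
        layer_dims=dims,
        l1_weight=l1_weight,
        epochs=int(sched["epochs"]),
        learning_rate=float(sched["learning_rate"]),
        batch_size=256,
        random_state=random_state,
    )
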