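"""Prediction models mapping measured astigmatism vectors to recCP.

Three model families, all operating on 2-vectors (C0, C45):

* ``ConstantCentroidModel`` — adds a fixed offset (centroid correction);
* ``BivariateLinearModel`` — y = A x + b fitted by maximum likelihood.
  With complete data the ML/ECM fixed point coincides with per-output
  ordinary least squares; the log-likelihood is evaluated under a
  bivariate normal residual model with the ML (divide-by-N) covariance.
* ``ShallowNetModel`` — a 2 -> 12 -> 12 -> 2 feedforward network with tanh
  hidden layers and a linear output, trained by full-batch Adam on the
  mean squared error with early stopping on an explicit validation set.

``published_models`` returns the five fixed regression models (one per
corneal-astigmatism measurement modality) reported for the MX60P cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MODALITIES",
    "SplitSpec",
    "split_dataset",
    "BivariateLinearModel",
    "fit_bivariate_regression",
    "predict_linear",
    "published_models",
    "ConstantCentroidModel",
    "fit_constant_model",
    "NetConfig",
    "ShallowNetModel",
    "fit_shallow_net",
    "predict_net",
    "SingularDesignError",
    "save_model",
    "load_model",
]

MODALITIES = ("IOLMK", "GK", "TCP2", "CorT", "CorTTP")


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the regression design matrix is (numerically) singular."""


# ---------------------------------------------------------------------------
# data splitting


@dataclass(frozen=True)
class SplitSpec:
    """A 60/20/20 train/validation/test partition of record indices."""

    seed: int
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    train: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    validation: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    test: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def split_dataset(
    n: int, seed: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> SplitSpec:
    """Randomly partition ``range(n)`` into train/validation/test sets.

    Sizes are round(f_train*n), round(f_val*n) and the remainder, so
    n = 509 yields the canonical 305/102/102.  Deterministic given seed.
    """
    if n < 5:
        raise ValueError(f"need at least 5 records to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n_train = round(fractions[0] * n)
    n_val = round(fractions[1] * n)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(
        seed=seed,
        fractions=tuple(fractions),
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
    )


# ---------------------------------------------------------------------------
# bivariate linear regression (ML / ECM fixed point = OLS for complete data)


@dataclass(frozen=True)
class BivariateLinearModel:
    """y = A x + b with x, y in (C0, C45) space; logL at the ML solution."""

    A: np.ndarray  # (2, 2)
    b: np.ndarray  # (2,)
    logL: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x @ np.asarray(self.A).T + np.asarray(self.b)

    def to_dict(self) -> dict:
        return {
            "kind": "bivariate_linear",
            "A": np.asarray(self.A).tolist(),
            "b": np.asarray(self.b).tolist(),
            "logL": None if np.isnan(self.logL) else float(self.logL),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BivariateLinearModel":
        return cls(
            A=np.asarray(d["A"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            logL=float("nan") if d.get("logL") is None else float(d["logL"]),
        )


def _gaussian_loglik(resid: np.ndarray) -> float:
    """Bivariate normal log-likelihood of residuals at the ML covariance."""
    n = resid.shape[0]
    sigma = resid.T @ resid / n  # ML (divide-by-N) covariance
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return float("-inf")
    d = resid.shape[1]
    # trace(Sigma^-1 Sigma_hat) = d exactly at the ML covariance
    return -0.5 * n * (d * np.log(2.0 * np.pi) + logdet + d)


def fit_bivariate_regression(
    X: Sequence[Sequence[float]], Y: Sequence[Sequence[float]]
) -> BivariateLinearModel:
    """Fit y = A x + b by maximum likelihood on complete (x, y) pairs.

    For complete data the iterative ECM solution reduces to ordinary least
    squares with intercept, solved per output component; the reported logL
    is the bivariate normal log-likelihood at the ML residual covariance.
    Residuals have exactly zero mean on the training data.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or X.shape != Y.shape:
        raise ValueError(f"X and Y must both be (n, 2); got {X.shape}, {Y.shape}")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("X and Y must be finite (no missing values in scope)")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    design = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise SingularDesignError("design matrix is rank-deficient (collinear X)")
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)  # (3, 2)
    A = coef[:2].T
    b = coef[2]
    resid = Y - (X @ A.T + b)
    return BivariateLinearModel(A=A, b=b, logL=_gaussian_loglik(resid))


def predict_linear(m: BivariateLinearModel, x: np.ndarray) -> np.ndarray:
    """Evaluate A x + b for a single (C0, C45) pair or an (n, 2) batch."""
    return m.predict(x)


_PUBLISHED = {
    "IOLMK": ([[0.543, 0.070], [-0.01, 0.375]], [-0.304, -0.043], -332.0),
    "GK": ([[0.524, 0.010], [-0.024, 0.336]], [-0.392, -0.023], -337.0),
    "TCP2": ([[0.508, -0.051], [-0.002, 0.269]], [-0.252, -0.021], -277.0),
    "CorT": ([[0.559, -0.088], [0.038, 0.314]], [-0.302, -0.053], -276.0),
    "CorTTP": ([[0.512, -0.006], [0.022, 0.313]], [-0.236, -0.024], -257.0),
}


def published_models() -> dict[str, BivariateLinearModel]:
    """The five fixed measured-astigmatism -> recCP regression models
    reported for the MX60P cohort (one per modality), with the published
    training log-likelihoods."""
    return {
        name: BivariateLinearModel(
            A=np.array(a, dtype=float), b=np.array(b, dtype=float), logL=logl
        )
        for name, (a, b, logl) in _PUBLISHED.items()
    }


# ---------------------------------------------------------------------------
# constant centroid correction


@dataclass(frozen=True)
class ConstantCentroidModel:
    """Prediction = x + offset: shifts the centroid, leaves the spread."""

    offset: np.ndarray  # (2,)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) + np.asarray(self.offset)

    def to_dict(self) -> dict:
        return {"kind": "constant_centroid", "offset": np.asarray(self.offset).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ConstantCentroidModel":
        return cls(offset=np.asarray(d["offset"], dtype=float))


def fit_constant_model(
    X: Sequence[Sequence[float]], Y: Sequence[Sequence[float]]
) -> ConstantCentroidModel:
    """offset = mean(Y) - mean(X); zeroes the training centroid error while
    leaving the error-ellipse area unchanged."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) < 1 or X.shape != Y.shape:
        raise ValueError("need at least one (x, y) pair of equal shape")
    return ConstantCentroidModel(offset=Y.mean(axis=0) - X.mean(axis=0))


# ---------------------------------------------------------------------------
# shallow feedforward network


@dataclass(frozen=True)
class NetConfig:
    """Training configuration for the shallow network.

    Defaults mirror common shallow-fitnet practice: tanh hidden layers,
    linear output, inputs/outputs rescaled to [-1, 1] over the training
    range, full-batch Adam, early stopping after ``patience`` validation
    checks without improvement.
    """

    hidden: tuple[int, int] = (12, 12)
    learning_rate: float = 0.02
    max_epochs: int = 1000
    patience: int = 6
    val_check_every: int = 5  # epochs between validation checks
    seed: int = 0


@dataclass(frozen=True)
class ShallowNetModel:
    """Weights, biases and scaling of the fitted 2 -> 12 -> 12 -> 2 net."""

    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    in_offset: np.ndarray
    in_scale: np.ndarray
    out_offset: np.ndarray
    out_scale: np.ndarray
    seed: int
    train_mse: float = float("nan")
    val_mse: float = float("nan")
    epochs_run: int = 0
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        h = ((np.atleast_2d(x) - self.in_offset) / self.in_scale)
        for W, c in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ W + c)
        out = h @ self.weights[-1] + self.biases[-1]
        out = out * self.out_scale + self.out_offset
        return out[0] if single else out

    def to_dict(self) -> dict:
        return {
            "kind": "shallow_net",
            "weights": [w.tolist() for w in self.weights],
            "biases": [c.tolist() for c in self.biases],
            "in_offset": self.in_offset.tolist(),
            "in_scale": self.in_scale.tolist(),
            "out_offset": self.out_offset.tolist(),
            "out_scale": self.out_scale.tolist(),
            "seed": int(self.seed),
            "train_mse": None if np.isnan(self.train_mse) else float(self.train_mse),
            "val_mse": None if np.isnan(self.val_mse) else float(self.val_mse),
            "epochs_run": int(self.epochs_run),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShallowNetModel":
        return cls(
            weights=tuple(np.asarray(w, dtype=float) for w in d["weights"]),
            biases=tuple(np.asarray(c, dtype=float) for c in d["biases"]),
            in_offset=np.asarray(d["in_offset"], dtype=float),
            in_scale=np.asarray(d["in_scale"], dtype=float),
            out_offset=np.asarray(d["out_offset"], dtype=float),
            out_scale=np.asarray(d["out_scale"], dtype=float),
            seed=int(d["seed"]),
            train_mse=float("nan") if d.get("train_mse") is None else d["train_mse"],
            val_mse=float("nan") if d.get("val_mse") is None else d["val_mse"],
            epochs_run=int(d.get("epochs_run", 0)),
            converged=bool(d.get("converged", True)),
        )


def _range_scaling(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Offset/scale mapping the training range of each column to [-1, 1]."""
    lo, hi = Z.min(axis=0), Z.max(axis=0)
    offset = (hi + lo) / 2.0
    scale = (hi - lo) / 2.0
    scale = np.where(scale <= 0, 1.0, scale)
    return offset, scale


def _init_layers(sizes: Sequence[int], rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def fit_shallow_net(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    config: NetConfig = NetConfig(),
) -> ShallowNetModel:
    """Train the shallow network on (C0, C45) pairs.

    Full-batch Adam on the MSE of the scaled outputs; validation MSE is
    checked every ``val_check_every`` epochs and training stops after
    ``patience`` consecutive checks without improvement.  The best-so-far
    weights (by validation MSE) are returned, also on non-convergence.
    Deterministic given ``config.seed``.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    Y_val = np.atleast_2d(np.asarray(Y_val, dtype=float))
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")

    in_off, in_sc = _range_scaling(X_train)
    out_off, out_sc = _range_scaling(Y_train)
    Xs, Ys = (X_train - in_off) / in_sc, (Y_train - out_off) / out_sc
    Xv, Yv = (X_val - in_off) / in_sc, (Y_val - out_off) / out_sc

    rng = np.random.default_rng(config.seed)
    sizes = [X_train.shape[1], *config.hidden, Y_train.shape[1]]
    weights, biases = _init_layers(sizes, rng)
    params = weights + biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def forward(x):
        acts = [x]
        h = x
        for W, c in zip(weights[:-1], biases[:-1]):
            h = np.tanh(h @ W + c)
            acts.append(h)
        acts.append(h @ weights[-1] + biases[-1])
        return acts

    def val_mse():
        out = forward(Xv)[-1]
        return float(np.mean((out - Yv) ** 2))

    best_val = val_mse()
    best = [p.copy() for p in params]
    fails = 0
    t = 0
    epochs_run = 0
    converged = False
    n = len(Xs)
    for epoch in range(1, config.max_epochs + 1):
        acts = forward(Xs)
        delta = 2.0 * (acts[-1] - Ys) / (n * Ys.shape[1])  # dMSE/dout
        grads_w, grads_b = [], []
        for layer in range(len(weights) - 1, -1, -1):
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ weights[layer].T) * (1.0 - acts[layer] ** 2)
        grads = grads_w[::-1] + grads_b[::-1]
        t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mhat = m[i] / (1 - beta1**t)
            vhat = v[i] / (1 - beta2**t)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        epochs_run = epoch
        if epoch % config.val_check_every == 0:
            current = val_mse()
            if current < best_val - 1e-12:
                best_val = current
                best = [p.copy() for p in params]
                fails = 0
            else:
                fails += 1
                if fails >= config.patience:
                    converged = True
                    break
    else:
        converged = epochs_run < config.max_epochs

    k = len(weights)
    weights = [b.copy() for b in best[:k]]
    biases = [b.copy() for b in best[k:]]
    model = ShallowNetModel(
        weights=tuple(weights),
        biases=tuple(biases),
        in_offset=in_off,
        in_scale=in_sc,
        out_offset=out_off,
        out_scale=out_sc,
        seed=config.seed,
        epochs_run=epochs_run,
        converged=converged,
    )
    train_pred = model.predict(X_train)
    val_pred = model.predict(X_val)
    return replace(
        model,
        train_mse=float(np.mean(np.sum((train_pred - Y_train) ** 2, axis=1))),
        val_mse=float(np.mean(np.sum((val_pred - Y_val) ** 2, axis=1))),
    )


def predict_net(m: ShallowNetModel, x: np.ndarray) -> np.ndarray:
    """Forward pass through the stored network (single pair or batch)."""
    return m.predict(x)


# ---------------------------------------------------------------------------
# serialization

_MODEL_KINDS = {
    "bivariate_linear": BivariateLinearModel,
    "constant_centroid": ConstantCentroidModel,
    "shallow_net": ShallowNetModel,
}


def save_model(model, path: str | Path) -> None:
    """Write any model to JSON (schema keyed by a ``kind`` tag)."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path: str | Path):
    """Read a model written by :func:`save_model`."""
    d = json.loads(Path(path).read_text())
    try:
        cls = _MODEL_KINDS[d["kind"]]
    except KeyError as exc:
        raise ValueError(f"unknown model kind {d.get('kind')!r}") from exc
    return cls.from_dict(d)
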