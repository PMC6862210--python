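"""Classifiers over multi-task pair features.

Three scoring paths:

* the published linear discriminant — a fixed affine score over the four
  pair features (⟨Tr3⟩, ⟨Tr5⟩, DTr3, DTr5) that ships as the package
  default;
* a retrainable Fisher linear discriminant (pooled within-class covariance,
  intercept at the pooled-mean midpoint);
* a one-hidden-layer perceptron (4-h-2 topology, softmax outputs,
  cross-entropy loss, full-batch gradient descent) for the non-linear
  decision surface that per-class prediction needs.

Predictor importance is ranked by sensitivity analysis: the ratio of the
model's error with one feature neutralised (replaced by its column mean, or
permuted) to the baseline error.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

FEATURES: tuple[str, ...] = ("Tr3_mean", "Tr5_mean", "DTr3", "DTr5")

#: published discriminant coefficients and intercept
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "Tr3_mean": -0.95,
    "Tr5_mean": -0.80,
    "DTr5": -0.80,
    "DTr3": 1.01,
}
PUBLISHED_INTERCEPT: float = -2.05


@dataclass
class LinearModel:
    """Affine score over the four pair features; defaults are the published fit."""

    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(PUBLISHED_COEFFICIENTS)
    )
    intercept: float = PUBLISHED_INTERCEPT
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(FEATURES) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing coefficients for {sorted(missing)}")
        values = [*self.coefficients.values(), self.intercept]
        if not np.all(np.isfinite(values)):
            raise ValueError("model coefficients must be finite")

    def score(self, features: Mapping[str, float]) -> float:
        return lda_score(features, self)


def lda_score(features: Mapping[str, float], model: LinearModel | None = None) -> float:
    """Discriminant score  Σ_i w_i x_i + b  of one pair-feature mapping.

    With the default (published) model:
    score = −0.95·⟨Tr3⟩ − 0.80·⟨Tr5⟩ − 0.80·DTr5 + 1.01·DTr3 − 2.05.
    """
    if model is None:
        model = LinearModel()
    total = model.intercept
    for name, coef in model.coefficients.items():
        if name not in features:
            raise KeyError(f"feature {name!r} missing from input")
        value = float(features[name])
        if not np.isfinite(value):
            raise ValueError(f"feature {name!r} is not finite")
        total += coef * value
    return float(total)


def classify(score: float, threshold: float = 0.0) -> int:
    """+1 iff score strictly exceeds the threshold; −1 otherwise (ties → −1)."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return 1 if score > threshold else -1


def _feature_matrix(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURES if c not in pairs.columns]
    if missing:
        raise ValueError(f"pair table lacks feature columns {missing}")
    X = pairs[list(FEATURES)].to_numpy(dtype=float)
    y = pairs["label"].to_numpy(dtype=int)
    return X, y


def fit_lda(pairs: pd.DataFrame, ridge: float = 0.0) -> LinearModel:
    """Two-class Fisher discriminant on the four pair features.

    Direction w = S_w⁻¹ (μ₊ − μ₋) with S_w the pooled within-class
    covariance; intercept places the decision boundary at the midpoint of
    the class means, so positive scores side with the +1 (enzyme-pair)
    class.  ``ridge`` adds a diagonal regulariser when S_w is singular.
    """
    X, y = _feature_matrix(pairs)
    for label in (1, -1):
        if (y == label).sum() < 5:
            raise ValueError(f"need at least 5 records with label {label}")
    Xp, Xn = X[y == 1], X[y == -1]
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    # pooled within-class covariance
    sw = (
        (Xp - mu_p).T @ (Xp - mu_p) + (Xn - mu_n).T @ (Xn - mu_n)
    ) / (len(X) - 2)
    if ridge:
        sw = sw + ridge * np.eye(sw.shape[0])
    try:
        w = np.linalg.solve(sw, mu_p - mu_n)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular; "
            "retry with a ridge > 0 regulariser"
        ) from None
    # Mahalanobis separation vs its null expectation p(1/n+ + 1/n-)
    d2 = float(w @ (mu_p - mu_n))
    null_d2 = X.shape[1] * (1.0 / len(Xp) + 1.0 / len(Xn))
    if d2 <= 5.0 * null_d2:
        warnings.warn(
            "class distributions are statistically indistinguishable; "
            "near-zero discriminant direction"
        )
    intercept = -float(w @ (mu_p + mu_n) / 2.0)
    return LinearModel(
        coefficients={name: float(c) for name, c in zip(FEATURES, w)},
        intercept=intercept,
        metadata={"fitted": True, "ridge": ridge, "n_records": int(len(X))},
    )


def standardized_coefficients(model: LinearModel, pairs: pd.DataFrame) -> dict[str, float]:
    """Coefficients rescaled by feature standard deviations (comparable sizes)."""
    X, _ = _feature_matrix(pairs)
    sd = X.std(axis=0, ddof=1)
    return {
        name: float(model.coefficients[name] * s) for name, s in zip(FEATURES, sd)
    }


# ---------------------------------------------------------------------------
# one-hidden-layer perceptron
# ---------------------------------------------------------------------------


@dataclass
class PerceptronModel:
    """4-h-2 perceptron: tanh hidden layer, softmax outputs.

    Inputs are standardised with the training means/scales stored on the
    model.  ``score`` returns the logit difference (class +1 minus class
    −1), so 0 is the natural decision threshold.
    """

    w1: np.ndarray  # (4, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h, 2)
    b2: np.ndarray  # (2,)
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    seed: int
    activation: str = "tanh"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h = self.w1.shape[1]
        if h < 1:
            raise ValueError("hidden layer must have at least 1 unit")
        if self.w1.shape[0] != len(FEATURES) or self.w2.shape != (h, 2):
            raise ValueError("inconsistent layer shapes for a 4-h-2 topology")

    @property
    def hidden(self) -> int:
        return self.w1.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def _logits(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_mean) / self.feature_scale
        return np.tanh(Z @ self.w1 + self.b1) @ self.w2 + self.b2

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        logits = self._logits(np.atleast_2d(X))
        return logits[:, 1] - logits[:, 0]  # column 1 = class +1

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) > 0, 1, -1)

    def score(self, features: Mapping[str, float]) -> float:
        x = np.array([[float(features[name]) for name in FEATURES]])
        return float(self.decision_values(x)[0])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fit_mlp(
    pairs: pd.DataFrame,
    hidden: int = 9,
    seed: int = 0,
    max_epochs: int = 3000,
    learning_rate: float = 0.02,
    split_fraction: float = 0.70,
    tol: float = 1e-6,
) -> PerceptronModel:
    """Train a 4-h-2 perceptron on pair records by full-batch gradient descent.

    The pair table is split 70/30 (seeded); the network is trained on the
    70% portion with cross-entropy loss and momentum, and train/validation
    accuracies are recorded in the model metadata.  Deterministic for a
    given seed.  If the loss has not levelled off within ``max_epochs`` a
    warning is issued and the best weights seen are returned.
    """
    if hidden < 1:
        raise ValueError("hidden must be ≥ 1")
    from .multitask import split_pairs  # deferred: avoids an import cycle

    train_df, valid_df = split_pairs(pairs, fraction=split_fraction, seed=seed)
    if valid_df.empty:
        valid_df = train_df
    X, y = _feature_matrix(train_df)
    Xv, yv = _feature_matrix(valid_df)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    T = np.column_stack([(y == -1), (y == 1)]).astype(float)  # one-hot

    rng = np.random.default_rng(seed)
    h = hidden
    w1 = rng.normal(scale=0.5, size=(len(FEATURES), h))
    b1 = np.zeros(h)
    w2 = rng.normal(scale=0.5, size=(h, 2))
    b2 = np.zeros(2)
    # Adam moments (full-batch adaptive gradient descent)
    m1 = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
    m2 = [np.zeros_like(p) for p in (w1, b1, w2, b2)]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    Z = (X - mean) / scale
    n = len(Z)
    best = (np.inf, None)
    prev_loss = np.inf
    converged = False
    for t in range(1, max_epochs + 1):
        H = np.tanh(Z @ w1 + b1)
        P = _softmax(H @ w2 + b2)
        loss = float(-(T * np.log(np.clip(P, 1e-12, None))).sum() / n)
        if loss < best[0]:
            best = (loss, (w1.copy(), b1.copy(), w2.copy(), b2.copy()))
        if abs(prev_loss - loss) < tol or loss < 1e-4:
            converged = True
            break
        prev_loss = loss
        dlogits = (P - T) / n
        grads = (
            Z.T @ (dlogits @ w2.T * (1 - H**2)),
            (dlogits @ w2.T * (1 - H**2)).sum(axis=0),
            H.T @ dlogits,
            dlogits.sum(axis=0),
        )
        params = [w1, b1, w2, b2]
        for i, (p, g) in enumerate(zip(params, grads)):
            m1[i] = beta1 * m1[i] + (1 - beta1) * g
            m2[i] = beta2 * m2[i] + (1 - beta2) * g**2
            mhat = m1[i] / (1 - beta1**t)
            vhat = m2[i] / (1 - beta2**t)
            p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
    if not converged:
        warnings.warn(
            f"MLP training did not converge within {max_epochs} epochs; "
            "returning the best weights seen"
        )
    w1, b1, w2, b2 = best[1]
    model = PerceptronModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        feature_mean=mean, feature_scale=scale, seed=seed,
    )
    model.metadata.update(
        {
            "hidden": h,
            "final_loss": best[0],
            "converged": converged,
            "train_accuracy": float((model.predict(X) == y).mean()),
            "validation_accuracy": float((model.predict(Xv) == yv).mean()),
            "split_fraction": split_fraction,
        }
    )
    return model


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


def _model_error(model, X: np.ndarray, y: np.ndarray) -> float:
    """Misclassification rate of the model against the ±1 targets.

    Classification error (not a score residual) is what degrades when a
    predictor is neutralised, so it is the quantity sensitivity ratios are
    built from.
    """
    if isinstance(model, LinearModel):
        w = np.array([model.coefficients[f] for f in FEATURES])
        pred = np.where(X @ w + model.intercept > 0, 1, -1)
    else:
        pred = model.predict(X)
    return float(np.mean(pred != y))


def sensitivity_analysis(
    model,
    pairs: pd.DataFrame,
    method: str = "mean-substitution",
    seed: int = 0,
    floor: float = 1e-12,
) -> pd.Series:
    """Rank predictors by the error inflation caused by neutralising them.

    For each feature the model error is recomputed with that feature column
    replaced by its mean (``method="mean-substitution"``) or randomly
    permuted (``method="permutation"``, seeded), and divided by the baseline
    error.  Features are returned sorted by descending sensitivity; an
    (effectively) zero baseline error is floored at ``floor`` with a
    warning, so the ranking is still usable.
    """
    if method not in ("mean-substitution", "permutation"):
        raise ValueError(f"unknown sensitivity method {method!r}")
    X, y = _feature_matrix(pairs)
    baseline = _model_error(model, X, y)
    if baseline < floor:
        warnings.warn(
            "baseline error is (near) zero; sensitivities are ratios to a floor"
        )
        baseline = floor
    rng = np.random.default_rng(seed)
    ratios = {}
    for i, name in enumerate(FEATURES):
        Xi = X.copy()
        if method == "mean-substitution":
            Xi[:, i] = X[:, i].mean()
        else:
            Xi[:, i] = rng.permutation(X[:, i])
        ratios[name] = _model_error(model, Xi, y) / baseline
    return pd.Series(ratios).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def save_model(model: LinearModel | PerceptronModel, path: str | Path) -> None:
    """Serialise a model to JSON (schema: type, coefficients/weights, metadata)."""
    meta = {
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "feature_names": list(FEATURES),
    }
    if isinstance(model, LinearModel):
        payload = {
            "type": "lda",
            "coefficients": model.coefficients,
            "intercept": model.intercept,
            "metadata": {**meta, **model.metadata},
        }
    elif isinstance(model, PerceptronModel):
        payload = {
            "type": "mlp",
            "weights": {
                "w1": model.w1.tolist(),
                "b1": model.b1.tolist(),
                "w2": model.w2.tolist(),
                "b2": model.b2.tolist(),
                "feature_mean": model.feature_mean.tolist(),
                "feature_scale": model.feature_scale.tolist(),
            },
            "activation": model.activation,
            "metadata": {**meta, "seed": model.seed, **model.metadata},
        }
    else:
        raise TypeError(f"cannot serialise model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> LinearModel | PerceptronModel:
    payload = json.loads(Path(path).read_text())
    return _model_from_payload(payload)


def _model_from_payload(payload: dict) -> LinearModel | PerceptronModel:
    kind = payload.get("type")
    if kind == "lda":
        return LinearModel(
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            intercept=float(payload["intercept"]),
            metadata=payload.get("metadata", {}),
        )
    if kind == "mlp":
        w = payload["weights"]
        return PerceptronModel(
            w1=np.asarray(w["w1"], dtype=float),
            b1=np.asarray(w["b1"], dtype=float),
            w2=np.asarray(w["w2"], dtype=float),
            b2=np.asarray(w["b2"], dtype=float),
            feature_mean=np.asarray(w["feature_mean"], dtype=float),
            feature_scale=np.asarray(w["feature_scale"], dtype=float),
            seed=int(payload.get("metadata", {}).get("seed", 0)),
            activation=payload.get("activation", "tanh"),
            metadata=payload.get("metadata", {}),
        )
    raise ValueError(f"unknown model type {kind!r}")


def load_default_model() -> LinearModel:
    """The published discriminant that ships with the package."""
    text = resources.files("srnzyme.data").joinpath("published_lda.json").read_text()
    return _model_from_payload(json.loads(text))
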