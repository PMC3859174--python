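"""Bitterness model builders: MLR, epsilon-SVR, small ANN, published equation.

The published six-descriptor linear model

    log(1/T) = 5.45 + 0.10 SPAN + 0.32 Mor11v - 7.88 MSD
               - 1.55 HATS8u - 5.39 G3p + 0.92 E3s

is available as a fixed predictor (:func:`predict_published`).  New models
are fitted with ordinary least squares (:func:`fit_mlr`, with the full
coefficient table), epsilon-insensitive support-vector regression with an
RBF kernel (:func:`fit_svr`, hyperparameters default to the published
cross-validated optimum C=91, eps=0.07, gamma=0.06), or a one-hidden-layer
feed-forward network trained by Levenberg-Marquardt damped least squares
with early stopping (:func:`fit_ann`).  SVR and ANN inputs are z-scored on
training statistics; MLR is fitted on the raw scale so its coefficients
stay comparable with the published equation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "PUBLISHED_COEFFS",
    "PUBLISHED_COEFF_SES",
    "predict_published",
    "FittedModel",
    "SvrConfig",
    "AnnConfig",
    "fit_mlr",
    "fit_svr",
    "tune_svr",
    "fit_ann",
]

#: The published equation: intercept and slopes on the log(1/T) scale.
PUBLISHED_COEFFS: dict[str, float] = {
    "intercept": 5.45,
    "SPAN": 0.10,
    "Mor11v": 0.32,
    "MSD": -7.88,
    "HATS8u": -1.55,
    "G3p": -5.39,
    "E3s": 0.92,
}

#: Printed standard errors of the published coefficients.
PUBLISHED_COEFF_SES: dict[str, float] = {
    "intercept": 0.63,
    "SPAN": 0.02,
    "Mor11v": 0.09,
    "MSD": 1.25,
    "HATS8u": 0.30,
    "G3p": 2.1,
    "E3s": 0.35,
}

DESCRIPTOR_ORDER = ("SPAN", "Mor11v", "MSD", "HATS8u", "G3p", "E3s")


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


class TrainingError(RuntimeError):
    """Iterative training diverged (non-finite loss or damping overflow)."""


def predict_published(vector) -> float | np.ndarray:
    """Evaluate the published six-descriptor equation.

    ``vector`` may be a mapping, a :class:`~qsbr.descriptors3d.DescriptorVector`,
    or a DataFrame with the six named columns; each required descriptor
    must be present and finite.
    """
    if hasattr(vector, "as_dict"):
        vector = vector.as_dict()
    if isinstance(vector, pd.DataFrame):
        out = np.full(len(vector), PUBLISHED_COEFFS["intercept"])
        for name in DESCRIPTOR_ORDER:
            if name not in vector.columns:
                raise KeyError(f"missing descriptor column {name!r}")
            out = out + PUBLISHED_COEFFS[name] * vector[name].to_numpy(dtype=float)
        return out
    total = PUBLISHED_COEFFS["intercept"]
    for name in DESCRIPTOR_ORDER:
        if name not in vector:
            raise KeyError(f"missing descriptor {name!r}")
        value = float(vector[name])
        if not np.isfinite(value):
            raise ValueError(f"descriptor {name!r} is not finite")
        total += PUBLISHED_COEFFS[name] * value
    return total


@dataclass
class FittedModel:
    """A trained predictor with its provenance.

    ``predict`` accepts a DataFrame containing (at least) the training
    columns, in any order, and returns log(1/T) predictions.
    """

    family: str
    columns: list[str]
    parameters: dict
    n_train: int
    seed: int | None = None
    _predict_fn: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def predict(self, matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(matrix, pd.DataFrame):
            missing = [c for c in self.columns if c not in matrix.columns]
            if missing:
                raise KeyError(f"missing column(s) {missing}")
            X = matrix[self.columns].to_numpy(dtype=float)
        else:
            X = np.asarray(matrix, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.columns):
                raise ValueError(
                    f"expected {len(self.columns)} columns, got {X.shape[1]}"
                )
        return self._predict_fn(X)

    def to_json(self, path: str | Path) -> None:
        """Serialize family, columns and parameters (weights as flat lists)."""
        payload = {
            "family": self.family,
            "columns": self.columns,
            "n_train": self.n_train,
            "seed": self.seed,
            "parameters": _jsonable(self.parameters),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# --------------------------------------------------------------------------
# MLR


def fit_mlr(matrix: pd.DataFrame, response: Sequence[float]) -> FittedModel:
    """Ordinary least squares with the full inferential table.

    The returned model's ``parameters`` hold the coefficient table
    (estimate and standard error per term), R^2, adjusted R^2, the F
    statistic and the standard error of the estimate (``sep``).

    Raises :class:`RankDeficiencyError` on collinear columns (the message
    lists them).
    """
    y = np.asarray(response, dtype=float)
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < p:
        # identify a minimal set of columns involved in the dependency
        R = np.corrcoef(X, rowvar=False)
        pairs = [
            (matrix.columns[i], matrix.columns[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(R[i, j]) > 0.999999
        ]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"exactly collinear pairs: {pairs or 'multi-column dependency'}"
        )
    res = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["intercept"] + list(matrix.columns)
    coef_table = pd.DataFrame(
        {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues},
        index=names,
    )
    params = {
        "coefficients": dict(zip(names, res.params)),
        "standard_errors": dict(zip(names, res.bse)),
        "r2": float(res.rsquared),
        "adj_r2": float(res.rsquared_adj),
        "f_statistic": float(res.fvalue),
        "sep": float(np.sqrt(res.mse_resid)),
    }
    beta = res.params.copy()

    model = FittedModel(
        family="mlr",
        columns=list(matrix.columns),
        parameters=params,
        n_train=n,
        _predict_fn=lambda A: beta[0] + A @ beta[1:],
    )
    model.coef_table = coef_table
    return model


# --------------------------------------------------------------------------
# SVR


@dataclass(frozen=True)
class SvrConfig:
    """epsilon-SVR hyperparameters (defaults: the published CV optimum)."""

    C: float = 91.0
    epsilon: float = 0.07
    gamma: float = 0.06
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if min(self.C, self.epsilon, self.gamma) <= 0:
            raise ValueError("C, epsilon and gamma must be positive")

    def with_(self, **kwargs) -> "SvrConfig":
        return replace(self, **kwargs)


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def fit_svr(
    matrix: pd.DataFrame,
    response: Sequence[float],
    config: SvrConfig = SvrConfig(),
) -> FittedModel:
    """epsilon-insensitive RBF support-vector regression on z-scored inputs."""
    y = np.asarray(response, dtype=float)
    X = matrix.to_numpy(dtype=float)
    mu, sd = _standardizer(X)
    svr = SVR(kernel="rbf", C=config.C, epsilon=config.epsilon, gamma=config.gamma)
    svr.fit((X - mu) / sd, y)
    params = {
        "C": config.C,
        "epsilon": config.epsilon,
        "gamma": config.gamma,
        "n_support": int(svr.n_support_[0]) if svr.n_support_.size else 0,
        "standardize_mean": mu,
        "standardize_sd": sd,
        "dual_coef": svr.dual_coef_,
        "intercept": svr.intercept_,
    }
    return FittedModel(
        family="svr",
        columns=list(matrix.columns),
        parameters=params,
        n_train=len(y),
        _predict_fn=lambda A: svr.predict((A - mu) / sd),
    )


def tune_svr(
    matrix: pd.DataFrame,
    response: Sequence[float],
    grid: dict[str, Sequence[float]],
    folds: int = 10,
    seed: int = 0,
) -> SvrConfig:
    """Exhaustive grid search minimizing k-fold CV RMSE.

    ``grid`` maps any of ``C`` / ``epsilon`` / ``gamma`` to candidate
    values (missing keys keep the default).  Ties are broken toward
    smaller C, then larger epsilon.
    """
    default = SvrConfig(cv_folds=folds)
    Cs = list(grid.get("C", [default.C]))
    epss = list(grid.get("epsilon", [default.epsilon]))
    gammas = list(grid.get("gamma", [default.gamma]))
    if not (Cs and epss and gammas):
        raise ValueError("grid must be non-empty")
    y = np.asarray(response, dtype=float)
    X = matrix.to_numpy(dtype=float)
    kf = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best: tuple[float, float, float, SvrConfig] | None = None
    for C in Cs:
        for eps in epss:
            for gamma in gammas:
                press = 0.0
                for train, test in splits:
                    mu, sd = _standardizer(X[train])
                    svr = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
                    svr.fit((X[train] - mu) / sd, y[train])
                    pred = svr.predict((X[test] - mu) / sd)
                    press += ((pred - y[test]) ** 2).sum()
                rmse = np.sqrt(press / len(y))
                key = (round(rmse, 12), C, -eps)
                if best is None or key < (best[0], best[1], best[2]):
                    best = (key[0], C, -eps, SvrConfig(C, eps, gamma, folds))
    return best[3]


# --------------------------------------------------------------------------
# ANN: one hidden layer, Levenberg-Marquardt, early stopping


@dataclass(frozen=True)
class AnnConfig:
    """Feed-forward network settings.

    Three hidden units by default (tanh hidden layer, linear output).  The
    training rows are split at random into training / validation / test
    parts (70/15/15 by default); Levenberg-Marquardt minimizes the
    training sum of squares while the validation part drives early
    stopping, the usual guard against overfitting in small-sample QSAR
    networks.
    """

    hidden_units: int = 3
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    max_epochs: int = 1000
    patience: int = 6
    damping_init: float = 1e-3
    grad_tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def with_(self, **kwargs) -> "AnnConfig":
        return replace(self, **kwargs)


def _ann_forward(theta: np.ndarray, X: np.ndarray, h: int):
    p = X.shape[1]
    W1 = theta[: h * p].reshape(h, p)
    b1 = theta[h * p : h * p + h]
    w2 = theta[h * p + h : h * p + 2 * h]
    b2 = theta[-1]
    A = np.tanh(X @ W1.T + b1)
    return A @ w2 + b2, A, W1


def _ann_jacobian(theta: np.ndarray, X: np.ndarray, h: int) -> np.ndarray:
    n, p = X.shape
    yhat, A, W1 = _ann_forward(theta, X, h)
    w2 = theta[h * p + h : h * p + 2 * h]
    dA = 1.0 - A**2  # tanh'
    J = np.empty((n, theta.size))
    # d yhat / d W1[k, j] = w2_k * (1 - a_k^2) * x_j
    J[:, : h * p] = ((dA * w2)[:, :, None] * X[:, None, :]).reshape(n, h * p)
    J[:, h * p : h * p + h] = dA * w2
    J[:, h * p + h : h * p + 2 * h] = A
    J[:, -1] = 1.0
    return J


def fit_ann(
    matrix: pd.DataFrame,
    response: Sequence[float],
    config: AnnConfig = AnnConfig(),
) -> FittedModel:
    """Train a one-hidden-layer network by Levenberg-Marquardt.

    Inputs are z-scored and the response is centered/scaled on training
    statistics.  The damping factor starts at ``damping_init``, shrinks
    tenfold after an accepted step and grows tenfold after a rejected one;
    iteration stops at the gradient tolerance, the epoch cap, or after
    ``patience`` consecutive epochs without validation improvement (the
    best-validation weights are kept).  Deterministic given the seed.

    Raises :class:`TrainingError` if the loss becomes non-finite.
    """
    y = np.asarray(response, dtype=float)
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    h = config.hidden_units
    n_params = h * p + 2 * h + 1
    if n < 10 * n_params:
        warnings.warn(
            f"{n} rows for {n_params} network parameters; "
            "10x parameters recommended",
            stacklevel=2,
        )
    mu, sd = _standardizer(X)
    Z = (X - mu) / sd
    y_mu, y_sd = y.mean(), y.std() or 1.0
    t = (y - y_mu) / y_sd
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(n)
    n_tr = max(1, int(round(config.split[0] * n)))
    n_va = int(round(config.split[1] * n))
    tr, va = idx[:n_tr], idx[n_tr : n_tr + n_va]
    if len(va) == 0:
        va = tr  # degenerate split: validate on training part
    theta = rng.normal(0.0, 0.5, size=n_params)
    lam = config.damping_init
    best_theta, best_val = theta.copy(), np.inf
    stall = 0
    for _ in range(config.max_epochs):
        resid = _ann_forward(theta, Z[tr], h)[0] - t[tr]
        sse = float(resid @ resid)
        if not np.isfinite(sse):
            raise TrainingError("training loss became non-finite")
        J = _ann_jacobian(theta, Z[tr], h)
        g = J.T @ resid
        if np.linalg.norm(g) < config.grad_tol:
            break
        JTJ = J.T @ J
        accepted = False
        while lam < 1e12:
            try:
                step = np.linalg.solve(JTJ + lam * np.eye(n_params), -g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            cand = theta + step
            r2 = _ann_forward(cand, Z[tr], h)[0] - t[tr]
            if np.isfinite(r2 @ r2) and (r2 @ r2) < sse:
                theta = cand
                lam = max(lam / 10, 1e-12)
                accepted = True
                break
            lam *= 10
        if not accepted:
            break  # damping overflow: no further descent possible
        val_resid = _ann_forward(theta, Z[va], h)[0] - t[va]
        val_sse = float(val_resid @ val_resid)
        if val_sse < best_val - 1e-12:
            best_val = val_sse
            best_theta = theta.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    theta = best_theta

    def predict(A: np.ndarray) -> np.ndarray:
        Zp = (A - mu) / sd
        return _ann_forward(theta, Zp, h)[0] * y_sd + y_mu

    params = {
        "hidden_units": h,
        "weights": theta,
        "weight_layout": "W1 (h x p, row-major), b1 (h), w2 (h), b2 (1)",
        "standardize_mean": mu,
        "standardize_sd": sd,
        "response_mean": y_mu,
        "response_sd": y_sd,
    }
    return FittedModel(
        family="ann",
        columns=list(matrix.columns),
        parameters=params,
        n_train=n,
        seed=config.seed,
        _predict_fn=predict,
    )
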