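"""Error and validation statistics for bitterness models.

Percentage-deviation statistics::

    IPD_i  = 100 |y_pred,i - y_obs,i| / y_obs,i        (per point)
    MPD    = mean(IPD)  (reported with its SD)
    ILRSD  = (100 / N) sum |y_i - ybar| / ybar         (replicate series)

Fit quality: R^2 is the squared Pearson correlation between observed and
predicted (the convention under which the study's R and R^2 tables are
mutually consistent), RMSE the root mean squared deviation, with adjusted
R^2 and the F statistic from the standard OLS formulas.  Internal
validation: leave-one-out / leave-many-out q^2 = 1 - PRESS/SS_tot, and
Y-randomization (refit on shuffled activities).  External validation: the
Golbraikh-Tropsha criteria (R^2, through-origin R0^2 and R0'^2, slopes K
and K') and Roy's Rm^2 = R^2 (1 - sqrt(R^2 - R0^2)).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ErrorStats",
    "ExternalValidationResult",
    "CrossValResult",
    "ipd",
    "mpd",
    "ilrsd",
    "ipd_bins",
    "fit_quality",
    "q2_crossval",
    "y_randomization",
    "external_criteria",
    "ValidationReport",
]


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have the same length")
    return y, yhat


@dataclass
class ErrorStats:
    """Percentage-deviation summary of one (model, subset) pair."""

    mpd: float
    mpd_sd: float
    ipd: np.ndarray
    n: int


def ipd(observed, predicted) -> np.ndarray:
    """Individual percentage deviations, 100 |pred - obs| / obs.

    Points with zero observed value are undefined; they are dropped with a
    warning (the packaged activities are all >= 1).
    """
    y, yhat = _pair(observed, predicted)
    mask = y != 0
    if not mask.all():
        warnings.warn(
            f"{(~mask).sum()} point(s) with zero observed value excluded",
            stacklevel=2,
        )
    return 100.0 * np.abs((yhat[mask] - y[mask]) / y[mask])


def mpd(observed, predicted) -> ErrorStats:
    """Mean percentage deviation (with SD) of predictions from observations."""
    series = ipd(observed, predicted)
    if series.size == 0:
        raise ValueError("no valid points for MPD")
    return ErrorStats(
        mpd=float(series.mean()),
        mpd_sd=float(series.std(ddof=1)) if series.size > 1 else 0.0,
        ipd=series,
        n=int(series.size),
    )


def ilrsd(values: Sequence[float]) -> float:
    """Inter-laboratory relative standard deviation of a replicate series.

    (100/N) sum |y - ybar| / ybar; scale-invariant, 0 for identical
    replicates.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicate values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("replicate mean is zero")
    return float(100.0 / x.size * np.sum(np.abs(x - mean)) / mean)


def ipd_bins(series: Sequence[float]) -> tuple[float, float, float]:
    """Fractions of IPDs below 15%, between 15 and 30%, and above 30%.

    Boundary convention: [0, 15), [15, 30], (30, inf).  The three
    fractions sum to 1.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return (0.0, 0.0, 0.0)
    low = float((x < 15).mean())
    mid = float(((x >= 15) & (x <= 30)).mean())
    return (low, mid, 1.0 - low - mid)


def fit_quality(observed, predicted, p: int = 0) -> dict[str, float]:
    """R^2, adjusted R^2, RMSE, F and standard error for a prediction set.

    ``p`` is the number of predictors of the generating model (needed for
    the adjusted R^2, F and sep entries; they are NaN when n <= p + 1).
    """
    y, yhat = _pair(observed, predicted)
    n = y.size
    if n < 2 or y.std() == 0 or yhat.std() == 0:
        raise ValueError("fit quality needs >= 2 points with variance")
    r = float(np.corrcoef(y, yhat)[0, 1])
    r2 = r * r
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    out = {"r": r, "r2": r2, "rmse": rmse, "n": n}
    if p > 0 and n > p + 1:
        out["adj_r2"] = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        out["f"] = (r2 / p) / ((1.0 - r2) / (n - p - 1))
        sse = float(np.sum((y - yhat) ** 2))
        out["sep"] = float(np.sqrt(sse / (n - p - 1)))
    else:
        out["adj_r2"] = out["f"] = out["sep"] = float("nan")
    return out


@dataclass
class CrossValResult:
    """q^2 and held-out RMSE of a cross-validation scheme."""

    q2: float
    rmse: float
    fold_assignments: np.ndarray
    scheme: str


def q2_crossval(
    matrix: pd.DataFrame,
    response: Sequence[float],
    scheme: str = "lmo",
    model_factory: Callable | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> CrossValResult:
    """Leave-one-out or leave-many-out cross-validated q^2.

    ``model_factory(X_train, y_train)`` must return an object with a
    ``predict`` method (defaults to OLS).  q^2 = 1 - PRESS / SS_tot with
    SS_tot about the whole-set mean; LMO uses ``n_folds`` seeded folds.
    """
    from .models import fit_mlr

    y = np.asarray(response, dtype=float)
    n = len(y)
    factory = model_factory or fit_mlr
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "lmo":
        if not 2 <= n_folds <= n:
            raise ValueError("need n >= n_folds >= 2")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = [perm[f::n_folds] for f in range(n_folds)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    assignment = np.empty(n, dtype=int)
    pred = np.empty(n)
    for f, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        if np.std(y[train]) == 0:
            raise ValueError(f"fold {f} has zero training variance")
        model = factory(matrix.iloc[train], y[train])
        pred[test] = model.predict(matrix.iloc[test])
        assignment[test] = f
    press = float(np.sum((pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CrossValResult(
        q2=1.0 - press / ss_tot,
        rmse=float(np.sqrt(press / n)),
        fold_assignments=assignment,
        scheme=scheme,
    )


def y_randomization(
    matrix: pd.DataFrame,
    response: Sequence[float],
    n_shuffles: int = 10,
    model_factory: Callable | None = None,
    seed: int = 0,
) -> list[float]:
    """Fit R^2 after shuffling the activities, once per shuffle.

    Low values (the study reports 0.01-0.10 over 10 shuffles) rule out
    chance correlation of the selected descriptors with the response.
    """
    from .models import fit_mlr

    y = np.asarray(response, dtype=float)
    factory = model_factory or fit_mlr
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        y_shuffled = rng.permutation(y)
        model = factory(matrix, y_shuffled)
        pred = model.predict(matrix)
        out.append(float(np.corrcoef(y_shuffled, pred)[0, 1] ** 2))
    return out


@dataclass
class ExternalValidationResult:
    """Golbraikh-Tropsha external-validation suite plus Roy's Rm^2.

    ``k`` is the slope of the through-origin regression of observed on
    predicted, ``k_prime`` of predicted on observed; ``r0_sq`` the
    through-origin coefficient of determination of observed against
    k * predicted, ``r0_prime_sq`` the converse.  The pass flags encode
    the printed inequalities; ``slope_criterion`` uses the either/or
    structure so the K/K' labeling ambiguity cannot flip the verdict.
    """

    r2: float
    r0_sq: float
    r0_prime_sq: float
    k: float
    k_prime: float
    rm_sq: float
    passes: dict[str, bool] = field(default_factory=dict)

    def all_pass(self) -> bool:
        return all(self.passes.values())


def external_criteria(observed, predicted) -> ExternalValidationResult:
    """Compute the external-validation criteria on a held-out set.

    Criteria (test-set convention): R^2 > 0.6; (R^2 - R0^2)/R^2 < 0.1 with
    0.85 <= K <= 1.15, or the primed counterparts; |R0^2 - R0'^2| < 0.3;
    Rm^2 = R^2 (1 - sqrt(R^2 - R0^2)) > 0.5.
    """
    y, yhat = _pair(observed, predicted)
    if y.size < 3:
        raise ValueError("external validation needs at least 3 points")
    if y.std() == 0 or yhat.std() == 0:
        raise ValueError("degenerate variance in observed or predicted")
    r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    k = float(np.sum(y * yhat) / np.sum(yhat**2))
    k_prime = float(np.sum(y * yhat) / np.sum(y**2))
    ss_y = float(np.sum((y - y.mean()) ** 2))
    ss_yhat = float(np.sum((yhat - yhat.mean()) ** 2))
    r0_sq = 1.0 - float(np.sum((y - k * yhat) ** 2)) / ss_y
    r0_prime_sq = 1.0 - float(np.sum((yhat - k_prime * y) ** 2)) / ss_yhat
    rm_sq = r2 * (1.0 - np.sqrt(abs(r2 - r0_sq)))
    passes = {
        "r2_gt_0.6": r2 > 0.6,
        "slope_criterion": (
            ((r2 - r0_sq) / r2 < 0.1 and 0.85 <= k <= 1.15)
            or ((r2 - r0_prime_sq) / r2 < 0.1 and 0.85 <= k_prime <= 1.15)
        ),
        "r0_diff_lt_0.3": abs(r0_sq - r0_prime_sq) < 0.3,
        "rm_sq_gt_0.5": rm_sq > 0.5,
    }
    return ExternalValidationResult(
        r2=r2,
        r0_sq=r0_sq,
        r0_prime_sq=r0_prime_sq,
        k=k,
        k_prime=k_prime,
        rm_sq=float(rm_sq),
        passes=passes,
    )


@dataclass
class ValidationReport:
    """All statistics for one (model, subset) pair, serializable to JSON."""

    model: str
    partition: str
    error: ErrorStats
    quality: dict[str, float]
    bins: tuple[float, float, float]
    external: ExternalValidationResult | None = None

    @classmethod
    def compute(
        cls,
        model: str,
        partition: str,
        observed,
        predicted,
        p: int = 6,
        with_external: bool = False,
    ) -> "ValidationReport":
        err = mpd(observed, predicted)
        y, yhat = _pair(observed, predicted)
        try:
            quality = fit_quality(y, yhat, p)
        except ValueError:
            # subsets too small (or flat) for correlation statistics still
            # get their deviation statistics reported
            nan = float("nan")
            quality = {
                "r": nan,
                "r2": nan,
                "rmse": float(np.sqrt(np.mean((y - yhat) ** 2))) if y.size else nan,
                "n": int(y.size),
                "adj_r2": nan,
                "f": nan,
                "sep": nan,
            }
        return cls(
            model=model,
            partition=partition,
            error=err,
            quality=quality,
            bins=ipd_bins(err.ipd),
            external=external_criteria(y, yhat)
            if with_external and y.size >= 3 and y.std() > 0 and yhat.std() > 0
            else None,
        )

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "partition": self.partition,
            "n": self.error.n,
            "mpd": self.error.mpd,
            "mpd_sd": self.error.mpd_sd,
            "ipd_lt_15": self.bins[0],
            "ipd_15_30": self.bins[1],
            "ipd_gt_30": self.bins[2],
            **{k: v for k, v in self.quality.items() if k != "n"},
        }
        if self.external is not None:
            d.update(
                {
                    "r0_sq": self.external.r0_sq,
                    "r0_prime_sq": self.external.r0_prime_sq,
                    "k": self.external.k,
                    "k_prime": self.external.k_prime,
                    "rm_sq": self.external.rm_sq,
                    "external_pass": self.external.all_pass(),
                }
            )
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
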