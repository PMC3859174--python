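"""Synthetic data with the statistical structure the bitterness analysis assumes.

Three generators cover the three kinds of input the pipeline consumes:

* :func:`gen_joint` draws (response, descriptor) rows from a multivariate
  normal whose correlation matrix is the published intercorrelation table
  of the six final descriptors with log(1/T);
* :func:`gen_equation_response` evaluates the published six-descriptor
  linear bitterness equation on a descriptor matrix and adds Gaussian
  noise, for coefficient-recovery experiments;
* :func:`gen_wide_matrix` plants a handful of informative columns in a
  wide descriptor matrix (plus near-duplicate and near-constant columns),
  the ground-truthed harness for the selection cascade;
* :func:`gen_conformer` builds toy 3D conformers (line / ring / random
  chain) for descriptor property tests.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .descriptors3d import Conformer

#: Variable order of the joint generator: response first, then the six
#: descriptors of the final model.
VARIABLES = ("response", "SPAN", "Mor11v", "MSD", "HATS8u", "G3p", "E3s")

DESCRIPTOR_NAMES = VARIABLES[1:]

#: Published intercorrelation of log(1/T) with the six final descriptors
#: (lower triangle as printed; symmetrized here).
DEFAULT_CORR = np.array(
    [
        #  resp  SPAN  Mor11v  MSD  HATS8u  G3p   E3s
        [1.00, 0.79, 0.34, -0.81, -0.56, -0.63, 0.41],
        [0.79, 1.00, 0.09, -0.78, -0.52, -0.64, 0.22],
        [0.34, 0.09, 1.00, -0.20, -0.25, -0.13, 0.31],
        [-0.81, -0.78, -0.20, 1.00, 0.38, 0.64, -0.38],
        [-0.56, -0.52, -0.25, 0.38, 1.00, 0.30, -0.16],
        [-0.63, -0.64, -0.13, 0.64, 0.30, 1.00, -0.25],
        [0.41, 0.22, 0.31, -0.38, -0.16, -0.25, 1.00],
    ]
)

#: Marginal moments.  The response moments are those of the packaged
#: bitterness values; E3s, HATS8u and Mor11v use the published training-set
#: statistics.  SPAN, MSD and G3p were not published -- their defaults are
#: plausible placeholders chosen to keep equation outputs inside the
#: observed 1.0-5.7 activity range, and are config-exposed.
DEFAULT_MEANS = {
    "response": 2.87,
    "SPAN": 25.0,
    "Mor11v": 0.10,
    "MSD": 0.35,
    "HATS8u": 0.33,
    "G3p": 0.15,
    "E3s": 0.21,
}
DEFAULT_SDS = {
    "response": 1.00,
    "SPAN": 9.0,
    "Mor11v": 0.40,
    "MSD": 0.10,
    "HATS8u": 0.13,
    "G3p": 0.05,
    "E3s": 0.10,
}

#: Coefficients of the published six-descriptor bitterness equation
#: (intercept first), on the log(1/T) scale.
EQUATION_COEFFS = {
    "intercept": 5.45,
    "SPAN": 0.10,
    "Mor11v": 0.32,
    "MSD": -7.88,
    "HATS8u": -1.55,
    "G3p": -5.39,
    "E3s": 0.92,
}

#: Default response-noise scale: the training-set RMSE of the published
#: linear model.
DEFAULT_NOISE_SD = 0.43


class ConfigError(ValueError):
    """A synthetic-data configuration is internally inconsistent."""


def repair_correlation(corr: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Return the nearest-in-spirit positive semi-definite correlation matrix.

    Printed correlation tables are rounded to two decimals and can be
    slightly indefinite; negative eigenvalues are clipped at ``clip`` and
    the diagonal renormalized back to 1.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ConfigError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ConfigError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ConfigError("correlation matrix must have a unit diagonal")
    w, V = np.linalg.eigh(corr)
    if w.min() >= 0:
        return corr
    if w.min() < -0.05:
        raise ConfigError(
            f"correlation matrix is far from positive semi-definite "
            f"(min eigenvalue {w.min():.3f})"
        )
    w = np.clip(w, clip, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


@dataclass
class SyntheticConfig:
    """Configuration of the joint (response, descriptor) generator."""

    corr: np.ndarray = field(default_factory=lambda: DEFAULT_CORR.copy())
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    coeffs: dict[str, float] = field(default_factory=lambda: dict(EQUATION_COEFFS))
    noise_sd: float = DEFAULT_NOISE_SD
    n: int = 181
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        for name in VARIABLES:
            if name not in self.means or name not in self.sds:
                raise ConfigError(f"missing moments for variable {name!r}")
            if self.sds[name] <= 0:
                raise ConfigError(f"sd for {name!r} must be > 0")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def gen_joint(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw ``config.n`` multivariate-normal rows over (response, descriptors).

    Returns the descriptor matrix (columns in :data:`DESCRIPTOR_NAMES`
    order) and the response series.  Used for correlation-recovery tests:
    sample correlations converge to ``config.corr`` as n grows.
    """
    corr = repair_correlation(config.corr)
    sds = np.array([config.sds[v] for v in VARIABLES])
    means = np.array([config.means[v] for v in VARIABLES])
    cov = corr * np.outer(sds, sds)
    rng = np.random.default_rng(config.seed)
    draws = rng.multivariate_normal(means, cov, size=config.n, method="cholesky")
    frame = pd.DataFrame(draws, columns=VARIABLES)
    return frame[list(DESCRIPTOR_NAMES)], frame["response"].rename("response")


def gen_equation_response(
    descriptors: pd.DataFrame,
    coeffs: dict[str, float] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> pd.Series:
    """Evaluate the published linear equation on descriptors and add noise.

    ``descriptors`` must provide exactly the six named columns.  With
    ``noise_sd=0`` the output is the deterministic linear combination, so a
    refit recovers the coefficients to machine precision.
    """
    coeffs = dict(EQUATION_COEFFS) if coeffs is None else coeffs
    missing = [c for c in DESCRIPTOR_NAMES if c not in descriptors.columns]
    if missing:
        raise KeyError(f"descriptor matrix is missing column(s): {missing}")
    y = np.full(len(descriptors), float(coeffs["intercept"]))
    for name in DESCRIPTOR_NAMES:
        y = y + float(coeffs[name]) * descriptors[name].to_numpy(dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    return pd.Series(y, index=descriptors.index, name="response")


@dataclass
class RedundancySpec:
    """Extra columns planted for filter tests.

    ``n_duplicates`` near-copies of informative columns at correlation
    ``dup_noise_sd`` from exact, and ``n_near_constant`` columns whose most
    frequent value occupies ``constant_fraction`` of the rows.
    """

    n_duplicates: int = 0
    dup_noise_sd: float = 0.0
    n_near_constant: int = 0
    constant_fraction: float = 0.95


def gen_wide_matrix(
    n: int,
    p: int,
    n_informative: int,
    redundancy: RedundancySpec | None = None,
    seed: int = 0,
    beta: float = 0.35,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Wide descriptor matrix with planted informative columns.

    The first ``n_informative`` base columns drive the response with slope
    ``beta`` each (all columns are standard normal); the remainder are pure
    noise.  The default slope and noise scale put the signal-to-noise ratio
    of a six-variable model at the level of the real study (model R^2 near
    0.8 at the study's training size).  Redundant columns, if requested,
    are appended after the base block and recorded in the truth labels.

    Returns (matrix, response, truth) where ``truth`` maps
    ``informative`` / ``duplicates`` / ``near_constant`` to column names.
    """
    if n_informative > p:
        raise ValueError("n_informative must be <= p")
    redundancy = redundancy or RedundancySpec()
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    names = [f"x{j:04d}" for j in range(p)]
    informative = names[:n_informative]
    y = X[:, :n_informative].sum(axis=1) * beta
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    frame = pd.DataFrame(X, columns=names)
    truth = {"informative": informative, "duplicates": [], "near_constant": []}
    for d in range(redundancy.n_duplicates):
        src = informative[d % max(n_informative, 1)]
        col = frame[src].to_numpy().copy()
        if redundancy.dup_noise_sd > 0:
            col = col + rng.normal(0.0, redundancy.dup_noise_sd, size=n)
        name = f"dup{d:03d}_{src}"
        frame[name] = col
        truth["duplicates"].append(name)
    for c in range(redundancy.n_near_constant):
        col = np.zeros(n)
        n_distinct = max(1, int(round((1.0 - redundancy.constant_fraction) * n)))
        idx = rng.choice(n, size=n_distinct, replace=False)
        col[idx] = rng.standard_normal(n_distinct)
        name = f"const{c:03d}"
        frame[name] = col
        truth["near_constant"].append(name)
    return frame, pd.Series(y, name="response"), truth


def gen_conformer(
    n_atoms: int,
    geometry: Literal["line", "ring", "random"] = "line",
    seed: int = 0,
    spacing: float = 1.5,
    element: str = "C",
) -> Conformer:
    """Toy conformer with chain (or ring) connectivity, coordinates in A.

    ``line`` places atoms on the x axis ``spacing`` apart; ``ring`` on a
    regular polygon with edge length ``spacing``; ``random`` draws
    coordinates from a 3-D normal scaled by ``spacing`` with path
    connectivity.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    elements = [element] * n_atoms
    if geometry == "line":
        coords = np.zeros((n_atoms, 3))
        coords[:, 0] = np.arange(n_atoms) * spacing
        bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    elif geometry == "ring":
        if n_atoms < 3:
            raise ValueError("a ring needs at least 3 atoms")
        angles = 2 * np.pi * np.arange(n_atoms) / n_atoms
        radius = spacing / (2 * np.sin(np.pi / n_atoms))
        coords = np.column_stack(
            [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_atoms)]
        )
        bonds = [(i, (i + 1) % n_atoms) for i in range(n_atoms)]
    elif geometry == "random":
        rng = np.random.default_rng(seed)
        coords = rng.standard_normal((n_atoms, 3)) * spacing
        bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return Conformer(elements=elements, coords=coords, bonds=bonds)
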