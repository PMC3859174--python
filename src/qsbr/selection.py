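"""Three-stage descriptor-selection cascade.

Stage 1 (:func:`correlation_filter`) removes constant and near-constant
columns, and from every pair correlated above |r| = 0.99 the member less
correlated with the activity.  Stage 2 (:func:`iterative_gapls`) scores
variables with a genetic algorithm wrapped around PLS regression
(fitness = cross-validated explained variance), working through the
variable list in subgroups of up to 200: the top half of each scored
subgroup is merged with the next 100 variables until the list is
exhausted, and the top fifth of the final round survives.  Stage 3
(:func:`stepwise_select`) is classical forward-stepwise regression with
F-based enter/remove tests and a final pairwise-intercorrelation check
(|r| < 0.9) on the kept variables.

The GA-PLS stage is stochastic by nature; the iterative carry-half scheme
is precisely what stabilizes it across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterRules",
    "GaplsConfig",
    "SelectionResult",
    "correlation_filter",
    "gapls_score",
    "iterative_gapls",
    "stepwise_select",
    "simpls",
]


@dataclass(frozen=True)
class FilterRules:
    """Thresholds of the correlation/frequency filter."""

    intercorrelation_cutoff: float = 0.99
    repeat_fraction_min: float = 0.10  # min fraction of cases off the mode

    def __post_init__(self) -> None:
        for v in (self.intercorrelation_cutoff, self.repeat_fraction_min):
            if not 0 < v <= 1:
                raise ValueError("filter cutoffs must lie in (0, 1]")


@dataclass(frozen=True)
class GaplsConfig:
    """GA-PLS settings.

    The subgroup scheme (200-variable chunks, carry the top 50%, append
    100 new variables per round, keep 20% of the final round) mirrors the
    published selection protocol; the GA internals (population 30,
    single-point crossover at rate 0.5, per-bit mutation 0.01, 100
    chromosome evaluations per run, 5-fold CV fitness, up to 10 PLS
    components) follow the usual GA-PLS defaults.
    """

    subgroup_size: int = 200
    n_runs: int = 100
    carry_fraction: float = 0.50
    next_block: int = 100
    final_keep_fraction: float = 0.20
    population_size: int = 30
    crossover_rate: float = 0.5
    mutation_rate: float = 0.01
    n_evaluations: int = 100
    max_components: int = 10
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.carry_fraction, self.final_keep_fraction):
            if not 0 < v <= 1:
                raise ValueError("fractions must lie in (0, 1]")
        if self.subgroup_size < self.next_block:
            raise ValueError("subgroup_size must be >= next_block")

    def with_(self, **kwargs) -> "GaplsConfig":
        return replace(self, **kwargs)


@dataclass
class SelectionResult:
    """Outcome of a selection stage (or of the whole cascade)."""

    kept: list[str]
    scores: dict[str, float] = field(default_factory=dict)
    history: list[list[str]] = field(default_factory=list)
    stepwise_path: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kept": self.kept,
                    "scores": self.scores,
                    "history": self.history,
                    "stepwise_path": [list(e) for e in self.stepwise_path],
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(
            kept=d["kept"],
            scores=d["scores"],
            history=d["history"],
            stepwise_path=[tuple(e) for e in d["stepwise_path"]],
        )


# --------------------------------------------------------------------------
# stage 1: correlation / frequency filter


def correlation_filter(
    matrix: pd.DataFrame,
    response: Sequence[float],
    rules: FilterRules = FilterRules(),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop constant, near-constant and redundant correlated columns.

    Rules, applied in order: (a) constant columns; (b) columns whose most
    frequent value occupies more than ``1 - repeat_fraction_min`` of the
    rows; (c) from every pair with |r| above the intercorrelation cutoff,
    the member whose |correlation with the response| is lower (ties keep
    the earlier column).  Returns the reduced matrix and a drop log
    mapping column name -> rule that fired.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(matrix):
        raise ValueError("response length does not match the matrix")
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows")
    drop_log: dict[str, str] = {}
    keep = list(matrix.columns)
    for col in list(keep):
        x = matrix[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            drop_log[col] = "constant"
            keep.remove(col)
            continue
        _, counts = np.unique(x, return_counts=True)
        if counts.max() / len(x) > 1.0 - rules.repeat_fraction_min:
            drop_log[col] = "near-constant (repeated values)"
            keep.remove(col)
    X = matrix[keep].to_numpy(dtype=float)
    ry = np.abs(_columnwise_corr(X, y))
    C = np.corrcoef(X, rowvar=False)
    if C.ndim == 0:  # single surviving column
        C = np.array([[1.0]])
    dropped = np.zeros(len(keep), dtype=bool)
    for a in range(len(keep)):
        if dropped[a]:
            continue
        for b in range(a + 1, len(keep)):
            if dropped[b]:
                continue
            if abs(C[a, b]) > rules.intercorrelation_cutoff:
                loser = b if ry[b] <= ry[a] else a
                winner = a + b - loser
                dropped[loser] = True
                drop_log[keep[loser]] = (
                    f"intercorrelated with {keep[winner]} "
                    f"(|r|={abs(C[a, b]):.3f}), lower activity correlation"
                )
                if loser == a:
                    break
    survivors = [c for c, d in zip(keep, dropped) if not d]
    return matrix[survivors], drop_log


def _columnwise_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    denom[denom == 0] = np.inf
    return Xc.T @ yc / denom


# --------------------------------------------------------------------------
# stage 2: GA-PLS


def simpls(X: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """SIMPLS regression coefficients for 1..n_components components.

    Returns a (p, n_components) array whose k-th column are the
    coefficients of the centered model with k components, so all component
    counts are costed in a single pass -- the property that makes the CV
    fitness of the genetic algorithm cheap.  Matches the standard PLS1
    solution (cross-checked against scikit-learn in the test suite).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    p = X.shape[1]
    K = min(n_components, p, len(y) - 1)
    B = np.zeros((p, max(K, 1)))
    s = Xc.T @ yc
    V = np.zeros((p, K))
    Wq = np.zeros(p)
    for k in range(K):
        r = s - V[:, :k] @ (V[:, :k].T @ s)
        norm_r = np.linalg.norm(r)
        if norm_r < 1e-12:
            B[:, k:] = B[:, [k - 1]] if k else 0.0
            break
        w = r / norm_r
        t = Xc @ w
        tt = t @ t
        if tt < 1e-12:
            B[:, k:] = B[:, [k - 1]] if k else 0.0
            break
        pvec = Xc.T @ t / tt
        q = yc @ t / tt
        v = pvec - V[:, :k] @ (V[:, :k].T @ pvec)
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            B[:, k:] = B[:, [k - 1]] if k else 0.0
            break
        V[:, k] = v / nv
        Wq += w * q
        B[:, k] = Wq
    else:
        return B
    return B


def _cv_explained_variance(
    X: np.ndarray, y: np.ndarray, folds: list[np.ndarray], max_components: int
) -> float:
    """Best cross-validated explained variance (%) over component counts."""
    n = len(y)
    K = min(max_components, X.shape[1], n - 2)
    if K < 1:
        return -np.inf
    press = np.zeros(K)
    used = np.zeros(K, dtype=bool)
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        Xtr, ytr = X[train], y[train]
        B = simpls(Xtr, ytr, K)
        kk = B.shape[1]
        pred = (X[test_idx] - Xtr.mean(axis=0)) @ B[:, :kk] + ytr.mean()
        press[:kk] += ((pred - y[test_idx, None]) ** 2).sum(axis=0)
        used[:kk] = True
    ss_tot = ((y - y.mean()) ** 2).sum()
    q2 = 1.0 - press[used] / ss_tot
    return float(100.0 * q2.max())


def _make_folds(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [idx[f::n_folds] for f in range(n_folds)]


def gapls_score(
    matrix: pd.DataFrame,
    response: Sequence[float],
    config: GaplsConfig = GaplsConfig(),
) -> dict[str, float]:
    """Per-variable GA-PLS scores on one subgroup of variables.

    A steady-state genetic algorithm over binary inclusion chromosomes:
    fitness is the cross-validated percentage of explained variance of a
    PLS model on the included variables (component count picked by the
    same CV).  The score of a variable is its selection frequency over all
    evaluated chromosomes weighted by their (non-negative) fitness,
    averaged over ``config.n_runs`` independent runs.
    """
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("GA-PLS needs at least 2 variables")
    if p > config.subgroup_size:
        raise ValueError(
            f"{p} variables exceed subgroup_size={config.subgroup_size}; "
            "use iterative_gapls"
        )
    rng = np.random.default_rng(config.seed)
    totals = np.zeros(p)
    weight_sum = 0.0
    for _ in range(config.n_runs):
        folds = _make_folds(n, min(config.cv_folds, n), rng)

        def fitness(chrom: np.ndarray) -> float:
            if chrom.sum() < 1:
                return -np.inf
            return _cv_explained_variance(
                X[:, chrom], y, folds, config.max_components
            )

        # sparse initial population: ~5 variables on average per chromosome
        p_on = min(5.0 / p, 0.5)
        pop = rng.random((config.population_size, p)) < p_on
        for chrom in pop:
            if not chrom.any():
                chrom[rng.integers(p)] = True
        fits = np.array([fitness(c) for c in pop])

        def tournament() -> int:
            i, j = rng.choice(config.population_size, size=2, replace=False)
            return i if fits[i] >= fits[j] else j

        for _ in range(config.n_evaluations):
            i, j = tournament(), tournament()
            child = pop[i].copy()
            if rng.random() < config.crossover_rate:
                cut = rng.integers(1, p)
                child = np.concatenate([pop[i][:cut], pop[j][cut:]])
            flip = rng.random(p) < config.mutation_rate
            child = child ^ flip
            if not child.any():
                child[rng.integers(p)] = True
            f = fitness(child)
            worst = int(np.argmin(fits))
            if f > fits[worst]:
                pop[worst] = child
                fits[worst] = f
        # score from the final (elitist, steady-state) population: the
        # fitness-weighted selection frequency of each variable
        w = np.clip(np.where(np.isfinite(fits), fits, 0.0), 0.0, None)
        if w.sum() > 0:
            totals += (w[:, None] * pop).sum(axis=0)
            weight_sum += w.sum()
    scores = totals / weight_sum if weight_sum > 0 else np.zeros(p)
    return {c: float(s) for c, s in zip(matrix.columns, scores)}


def _top_fraction(scores: dict[str, float], fraction: float) -> list[str]:
    """Names of the top ``fraction`` of variables (stable ties: input order)."""
    names = list(scores)
    order = sorted(range(len(names)), key=lambda i: (-scores[names[i]], i))
    n_keep = max(1, math.ceil(fraction * len(names)))
    return [names[i] for i in sorted(order[:n_keep])]


def iterative_gapls(
    matrix: pd.DataFrame,
    response: Sequence[float],
    config: GaplsConfig = GaplsConfig(),
) -> SelectionResult:
    """Work through all variables in subgroups, carrying the best forward.

    The first subgroup holds up to ``subgroup_size`` variables; after
    scoring, the top ``carry_fraction`` are merged with the next
    ``next_block`` variables and rescored, until the variable list is
    exhausted; the top ``final_keep_fraction`` of the last round is
    returned.  With p <= subgroup_size this reduces to a single
    :func:`gapls_score` call.
    """
    columns = list(matrix.columns)
    history: list[list[str]] = []
    current = columns[: config.subgroup_size]
    remaining = columns[config.subgroup_size :]
    round_no = 0
    while True:
        sub_config = config.with_(seed=config.seed + round_no)
        if len(current) < 2:
            scores = {c: 1.0 for c in current}
        else:
            scores = gapls_score(matrix[current], response, sub_config)
        history.append(list(current))
        if not remaining:
            kept = _top_fraction(scores, config.final_keep_fraction)
            final_scores = {c: scores[c] for c in kept}
            return SelectionResult(kept=kept, scores=final_scores, history=history)
        carried = _top_fraction(scores, config.carry_fraction)
        current = carried + remaining[: config.next_block]
        remaining = remaining[config.next_block :]
        round_no += 1


# --------------------------------------------------------------------------
# stage 3: stepwise regression


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    return float(resid @ resid)


def stepwise_select(
    matrix: pd.DataFrame,
    response: Sequence[float],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    intercorrelation_max: float = 0.9,
) -> SelectionResult:
    """Forward-stepwise regression with removal and a collinearity check.

    At each step the candidate with the largest partial F enters if its
    p-value is below ``p_enter``; entered variables whose partial F
    p-value rises above ``p_remove`` are removed.  After the search, any
    kept pair correlated at |r| >= ``intercorrelation_max`` loses its
    later entrant (logged in ``stepwise_path``).  Default significance
    levels are the common statistical-package stepwise defaults.
    """
    y = np.asarray(response, dtype=float)
    names = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    n = len(y)
    kept: list[str] = []
    path: list[tuple[str, str]] = []

    def partial_f(current: list[str], candidate: str) -> tuple[float, float]:
        cur_idx = [names.index(c) for c in current]
        rss0 = _ols_rss(X[:, cur_idx], y)
        new_idx = cur_idx + [names.index(candidate)]
        rss1 = _ols_rss(X[:, new_idx], y)
        df2 = n - len(new_idx) - 1
        if df2 <= 0 or rss1 <= 0:
            return np.inf, 0.0
        F = (rss0 - rss1) / (rss1 / df2)
        return F, float(stats.f.sf(F, 1, df2))

    improved = True
    while improved:
        improved = False
        candidates = [c for c in names if c not in kept]
        if candidates and n > len(kept) + 2:
            results = [(c, *partial_f(kept, c)) for c in candidates]
            best = max(results, key=lambda t: t[1])
            if best[2] < p_enter:
                kept.append(best[0])
                path.append(("enter", best[0]))
                improved = True
        # removal pass: drop any kept variable that no longer earns its place
        removed = True
        while removed and len(kept) > 1:
            removed = False
            worst_name, worst_p = None, -1.0
            for c in kept:
                others = [k for k in kept if k != c]
                _, pval = partial_f(others, c)
                if pval > worst_p:
                    worst_name, worst_p = c, pval
            if worst_p > p_remove:
                kept.remove(worst_name)
                path.append(("remove", worst_name))
                removed = improved = True
    # final bivariate intercorrelation check: later entrant loses
    entry_order = [c for a, c in path if a == "enter" and c in kept]
    i = 0
    while i < len(kept):
        j = i + 1
        while j < len(kept):
            a, b = kept[i], kept[j]
            r = np.corrcoef(matrix[a], matrix[b])[0, 1]
            if abs(r) >= intercorrelation_max:
                later = b if entry_order.index(b) > entry_order.index(a) else a
                kept.remove(later)
                path.append(("remove-intercorrelated", later))
                if later == a:
                    j = i + 1
                    continue
            else:
                j += 1
        i += 1
    scores = {}
    for c in kept:
        _, pval = partial_f([k for k in kept if k != c], c)
        scores[c] = 1.0 - pval
    return SelectionResult(kept=kept, scores=scores, stepwise_path=path)


def run_cascade(
    matrix: pd.DataFrame,
    response: Sequence[float],
    filter_rules: FilterRules = FilterRules(),
    gapls_config: GaplsConfig = GaplsConfig(),
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> SelectionResult:
    """Filter -> iterative GA-PLS -> stepwise, returning the final result.

    The history records the filter survivors, each GA round, and the
    GA survivors handed to the stepwise stage.
    """
    filtered, _ = correlation_filter(matrix, response, filter_rules)
    ga = iterative_gapls(filtered, response, gapls_config)
    step = stepwise_select(filtered[ga.kept], response, p_enter, p_remove)
    step.history = [list(filtered.columns)] + ga.history + [list(ga.kept)]
    step.scores = {c: ga.scores.get(c, math.nan) for c in step.kept}
    return step
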