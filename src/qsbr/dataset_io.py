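"""Peptide bitterness dataset: loading, screening and partitioning.

The packaged dataset holds 227 peptides (1-14 residues, one-letter codes)
with observed bitterness log(1/T), a fixed training/test/validation
partition (181/36/10), and the per-peptide predictions of three previously
fitted models (MLR, SVM, ANN) together with their individual percentage
deviations (IPD).  The same CSV dialect is used for any user-supplied
descriptor/activity table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

PARTITIONS = ("training", "test", "validation")

#: Columns every dataset file must provide.
MANDATORY_COLUMNS = ("sequence", "partition", "observed")

#: Optional per-model prediction and error columns.
OPTIONAL_COLUMNS = (
    "pred_mlr",
    "ipd_mlr",
    "pred_svm",
    "ipd_svm",
    "pred_ann",
    "ipd_ann",
)


class DatasetFormatError(ValueError):
    """A dataset file violates the CSV contract (missing columns, bad rows)."""


class DegenerateInputError(ValueError):
    """An input has no variance (or too few points) for the requested statistic."""


@dataclass
class BitterRecord:
    """One peptide: sequence, observed bitterness and model predictions.

    ``observed`` and the ``pred_*`` fields are on the log(1/T) scale;
    ``ipd_*`` fields are percentages.  Missing predictions are NaN.
    """

    sequence: str
    partition: str
    observed: float
    pred_mlr: float = math.nan
    ipd_mlr: float = math.nan
    pred_svm: float = math.nan
    ipd_svm: float = math.nan
    pred_ann: float = math.nan
    ipd_ann: float = math.nan
    duplicate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.partition not in PARTITIONS:
            raise DatasetFormatError(
                f"partition must be one of {PARTITIONS}, got {self.partition!r}"
            )


@dataclass
class Partitioning:
    """A training/test/validation assignment produced by k-means splitting."""

    labels: list[str]
    n_clusters: int
    seed: int
    cluster_ids: list[int] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {p: self.labels.count(p) for p in PARTITIONS}


def _records_to_frame(records: Iterable[BitterRecord]) -> pd.DataFrame:
    cols = [f.name for f in fields(BitterRecord) if f.name != "duplicate"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def load_dataset(source: str | Path) -> list[BitterRecord]:
    """Read a bitterness CSV into records.

    Duplicate (sequence, partition, observed) triples are legal -- the
    packaged table contains repeated sequences with distinct activities --
    and are flagged via :attr:`BitterRecord.duplicate` with a warning
    rather than rejected.

    Raises
    ------
    DatasetFormatError
        If a mandatory column is missing or an ``observed`` value is not
        numeric (the error names the offending row).
    """
    df = pd.read_csv(source, dtype={"sequence": str, "partition": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing mandatory column(s): {missing}")
    records: list[BitterRecord] = []
    for idx, row in df.iterrows():
        try:
            observed = float(row["observed"])
        except (TypeError, ValueError) as exc:
            raise DatasetFormatError(
                f"row {idx}: non-numeric observed value {row['observed']!r}"
            ) from exc
        kwargs = {
            c: float(row[c]) if c in df.columns and pd.notna(row[c]) else math.nan
            for c in OPTIONAL_COLUMNS
        }
        records.append(
            BitterRecord(
                sequence=str(row["sequence"]),
                partition=str(row["partition"]),
                observed=observed,
                **kwargs,
            )
        )
    seen: set[tuple[str, str, float]] = set()
    n_dup = 0
    for rec in records:
        key = (rec.sequence, rec.partition, rec.observed)
        if key in seen:
            rec.duplicate = True
            n_dup += 1
        seen.add(key)
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicate (sequence, partition, observed) triple(s) flagged",
            stacklevel=2,
        )
    return records


def load_packaged_dataset() -> list[BitterRecord]:
    """Load the 227-peptide bitterness table shipped with the package."""
    ref = resources.files("qsbr.data").joinpath("bitter_peptides.csv")
    with resources.as_file(ref) as path:
        return load_dataset(path)


def packaged_frame() -> pd.DataFrame:
    """The packaged dataset as a DataFrame (one row per peptide)."""
    return _records_to_frame(load_packaged_dataset())


def write_dataset(records: Sequence[BitterRecord], dest: str | Path) -> None:
    """Write records in the standard CSV dialect; NaN becomes an empty field."""
    _records_to_frame(records).to_csv(dest, index=False)


def screen_outliers(responses: Sequence[float], threshold: float = 3.0) -> list[int]:
    """Indices whose standard score |z| meets or exceeds ``threshold``.

    z is computed against the series mean and population standard
    deviation.  The default cutoff of 3 is the usual convention for
    response-space outlier screening.

    Raises
    ------
    DegenerateInputError
        If fewer than 3 values are given or the series has zero variance.
    """
    x = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise DegenerateInputError("need at least 3 values to screen outliers")
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("zero-variance series has no standard scores")
    z = (x - x.mean()) / sd
    return [int(i) for i in np.flatnonzero(np.abs(z) >= threshold)]


def pca_scores(matrix: pd.DataFrame | np.ndarray, n_components: int) -> np.ndarray:
    """Scores of the first principal axes of the standardized columns.

    Used for outlier inspection in descriptor space (the score map).  The
    sign of each axis is fixed by making its largest-magnitude loading
    positive, so scores are reproducible across linear-algebra backends.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    n, p = X.shape
    if not 1 <= n_components <= p:
        raise ValueError(f"n_components must be in 1..{p}")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    if n_components > np.linalg.matrix_rank(Z):
        raise ValueError("n_components exceeds the rank of the standardized matrix")
    # SVD of the centered matrix: scores are U*S on the leading axes.
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return U[:, :n_components] * S[:n_components]


def _allocate_counts(size: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``size`` items over fractions."""
    raw = [size * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    short = size - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i]), reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def kmeans_partition(
    features: pd.DataFrame | np.ndarray,
    n_clusters: int = 10,
    fractions: Sequence[float] = (0.79, 0.16, 0.05),
    seed: int = 0,
) -> Partitioning:
    """Split molecules into training/test/validation via k-means clustering.

    Features (typically descriptors plus the activity) are standardized to
    zero mean and unit variance, clustered with k-means++ seeding, and each
    cluster's members are allocated to the three subsets in the requested
    proportions (largest-remainder rounding, members drawn in a seeded
    random order within the cluster), so every subset reflects the
    structural diversity of the whole set.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in 1..{n}")
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three proportions summing to 1")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    cluster_ids = km.fit_predict(Z)
    rng = np.random.default_rng(seed)
    labels = [""] * n
    for c in range(n_clusters):
        members = np.flatnonzero(cluster_ids == c)
        members = members[rng.permutation(len(members))]
        counts = _allocate_counts(len(members), fractions)
        pos = 0
        for part, cnt in zip(PARTITIONS, counts):
            for i in members[pos : pos + cnt]:
                labels[int(i)] = part
            pos += cnt
    # guarantee non-empty subsets: steal from the largest partition if needed
    for part in PARTITIONS:
        if part not in labels:
            biggest = max(PARTITIONS, key=labels.count)
            labels[labels.index(biggest)] = part
    return Partitioning(
        labels=labels,
        n_clusters=n_clusters,
        seed=seed,
        cluster_ids=[int(c) for c in cluster_ids],
    )
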