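"""Data washing: normalization, local 3-sigma (Pauta) outlier removal,
correlation-based descriptor pruning, and an optional PCA reduction.

The outlier rule rests on the QSAR premise that structurally similar
compounds have similar activity: a compound whose activity deviates from the
mean of its descriptor-space neighbourhood by more than ``sigma`` local
standard deviations is an outlier — but only when the neighbourhood is large
enough (strictly more than ``min_neighbors`` members) for the statistic to
be meaningful. Statistics are local by default; a dataset-global mode is
available behind a flag.

Descriptor pruning runs a greedy double loop over the Pearson correlation
matrix: earlier columns always win, and a later column is deleted as soon as
its absolute correlation with a retained earlier column exceeds the
threshold. The surviving table has no pair above the threshold, and the
operation is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_io import logger
from .errors import ValidationError
from .table import DescriptorTable


# ---------------------------------------------------------------- containers
@dataclass
class NormalizationParams:
    """Per-descriptor location/scale, reusable on prediction inputs."""

    mode: str                       # "zscore" or "minmax"
    columns: list[str]              # retained descriptor names, in order
    location: np.ndarray            # mean (zscore) or min (minmax)
    scale: np.ndarray               # sd (zscore) or range (minmax)
    constant_columns: list[str] = field(default_factory=list)

    def transform(self, table: DescriptorTable) -> DescriptorTable:
        sub = table.select_descriptors(self.columns)
        Z = (sub.X - self.location) / self.scale
        return DescriptorTable(
            pd.DataFrame(Z, index=sub.descriptors.index, columns=self.columns),
            sub.activity, sub.activity_name,
        )

    def inverse_transform(self, table: DescriptorTable) -> DescriptorTable:
        sub = table.select_descriptors(self.columns)
        Z = sub.X * self.scale + self.location
        return DescriptorTable(
            pd.DataFrame(Z, index=sub.descriptors.index, columns=self.columns),
            sub.activity, sub.activity_name,
        )


@dataclass
class OutlierRecord:
    compound_id: str
    neighbor_count: int
    local_mean: float
    local_sd: float
    deviation: float


@dataclass
class PruneRecord:
    removed: str
    retained: str      # the earlier column that triggered the removal
    correlation: float


@dataclass
class WashReport:
    """Audit trail of a washing run: what was removed and why."""

    removed_outliers: list[OutlierRecord] = field(default_factory=list)
    removed_descriptors: list[PruneRecord] = field(default_factory=list)
    normalization: NormalizationParams | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.removed_outliers:
            rows.append({
                "kind": "outlier", "name": o.compound_id,
                "neighbor_count": o.neighbor_count, "local_mean": o.local_mean,
                "local_sd": o.local_sd, "deviation": o.deviation,
                "retained_partner": "", "correlation": np.nan,
            })
        for p in self.removed_descriptors:
            rows.append({
                "kind": "descriptor", "name": p.removed,
                "neighbor_count": np.nan, "local_mean": np.nan,
                "local_sd": np.nan, "deviation": np.nan,
                "retained_partner": p.retained, "correlation": p.correlation,
            })
        return pd.DataFrame(rows)


@dataclass
class PCAResult:
    column_means: np.ndarray        # per-descriptor means removed in step 1
    eigenvalues: np.ndarray         # all eigenvalues, descending
    components: np.ndarray          # feature matrix, n x p, orthonormal columns
    reduced: np.ndarray             # projected data, m x p
    p: int


# -------------------------------------------------------------- normalization
def normalize(
    table: DescriptorTable, mode: str = "zscore"
) -> tuple[DescriptorTable, NormalizationParams]:
    """Column-wise normalization so no descriptor dominates by raw scale.

    ``zscore`` maps each column to mean 0, sd 1 (population sd); ``minmax``
    maps to [0, 1]. Constant columns carry no information and are dropped
    (reported via ``constant_columns``).
    """
    if mode not in ("zscore", "minmax"):
        raise ValidationError(f"unknown normalization mode {mode!r}")
    X = table.X
    if mode == "zscore":
        loc_all, scale_all = X.mean(axis=0), X.std(axis=0)
    else:
        loc_all = X.min(axis=0)
        scale_all = X.max(axis=0) - loc_all
    keep = scale_all > 0
    if not keep.any():
        raise ValidationError("all descriptor columns are constant")
    names = np.asarray(table.descriptor_names)
    constant = [str(c) for c in names[~keep]]
    if constant:
        logger.info("normalize: dropping constant columns %s", constant)
    params = NormalizationParams(
        mode=mode,
        columns=[str(c) for c in names[keep]],
        location=loc_all[keep],
        scale=scale_all[keep],
        constant_columns=constant,
    )
    return params.transform(table), params


# ------------------------------------------------------------------- outliers
def _neighborhoods(X: np.ndarray, radius_quantile: float) -> tuple[np.ndarray, float]:
    dists = pdist(X)
    r = float(np.quantile(dists, radius_quantile)) if dists.size else 0.0
    D = squareform(dists)
    np.fill_diagonal(D, np.inf)     # a compound is not its own neighbour
    return D <= r, r


def detect_outliers(
    table: DescriptorTable,
    sigma: float = 3.0,
    min_neighbors: int = 10,
    radius_quantile: float = 0.10,
    mode: str = "local",
) -> tuple[DescriptorTable, WashReport]:
    """Flag and remove activity outliers by the 3-sigma rule.

    A compound is flagged iff its neighbourhood (compounds within the
    ``radius_quantile`` quantile of all pairwise Euclidean distances) has
    strictly more than ``min_neighbors`` members AND its activity deviates
    from the neighbourhood mean by more than ``sigma`` neighbourhood standard
    deviations. Detection uses the original table throughout; removals do
    not cascade. A zero local sd with a nonzero deviation still flags.
    """
    if table.m < min_neighbors + 2:
        raise ValidationError(
            f"need at least min_neighbors + 2 = {min_neighbors + 2} compounds, "
            f"got {table.m}"
        )
    y = table.y
    ids = table.compound_ids
    report = WashReport()
    if mode == "global":
        mu, sd = float(y.mean()), float(y.std())
        for i, cid in enumerate(ids):
            dev = y[i] - mu
            if abs(dev) > sigma * sd and dev != 0:
                report.removed_outliers.append(
                    OutlierRecord(cid, table.m - 1, mu, sd, float(dev))
                )
    elif mode == "local":
        nbr, r = _neighborhoods(table.X, radius_quantile)
        logger.info("detect_outliers: neighbourhood radius %.4g", r)
        for i, cid in enumerate(ids):
            mask = nbr[i]
            count = int(mask.sum())
            if count <= min_neighbors:
                continue
            mu = float(y[mask].mean())
            sd = float(y[mask].std())
            dev = float(y[i] - mu)
            flagged = abs(dev) > sigma * sd if sd > 0 else dev != 0
            if flagged:
                report.removed_outliers.append(
                    OutlierRecord(cid, count, mu, sd, dev)
                )
    else:
        raise ValidationError(f"unknown outlier mode {mode!r}")
    removed = [o.compound_id for o in report.removed_outliers]
    if removed:
        logger.info("detect_outliers: removed %d outliers: %s", len(removed), removed)
    return table.drop_compounds(removed), report


# -------------------------------------------------------------------- pruning
def prune_correlated(
    table: DescriptorTable, threshold: float = 0.95
) -> tuple[DescriptorTable, WashReport]:
    """Greedy removal of redundant descriptors by pairwise Pearson correlation.

    For i = 1..n, for j = i+1..n (skipping already-deleted columns): delete
    column j when ``|corr(b_i, b_j)| > threshold``. Earlier columns always
    win. Every remaining pair of the returned table satisfies
    ``|corr| <= threshold``.
    """
    if not (0 < threshold <= 1):
        raise ValidationError("correlation threshold must be in (0, 1]")
    if table.n < 2:
        raise ValidationError("need at least 2 descriptor columns")
    X = table.X
    if (X.std(axis=0) == 0).any():
        bad = [c for c, s in zip(table.descriptor_names, X.std(axis=0)) if s == 0]
        raise ValidationError(f"constant columns (normalize first): {bad}")
    corr = np.corrcoef(X, rowvar=False)
    names = table.descriptor_names
    n = table.n
    deleted = np.zeros(n, dtype=bool)
    report = WashReport()
    for i in range(n):
        if deleted[i]:
            continue
        for j in range(i + 1, n):
            if deleted[j]:
                continue
            if abs(corr[i, j]) > threshold:
                deleted[j] = True
                report.removed_descriptors.append(
                    PruneRecord(names[j], names[i], float(corr[i, j]))
                )
    kept = [names[i] for i in range(n) if not deleted[i]]
    if report.removed_descriptors:
        logger.info(
            "prune_correlated: removed %d of %d descriptors at threshold %g",
            n - len(kept), n, threshold,
        )
    return table.select_descriptors(kept), report


# ------------------------------------------------------------------------ PCA
def pca_reduce(table: DescriptorTable, p: int) -> PCAResult:
    """Principal-component reduction of the descriptor matrix.

    Center columns, form the covariance matrix, eigendecompose, order the
    eigenpairs by decreasing eigenvalue, and project onto the leading ``p``
    eigenvectors.
    """
    X = table.X
    m, n = X.shape
    if not (1 <= p <= min(m, n)):
        raise ValidationError(f"p must be in [1, {min(m, n)}], got {p}")
    means = X.mean(axis=0)
    Xc = X - means
    cov = (Xc.T @ Xc) / (m - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    components = evecs[:, :p]
    return PCAResult(
        column_means=means,
        eigenvalues=evals,
        components=components,
        reduced=Xc @ components,
        p=p,
    )


# ----------------------------------------------------------------- similarity
def euclidean_nearest(
    table: DescriptorTable, query_id: str
) -> tuple[str, float]:
    """Most similar other compound by Euclidean distance in descriptor space.

    A small distance to the training set means the query sits in well-sampled
    chemical space and its prediction is more trustworthy (applicability
    diagnostic).
    """
    ids = table.compound_ids
    if query_id not in ids:
        raise ValidationError(f"unknown compound {query_id!r}")
    X = table.X
    qi = ids.index(query_id)
    d = np.linalg.norm(X - X[qi], axis=1)
    d[qi] = np.inf
    j = int(np.argmin(d))
    return ids[j], float(d[j])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on on-bits; 0 (with a warning)
    when both fingerprints are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0")
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_nearest(
    fingerprints: pd.DataFrame, query_id: str
) -> tuple[str, float]:
    """Most similar other compound by Tanimoto coefficient on binary bits."""
    if query_id not in fingerprints.index:
        raise ValidationError(f"unknown compound {query_id!r}")
    vals = fingerprints.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError("fingerprint cells must be 0 or 1")
    q = vals[fingerprints.index.get_loc(query_id)]
    best_id, best_tc = "", -1.0
    for cid, row in zip(fingerprints.index, vals):
        if cid == query_id:
            continue
        tc = tanimoto(q, row)
        if tc > best_tc:
            best_id, best_tc = str(cid), tc
    return best_id, best_tc
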