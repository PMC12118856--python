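"""Protein-level quantification and multivariate protocol comparison.

The quantification chain is iBAQ -> log2 -> left-censored imputation
(QRILC) -> per-column z-scores:

* iBAQ divides a protein's summed precursor intensity by its number of
  theoretical tryptic peptides, giving an abundance estimate comparable
  across proteins of different length.
* QRILC treats missing values as missing-not-at-random low-abundance
  observations: each column's underlying normal is estimated by regressing
  the observed order statistics on their normal quantiles (offset by the
  censored fraction), and imputations are drawn from that normal truncated
  above at a low quantile (default 0.01).
* z-scoring standardises each protocol column to mean 0, SD 1 so that
  profile shapes, not acquisition depth, drive the comparison.

On top of the matrix sit Pearson correlation, agglomerative clustering,
classical (metric) multidimensional scaling, and exclusive set
intersections for upset-style presence/absence comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, truncnorm

from .proteome_core import ProteinRecord, count_theoretical_peptides

logger = logging.getLogger(__name__)

STAGES = ("raw", "log2", "imputed", "z")

_METRIC_NAMES = {"manhattan": "cityblock", "euclidean": "euclidean"}


@dataclass
class ProteinQuantMatrix:
    """Proteins x protocols quantification matrix with a processing-stage
    tag and the original missingness mask. Stage transitions only move
    forward along ``raw -> log2 -> imputed -> z``."""

    data: pd.DataFrame
    stage: str = "raw"
    missing_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.missing_mask is None:
            self.missing_mask = self.data.isna()

    def advance(self, data: pd.DataFrame, stage: str) -> "ProteinQuantMatrix":
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise ValueError(
                f"stage may only move forward ({self.stage} -> {stage})"
            )
        return ProteinQuantMatrix(data, stage, self.missing_mask)


def compute_ibaq(
    rows: pd.DataFrame,
    database: Mapping[str, ProteinRecord],
    bounds: tuple[int, int] = (7, 30),
    proline_rule: bool = True,
) -> ProteinQuantMatrix:
    """iBAQ matrix from filtered precursor rows: per (protein leader, run),
    summed intensity divided by the count of theoretical tryptic peptides.
    Cells without any observed precursor are missing, not zero."""
    leaders = sorted(rows["leader"].unique())
    absent = [acc for acc in leaders if acc not in database]
    if absent:
        raise KeyError(f"protein-group leader(s) missing from FASTA: {absent}")
    divisors = {}
    for acc in leaders:
        n = count_theoretical_peptides(
            database[acc], bounds[0], bounds[1], proline_rule
        )
        if n == 0:
            logger.warning(
                "%s has no theoretical peptide in bounds %s; iBAQ undefined",
                acc,
                bounds,
            )
            n = np.nan
        divisors[acc] = n
    sums = (
        rows.dropna(subset=["intensity"])
        .groupby(["leader", "run"])["intensity"]
        .sum()
        .unstack("run")
    )
    sums = sums.reindex(index=leaders, columns=sorted(rows["run"].unique()))
    ibaq = sums.div(pd.Series(divisors), axis=0)
    return ProteinQuantMatrix(ibaq, "raw")


def log2_transform(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    if matrix.stage != "raw":
        raise ValueError("log2_transform expects a raw-stage matrix")
    return matrix.advance(np.log2(matrix.data), "log2")


def _qq_fit(observed: np.ndarray, n_total: int) -> tuple[float, float]:
    """Estimate (mean, sd) of the censored column's normal by regressing
    the sorted observed values on normal quantiles whose plotting positions
    start at the censored fraction."""
    obs = np.sort(observed)
    f_miss = 1.0 - len(obs) / n_total
    p = f_miss + (1.0 - f_miss) * (np.arange(1, len(obs) + 1) - 0.5) / len(obs)
    z = norm.ppf(p)
    # Upper half of the Q-Q pairs is least distorted by censoring artefacts.
    half = len(obs) // 2
    sd, mu = np.polyfit(z[half:], obs[half:], 1)
    return float(mu), float(max(sd, 1e-9))


def impute_qrilc(
    matrix: ProteinQuantMatrix,
    quantile: float = 0.01,
    seed: int | None = None,
) -> ProteinQuantMatrix:
    """Quantile-regression imputation of left-censored data.

    Per column, imputations are drawn from the estimated normal truncated
    above at its ``quantile`` quantile, so imputed values sit in the low
    tail below the observed values (in expectation). Deterministic under
    ``seed``. Columns with fewer than 3 observations fall back to a global
    estimate pooled over all columns (with a warning).
    """
    if matrix.stage != "log2":
        raise ValueError("impute_qrilc expects a log2-stage matrix")
    if not 0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    n_total = len(data)
    pooled = data.to_numpy().ravel()
    pooled = pooled[~np.isnan(pooled)]
    z_cut = norm.ppf(quantile)
    for col in data.columns:
        col_vals = data[col].to_numpy(float)
        miss = np.isnan(col_vals)
        if not miss.any():
            continue
        observed = col_vals[~miss]
        if len(observed) < 3:
            logger.warning(
                "column %s has %d observed values; using global estimate",
                col,
                len(observed),
            )
            mu, sd = _qq_fit(pooled, pooled.size + int(miss.sum()))
        else:
            mu, sd = _qq_fit(observed, n_total)
        draws = truncnorm.rvs(
            -np.inf,
            z_cut,
            loc=mu,
            scale=sd,
            size=int(miss.sum()),
            random_state=rng,
        )
        col_vals[miss] = draws
        data[col] = col_vals
    return matrix.advance(data, "imputed")


def zscore_columns(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Standardise each protocol column to mean 0, SD 1 (sample SD, n-1)."""
    if matrix.data.isna().any().any():
        raise ValueError("z-scoring requires a complete (imputed) matrix")
    sd = matrix.data.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError(
            f"zero-variance column(s): {list(sd.index[sd == 0])}"
        )
    z = (matrix.data - matrix.data.mean(axis=0)) / sd
    if matrix.stage == "z":
        raise ValueError("matrix already z-scored")
    return ProteinQuantMatrix(z, "z", matrix.missing_mask)


def correlation_matrix(matrix: ProteinQuantMatrix | pd.DataFrame) -> pd.DataFrame:
    """Protocol x protocol Pearson correlation matrix."""
    data = matrix.data if isinstance(matrix, ProteinQuantMatrix) else matrix
    if data.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ClusterResult:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix (merges + heights)
    leaf_order: list[str]


def hierarchical_cluster(
    matrix: ProteinQuantMatrix | pd.DataFrame,
    axis: str = "columns",
    metric: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of rows or columns. Items enter in sorted
    label order so leaf ordering is deterministic under ties."""
    if metric not in _METRIC_NAMES:
        raise ValueError(f"metric must be one of {sorted(_METRIC_NAMES)}")
    if linkage not in {"complete", "average", "single"}:
        raise ValueError("linkage must be complete, average or single")
    data = matrix.data if isinstance(matrix, ProteinQuantMatrix) else matrix
    if axis == "columns":
        data = data.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    data = data.sort_index()
    labels = [str(i) for i in data.index]
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    d = pdist(data.to_numpy(float), metric=_METRIC_NAMES[metric])
    Z = scipy_linkage(d, method=linkage)
    order = [labels[i] for i in leaves_list(Z)]
    return ClusterResult(labels, Z, order)


def metric_mds(
    matrix: ProteinQuantMatrix | pd.DataFrame,
    metric: str = "manhattan",
    dims: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Classical (Torgerson) metric MDS of the protocol columns.

    Returns (coordinates, stress) where stress is Kruskal's stress-1
    between input and embedded distances. The sign of each axis is fixed
    so the first point's coordinate is non-negative.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    data = matrix.data if isinstance(matrix, ProteinQuantMatrix) else matrix
    points = data.T.sort_index()
    labels = list(points.index)
    D = squareform(pdist(points.to_numpy(float), metric=_METRIC_NAMES[metric]))
    n = len(labels)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(dims, n)
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    if coords.shape[1] < dims:
        coords = np.hstack(
            [coords, np.zeros((n, dims - coords.shape[1]))]
        )
    for j in range(coords.shape[1]):
        ref = next((c for c in coords[:, j] if abs(c) > 1e-12), 0.0)
        if ref < 0:
            coords[:, j] = -coords[:, j]
    emb = squareform(pdist(coords))
    denom = (D**2).sum()
    stress = float(np.sqrt(((emb - D) ** 2).sum() / denom)) if denom > 0 else 0.0
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"dim{j + 1}" for j in range(dims)]
    )
    return frame, stress


def intersection_counts(
    protein_sets: Mapping[str, set]
) -> pd.DataFrame:
    """Exclusive intersection counts over every nonempty protocol
    combination (upset-plot table). Counts partition the union."""
    names = sorted(protein_sets)
    membership: dict[frozenset, int] = {}
    union = set().union(*protein_sets.values()) if protein_sets else set()
    for item in union:
        combo = frozenset(n for n in names if item in protein_sets[n])
        membership[combo] = membership.get(combo, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            key = frozenset(combo)
            rows.append(
                {
                    "protocols": ";".join(combo),
                    "degree": r,
                    "count": membership.get(key, 0),
                }
            )
    frame = pd.DataFrame(rows, columns=["protocols", "degree", "count"])
    assert frame["count"].sum() == len(union)
    return frame


def presence_sets(rows: pd.DataFrame) -> dict[str, set]:
    """Protein leader sets per run label, for intersection analysis."""
    return {
        run: set(sub["leader"].unique())
        for run, sub in rows.groupby("run")
    }
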