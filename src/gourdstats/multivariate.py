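"""Correlation-matrix PCA, UPGMA clustering and Newick export.

PCA is the eigendecomposition of the trait correlation matrix: eigenvalues
sum to the number of variables, per-component variability is lambda/p x 100,
components with eigenvalue >= 1 are retained (Kaiser), and loadings with
|value| > 0.6 are treated as significant.  Clustering is classic UPGMA on
Euclidean distances between standardized landrace profiles, with merge
heights at half the cluster distance (ultrametric convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import DesignError, GourdstatsError, InsufficientDataError

__all__ = [
    "PCAResult",
    "ClusterTree",
    "zscore_standardize",
    "mean_impute",
    "pca_correlation",
    "kaiser_retain",
    "significant_loadings",
    "biplot_coords",
    "euclidean_dissimilarity",
    "upgma",
    "cut_clusters",
    "tree_to_newick",
]


def zscore_standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0 and sample SD 1 (ddof=1).

    A constant column has no scale and raises an error naming the trait.
    """
    X = pd.DataFrame(X)
    sd = X.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        raise GourdstatsError(
            f"constant column(s) cannot be standardized: {constant}"
        )
    return (X - X.mean()) / sd


def mean_impute(X: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the column (across-landrace) mean.

    Used before PCA/clustering so that a landrace missing one trait group
    (e.g. no harvestable shoots) still appears in the ordination; a warning
    reports how many entries were imputed.
    """
    X = pd.DataFrame(X)
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        warnings.warn(
            f"imputing {n_missing} missing landrace-trait summaries with "
            "trait means before ordination",
            stacklevel=2,
        )
        X = X.fillna(X.mean())
    return X


@dataclass(frozen=True)
class PCAResult:
    """Eigendecomposition of a trait correlation matrix.

    Loadings are scaled so each component's squared loadings sum to its
    eigenvalue (i.e. loading = eigenvector x sqrt(lambda)); with all
    components kept, ``L @ L.T`` reproduces the correlation matrix.
    """

    eigenvalues: np.ndarray  # descending
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # observations x components
    variability: np.ndarray  # percent per component
    cumulative: np.ndarray  # percent, non-decreasing
    retained: tuple[int, ...]  # 0-based indices with eigenvalue >= 1


def pca_correlation(X: pd.DataFrame) -> PCAResult:
    """PCA of the correlation matrix of ``X`` (observations x variables).

    The input is internally z-standardized; components are ordered by
    decreasing eigenvalue and each eigenvector's sign is fixed by making
    its largest-magnitude element positive, so results are deterministic.
    Rank-deficient inputs are allowed (zero eigenvalues retained as zeros).
    """
    X = pd.DataFrame(X)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientDataError("PCA needs at least 2 rows and 2 columns")
    if X.isna().any().any():
        raise InsufficientDataError(
            "missing entries: impute first (see mean_impute)"
        )
    Z = zscore_standardize(X)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude element of each eigenvector positive
    for j in range(eigvec.shape[1]):
        i_max = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i_max, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    p = X.shape[1]
    comp_names = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(
        eigvec * np.sqrt(eigval), index=X.columns, columns=comp_names
    )
    scores = pd.DataFrame(
        Z.to_numpy() @ eigvec, index=X.index, columns=comp_names
    )
    variability = eigval / p * 100.0
    cumulative = np.cumsum(variability)
    return PCAResult(
        eigenvalues=eigval,
        loadings=loadings,
        scores=scores,
        variability=variability,
        cumulative=cumulative,
        retained=kaiser_retain(eigval),
    )


def kaiser_retain(eigenvalues: Sequence[float], boundary: float = 1.0) -> tuple[int, ...]:
    """Kaiser rule: indices of components with eigenvalue >= ``boundary``.

    The boundary is inclusive.  If no component qualifies the first is
    retained anyway, with a warning — an ordination needs at least one axis.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise GourdstatsError("empty eigenvalue list")
    if np.any(np.diff(ev) > 1e-12):
        raise GourdstatsError("eigenvalues must be sorted in descending order")
    idx = tuple(int(i) for i in np.flatnonzero(ev >= boundary))
    if not idx:
        warnings.warn(
            "no eigenvalue reaches the retention boundary; keeping the first "
            "component only",
            stacklevel=2,
        )
        return (0,)
    return idx


def significant_loadings(result: PCAResult, threshold: float = 0.6) -> pd.DataFrame:
    """Boolean mask of loadings with |value| strictly above ``threshold``."""
    return result.loadings.abs() > threshold


def biplot_coords(result: PCAResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observation scores and variable loading vectors on PC1/PC2."""
    if result.eigenvalues.size < 2:
        raise GourdstatsError("biplot needs at least 2 components")
    return result.scores.iloc[:, :2].copy(), result.loadings.iloc[:, :2].copy()


def euclidean_dissimilarity(X: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance matrix between rows (no missing allowed)."""
    X = pd.DataFrame(X)
    if X.isna().any().any():
        raise InsufficientDataError(
            "missing entries: impute first (see mean_impute)"
        )
    D = squareform(pdist(X.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(D, index=X.index, columns=X.index)


@dataclass(frozen=True)
class ClusterTree:
    """UPGMA merge history.

    ``merges`` lists ``(node_a, node_b, height, new_node)`` in merge order;
    leaves are nodes ``0..n-1`` (aligned with ``labels``), internal nodes
    are numbered from ``n`` upward.  Heights are ultrametric (half the
    cluster distance) and non-decreasing along the sequence.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def upgma(D: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> ClusterTree:
    """Unweighted pair-group (arithmetic average) agglomerative clustering.

    Repeatedly merges the closest pair of clusters; the distance from the
    merged cluster to any other is the size-weighted mean of its members'
    distances, which equals the plain average of all between-cluster leaf
    distances.  Merge height is d/2.  Ties are broken by the smallest
    label-sorted pair, so the tree is deterministic.
    """
    if isinstance(D, pd.DataFrame):
        if labels is None:
            labels = [str(x) for x in D.index]
        D = D.to_numpy(dtype=float)
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise DesignError("distance matrix must be square")
    if n < 2:
        raise DesignError("need at least 2 leaves")
    if not np.allclose(D, D.T, atol=1e-10):
        raise DesignError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise DesignError("distances must be non-negative")
    if labels is None:
        labels = [f"L{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]

    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(D[i, j])
    active: dict[int, tuple[int, str]] = {
        i: (1, labels[i]) for i in range(n)
    }  # node -> (size, smallest member label for tie-breaks)
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    while len(active) > 1:
        best = None
        for key, d in dist.items():
            a, b = sorted(key)
            la = min(active[a][1], active[b][1])
            lb = max(active[a][1], active[b][1])
            cand = (d, la, lb, a, b)
            if best is None or cand < best:
                best = cand
        d, _, _, a, b = best
        size_a, lab_a = active[a]
        size_b, lab_b = active[b]
        new = next_node
        next_node += 1
        for other in list(active):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new, other))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        dist.pop(frozenset((a, b)))
        del active[a], active[b]
        active[new] = (size_a + size_b, min(lab_a, lab_b))
        merges.append((a, b, d / 2.0, new))
    return ClusterTree(labels=tuple(labels), merges=tuple(merges))


def cut_clusters(tree: ClusterTree, k: int) -> dict[str, int]:
    """Cut the dendrogram into exactly ``k`` clusters.

    Undoes the last ``k - 1`` merges: cluster ids (1-based) are assigned in
    order of each cluster's first leaf label.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise GourdstatsError(f"k must lie in [1, {n}], got {k}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for a, b, _height, new in tree.merges[: n - k]:
        members[new] = members.pop(a) + members.pop(b)
    clusters = sorted(
        members.values(), key=lambda leaves: min(tree.labels[i] for i in leaves)
    )
    out: dict[str, int] = {}
    for cid, leaves in enumerate(clusters, start=1):
        for leaf in leaves:
            out[tree.labels[leaf]] = cid
    return out


def _quote_label(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_to_newick(tree: ClusterTree) -> str:
    """Serialize an ultrametric merge history as a Newick string.

    Branch lengths are differences of merge heights, so leaf-to-root path
    lengths all equal the final merge height.  Labels containing spaces or
    Newick metacharacters are single-quoted.
    """
    n = tree.n_leaves
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    newick: dict[int, str] = {
        i: _quote_label(tree.labels[i]) for i in range(n)
    }
    root = n - 1 if not tree.merges else tree.merges[-1][3]
    for a, b, h, new in tree.merges:
        part_a = f"{newick.pop(a)}:{h - height.pop(a):.10g}"
        part_b = f"{newick.pop(b)}:{h - height.pop(b):.10g}"
        newick[new] = f"({part_a},{part_b})"
        height[new] = h
    return newick[root] + ";"
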