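"""Distance matrices and hierarchical clustering for germplasm panels.

Implements the two genetic distances used for phenotypic core sampling
(Euclidean and Mahalanobis), a generalized Lance–Williams agglomerative
engine covering the eight systematic clustering methods used in the
core-sampling strategy grid (single, complete, median, centroid, group
average / UPGMA, weighted average / WPGMA, flexible-beta, Ward), dendrogram
cutting, and neighbor-joining trees for genotype data.

The Lance–Williams recurrence updates the distance from a cluster ``k`` to
the merge of ``i`` and ``j`` as::

    d(k, i+j) = a_i d(k,i) + a_j d(k,j) + b d(i,j) + g |d(k,i) - d(k,j)|

The geometric methods (centroid, median, Ward) apply the recurrence to
squared distances — the only space in which their parameter sets are exact —
and reported merge heights are square-rooted back.  The remaining methods
operate on raw distances.  Nearest-pair ties are broken by the smallest
(i, j) index pair so merge order is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

__all__ = [
    "DistanceMatrix",
    "MergeTree",
    "NJTree",
    "LINKAGE_METHODS",
    "euclidean_distance",
    "mahalanobis_distance",
    "agglomerate",
    "cut_tree",
    "neighbor_joining",
]

#: the eight supported linkage method names
LINKAGE_METHODS = (
    "single",
    "complete",
    "median",
    "centroid",
    "group_average",
    "weighted_average",
    "flexible",
    "ward",
)

#: methods whose Lance–Williams parameters are exact only on squared distances
_SQUARED_SPACE = frozenset({"median", "centroid", "ward"})


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with accession ids."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0.0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def write_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


@dataclass
class MergeTree:
    """Agglomerative merge history in scipy labelling.

    Leaves are 0..n-1; the cluster formed by merge step ``s`` (0-based) has
    label ``n + s``.  ``merges`` is an (n-1, 4) array of
    (left, right, height, size).
    """

    leaf_ids: list[str]
    merges: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("expected n-1 merges")
        if not np.isfinite(self.merges).all():
            raise ValueError("non-finite merge record")

    @property
    def n(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_scipy_linkage(self) -> np.ndarray:
        """The merge history as a scipy.cluster.hierarchy linkage matrix."""
        return self.merges.copy()

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.merges, columns=["left", "right", "height", "size"]).to_csv(
            path, sep="\t", index=False
        )


def euclidean_distance(X: np.ndarray, ids: list[str]) -> DistanceMatrix:
    """Pairwise Euclidean distances between accession rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute upstream")
    return DistanceMatrix(list(ids), squareform(pdist(X, metric="euclidean")))


def mahalanobis_distance(
    X: np.ndarray, ids: list[str], cov_regularization: float = 0.0
) -> DistanceMatrix:
    """Pairwise Mahalanobis distances d_ij = sqrt((x_i-x_j)' S+ (x_i-x_j)).

    ``S`` is the sample covariance of ``X``.  Its inverse is the
    Moore–Penrose pseudo-inverse when singular, or ``(S + lambda I)^-1``
    when ``cov_regularization`` (lambda) is positive.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute upstream")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 accessions")
    if cov_regularization < 0:
        raise ValueError("cov_regularization must be >= 0")
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    if cov_regularization > 0:
        VI = np.linalg.inv(S + cov_regularization * np.eye(S.shape[0]))
    else:
        VI = np.linalg.pinv(S, hermitian=True)
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, VI, diff)
    d2 = np.clip(d2, 0.0, None)
    d = np.sqrt(d2)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ids), d)


def _lw_params(method: str, ni: float, nj: float, nk: float, beta: float):
    """Lance–Williams coefficients (a_i, a_j, b, g) for one update."""
    if method == "single":
        return 0.5, 0.5, 0.0, -0.5
    if method == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if method == "median":
        return 0.5, 0.5, -0.25, 0.0
    if method == "centroid":
        s = ni + nj
        return ni / s, nj / s, -ni * nj / (s * s), 0.0
    if method == "group_average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if method == "weighted_average":
        return 0.5, 0.5, 0.0, 0.0
    if method == "flexible":
        return (1.0 - beta) / 2.0, (1.0 - beta) / 2.0, beta, 0.0
    if method == "ward":
        N = ni + nj + nk
        return (ni + nk) / N, (nj + nk) / N, -nk / N, 0.0
    raise ValueError(f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}")


def agglomerate(D: DistanceMatrix, method: str, flexible_beta: float = -0.25) -> MergeTree:
    """Agglomerative clustering of ``D`` under a Lance–Williams linkage.

    Repeatedly merges the globally nearest active pair and updates distances
    by the Lance–Williams recurrence for ``method``.  See the module
    docstring for the parameter table and squared-space convention.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}")
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 accessions to cluster")
    squared = method in _SQUARED_SPACE
    d = D.matrix.astype(float) ** 2 if squared else D.matrix.astype(float).copy()
    np.fill_diagonal(d, np.inf)

    size = np.ones(n)
    label = np.arange(n)          # current cluster label per active slot
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        work = np.where(active[:, None] & active[None, :], d, np.inf)
        flat = int(np.argmin(work))            # row-major first => lexicographic tie-break
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        height = float(np.sqrt(max(dij, 0.0))) if squared else float(dij)
        merges[step] = (label[i], label[j], height, size[i] + size[j])

        ni, nj = size[i], size[j]
        others = np.flatnonzero(active)
        others = others[(others != i) & (others != j)]
        for k in others:
            ai, aj, b, g = _lw_params(method, ni, nj, size[k], flexible_beta)
            new = ai * d[k, i] + aj * d[k, j] + b * dij + g * abs(d[k, i] - d[k, j])
            d[i, k] = d[k, i] = new
        active[j] = False
        size[i] = ni + nj
        label[i] = n + step
    return MergeTree(list(D.ids), merges, method)


def cut_tree(tree: MergeTree, k: int) -> np.ndarray:
    """Cluster labels for a k-cluster cut (undoing the last k-1 merges).

    Labels are 0..k-1 in order of first appearance over accessions, so a
    permutation-independent canonical labelling.
    """
    n = tree.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for step in range(n - k):
        left, right = int(tree.merges[step, 0]), int(tree.merges[step, 1])
        new = n + step
        parent[find(left)] = new
        parent[find(right)] = new

    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[i] = relabel[r]
    assert len(relabel) == k
    return out


@dataclass
class NJTree:
    """Unrooted neighbor-joining tree with non-negative branch lengths."""

    tree: TreeNode
    ids: list[str]

    def to_newick(self) -> str:
        return str(self.tree).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def path_length_matrix(self) -> np.ndarray:
        """Leaf-to-leaf path lengths in the order of ``self.ids``."""
        dm = self.tree.tip_tip_distances(self.ids)
        return np.asarray(dm.data, dtype=float)


def neighbor_joining(D: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbor joining; negative branch lengths clamped to 0."""
    if D.n < 3:
        raise ValueError("neighbor joining needs at least 3 accessions")
    m = (D.matrix + D.matrix.T) / 2.0  # exact symmetry for skbio's validator
    tree = _skbio_nj(_SkbioDM(m, ids=D.ids), neg_as_zero=True)
    return NJTree(tree=tree, ids=list(D.ids))
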