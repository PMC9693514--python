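"""Two-way Ward clustering and discriminant validation.

The agglomerator is written from first principles: at each step the pair
of clusters whose merge minimally increases the total within-cluster sum
of squared Euclidean distances is fused (Ward's criterion,
ΔSSE(A, B) = |A||B|/(|A|+|B|) · ‖μ_A − μ_B‖²).  Merge heights record the
ΔSSE of each fusion, so two singletons merge at half their squared
distance.  Ties are broken lexicographically on the smallest member index
for full determinism.

Group validation follows classical discriminant analysis: group centroids
with a pooled within-group covariance (lightly shrunk toward its
diagonal), squared Mahalanobis distances between centroids, and nearest-
centroid classification in the Mahalanobis metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinkageTree",
    "GroupModel",
    "ward_linkage",
    "brute_force_ward",
    "two_way_cluster",
    "cut_tree",
    "fit_discriminant",
    "mahalanobis_matrix",
]


@dataclass
class LinkageTree:
    """Agglomeration history over ``labels``.

    ``merges`` is an ordered list of ``(members_a, members_b, height)``
    with members given as sorted tuples of leaf indices; heights are the
    Ward SSE increase of each fusion and are non-decreasing.
    """

    labels: list[str]
    merges: list[tuple[tuple[int, ...], tuple[int, ...], float]] = \
        field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def leaf_order(self) -> list[int]:
        """Display order: leaves as encountered by recursive expansion of
        the merge history (smaller-first at every junction)."""
        if not self.merges:
            return list(range(self.n_leaves))
        children: dict[tuple[int, ...], tuple] = {}
        for a, b, _ in self.merges:
            children[tuple(sorted(a + b))] = (a, b)
        root = tuple(sorted(self.merges[-1][0] + self.merges[-1][1]))

        order: list[int] = []

        def expand(node: tuple[int, ...]) -> None:
            if len(node) == 1:
                order.append(node[0])
                return
            a, b = children[node]
            expand(tuple(sorted(a)))
            expand(tuple(sorted(b)))

        expand(root)
        # leaves never merged (k < n-1 histories) follow in index order
        seen = set(order)
        order.extend(i for i in range(self.n_leaves) if i not in seen)
        return order

    def to_merge_frame(self) -> pd.DataFrame:
        rows = []
        for step, (a, b, h) in enumerate(self.merges, start=1):
            rows.append({
                "step": step,
                "members_a": "|".join(self.labels[i] for i in a),
                "members_b": "|".join(self.labels[i] for i in b),
                "height": h,
            })
        return pd.DataFrame(rows, columns=["step", "members_a",
                                           "members_b", "height"])

    def to_newick(self) -> str:
        """Serialise with node heights as cumulative branch lengths."""
        node_h: dict[tuple[int, ...], float] = {}
        name: dict[tuple[int, ...], str] = {
            (i,): self.labels[i] for i in range(self.n_leaves)}
        for i in range(self.n_leaves):
            node_h[(i,)] = 0.0
        for a, b, h in self.merges:
            key = tuple(sorted(a + b))
            la = h - node_h[tuple(sorted(a))]
            lb = h - node_h[tuple(sorted(b))]
            name[key] = (f"({name[tuple(sorted(a))]}:{max(la, 0.0):.9g},"
                         f"{name[tuple(sorted(b))]}:{max(lb, 0.0):.9g})")
            node_h[key] = h
        root = tuple(sorted(self.merges[-1][0] + self.merges[-1][1])) \
            if self.merges else (0,)
        return name[root] + ";"


def _ward_cost(na: int, nb: int, mu_a: np.ndarray, mu_b: np.ndarray) -> float:
    d = mu_a - mu_b
    return na * nb / (na + nb) * float(d @ d)


def ward_linkage(matrix, labels: list[str] | None = None) -> LinkageTree:
    """Ward agglomeration of the rows of ``matrix``.

    Maintains cluster centroids and sizes; at each step merges the pair
    with minimal SSE increase, breaking ties on the lexicographically
    smallest (members_a, members_b) index tuples.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = labels if labels is not None else list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = labels if labels is not None else \
            [str(i) for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a non-empty 2-D matrix")
    if np.isnan(X).any():
        raise ValueError("NaN in clustering matrix")
    if X.shape[0] == 1:
        return LinkageTree(labels=list(labels))  # degenerate: no merges

    clusters: dict[tuple[int, ...], tuple[int, np.ndarray]] = {
        (i,): (1, X[i].copy()) for i in range(X.shape[0])}
    tree = LinkageTree(labels=list(labels))
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i, ka in enumerate(keys):
            na, mu_a = clusters[ka]
            for kb in keys[i + 1:]:
                nb, mu_b = clusters[kb]
                cost = _ward_cost(na, nb, mu_a, mu_b)
                cand = (cost, ka, kb)
                if best is None or cand < best:
                    best = cand
        cost, ka, kb = best
        na, mu_a = clusters.pop(ka)
        nb, mu_b = clusters.pop(kb)
        merged = tuple(sorted(ka + kb))
        clusters[merged] = (na + nb, (na * mu_a + nb * mu_b) / (na + nb))
        tree.merges.append((ka, kb, cost))
    return tree


def brute_force_ward(matrix, labels: list[str] | None = None) -> LinkageTree:
    """Reference agglomerator: recompute total within-cluster SSE from raw
    points for every candidate merge at every step.  O(n⁴ p); used as an
    independent oracle for :func:`ward_linkage` on small instances."""
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) \
        else np.asarray(matrix, dtype=float)
    labels = labels if labels is not None else \
        [str(i) for i in range(X.shape[0])]

    def sse(members: tuple[int, ...]) -> float:
        pts = X[list(members)]
        mu = pts.mean(axis=0)
        return float(((pts - mu) ** 2).sum())

    clusters = [(i,) for i in range(X.shape[0])]
    tree = LinkageTree(labels=list(labels))
    while len(clusters) > 1:
        best = None
        for i, ka in enumerate(sorted(clusters)):
            for kb in sorted(clusters)[i + 1:]:
                cost = sse(tuple(sorted(ka + kb))) - sse(ka) - sse(kb)
                cand = (cost, ka, kb)
                if best is None or cand < best:
                    best = cand
        cost, ka, kb = best
        clusters.remove(ka)
        clusters.remove(kb)
        clusters.append(tuple(sorted(ka + kb)))
        tree.merges.append((ka, kb, cost))
    return tree


def two_way_cluster(matrix: pd.DataFrame
                    ) -> tuple[LinkageTree, LinkageTree, pd.DataFrame]:
    """Cluster rows (species) and columns (traits); return both trees and
    the heatmap-ready matrix reordered by both leaf orders."""
    row_tree = ward_linkage(matrix)
    col_tree = ward_linkage(matrix.T)
    rows = [matrix.index[i] for i in row_tree.leaf_order()]
    cols = [matrix.columns[i] for i in col_tree.leaf_order()]
    return row_tree, col_tree, matrix.loc[rows, cols]


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    """Cut into exactly ``k`` clusters by undoing the k−1 highest merges.

    Cluster ids are assigned by the smallest member index of each cluster
    (0-based, increasing).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    # Ward heights are monotone, so the k-1 highest merges are the last ones
    kept = tree.merges[: n - k]
    live = {(i,) for i in range(n)}
    for a, b, _ in kept:
        merged = tuple(sorted(a + b))
        live.discard(tuple(sorted(a)))
        live.discard(tuple(sorted(b)))
        live.add(merged)
    ordered = sorted(live, key=lambda m: m[0])
    out: dict[str, int] = {}
    for cid, mem in enumerate(ordered):
        for i in mem:
            out[tree.labels[i]] = cid
    return out


# ---------------------------------------------------------------------------
# Discriminant analysis

@dataclass
class GroupModel:
    """Centroids + pooled within-group covariance in transformed space."""

    groups: list[str]
    centroids: pd.DataFrame           # group × feature
    pooled_cov: pd.DataFrame          # feature × feature
    sizes: pd.Series
    shrinkage: float = 0.01

    def _cov_inv(self) -> np.ndarray:
        return np.linalg.inv(self.pooled_cov.to_numpy())

    def mahalanobis_sq(self, x, group: str) -> float:
        """Squared Mahalanobis distance of a feature vector to a centroid."""
        d = np.asarray(x, dtype=float) - \
            self.centroids.loc[group].to_numpy()
        return float(d @ self._cov_inv() @ d)

    def classify(self, X: pd.DataFrame) -> pd.Series:
        """Assign each row to the nearest centroid (Mahalanobis metric)."""
        VI = self._cov_inv()
        M = self.centroids.to_numpy()
        A = X[self.centroids.columns].to_numpy(dtype=float)
        d2 = np.empty((A.shape[0], M.shape[0]))
        for g in range(M.shape[0]):
            diff = A - M[g]
            d2[:, g] = np.einsum("ij,jk,ik->i", diff, VI, diff)
        idx = d2.argmin(axis=1)
        return pd.Series([self.groups[i] for i in idx], index=X.index,
                         name="group")


def fit_discriminant(matrix: pd.DataFrame, labels: pd.Series,
                     shrinkage: float = 0.01) -> GroupModel:
    """Fit centroids and pooled covariance for discriminant validation.

    Pooled covariance = within-group scatter / (n − g), then shrunk as
    (1−λ)·Σ + λ·diag(Σ) to keep it invertible when group sizes approach
    the feature dimension.
    """
    labels = labels.loc[matrix.index]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = labels.value_counts()
    small = [g for g in groups if sizes[g] < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 members: {small}")
    n, p = matrix.shape
    centroids = matrix.groupby(labels).mean().loc[groups]
    scatter = np.zeros((p, p))
    for g in groups:
        sub = matrix[labels == g].to_numpy(dtype=float)
        dev = sub - sub.mean(axis=0)
        scatter += dev.T @ dev
    pooled = scatter / (n - len(groups))
    pooled = (1 - shrinkage) * pooled + shrinkage * np.diag(np.diag(pooled))
    # features with zero within-group variance (e.g. a binary flag constant
    # inside every group) make the diagonal itself singular: such a feature
    # is infinitely discriminative in the Gaussian model.  Floor its
    # variance on the scale of the shrinkage intensity so distances stay
    # finite; distances dominated by such features are qualitative.
    diag = np.diag(pooled).copy()
    positive = diag[diag > 0]
    floor = max(shrinkage, 1e-6) * (positive.mean() if positive.size
                                    else 1.0)
    deficit = np.maximum(floor - diag, 0.0)
    pooled = pooled + np.diag(deficit)
    pooled_df = pd.DataFrame(pooled, index=matrix.columns,
                             columns=matrix.columns)
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "pooled covariance is numerically singular even after "
            "shrinkage; reduce the feature dimension")
    return GroupModel(groups=groups, centroids=centroids,
                      pooled_cov=pooled_df, sizes=sizes.loc[groups],
                      shrinkage=shrinkage)


def mahalanobis_matrix(model: GroupModel) -> pd.DataFrame:
    """Squared Mahalanobis distances between all group centroids."""
    VI = model._cov_inv()
    g = len(model.groups)
    M = model.centroids.to_numpy()
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            d = M[i] - M[j]
            out[i, j] = out[j, i] = float(d @ VI @ d)
    return pd.DataFrame(out, index=model.groups, columns=model.groups)
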