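"""Genetic-cluster inference: DAPC with BIC model selection and NJ trees.

DAPC (discriminant analysis of principal components) reduces the
mean-imputed, centered dosage matrix by PCA, runs k-means on the retained PC
scores over a grid of K, scores each K with the spherical-Gaussian BIC
``n ln(WSS/n) + K ln(n)``, and fits a linear discriminant analysis to the
clustering at the BIC-optimal K; per-sample group posteriors come from the
discriminant-space Gaussian model, and samples whose best posterior falls
below a threshold are labeled UNASSIGNED.

The neighbor-joining tree is the Saitou-Nei agglomeration on an IBS
distance matrix, with negative branch lengths clamped to zero and the
deficit shifted to the sister branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from heteropat.genotypes import MISSING, GenotypeMatrix
from heteropat.popgen import DistanceMatrix

__all__ = ["DAPCResult", "Tree", "run_dapc", "nj_tree", "cluster_composition", "UNASSIGNED"]

UNASSIGNED = "UN"


@dataclass
class DAPCResult:
    """BIC curve, chosen K, assignments and discriminant-space coordinates."""

    k_grid: list[int]
    bic: np.ndarray
    k_star: int
    n_pcs_retained: int
    variance_explained: float
    assignments: pd.Series  # sample -> "1".."K" or UNASSIGNED
    posteriors: pd.DataFrame  # samples x groups
    da_coords: pd.DataFrame  # first discriminant axes per sample
    da_loadings: np.ndarray  # PC-space discriminant axes

    def bic_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_grid, "bic": self.bic})


def _impute_center(g: GenotypeMatrix, scale: bool) -> np.ndarray:
    X = g.dosage.astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    X -= col_mean
    if scale:
        sd = X.std(axis=0)
        X /= np.where(sd > 0, sd, 1.0)
    return X


def run_dapc(
    g: GenotypeMatrix,
    k_grid: list[int] | range = range(2, 11),
    n_pcs: int | float = 0.90,
    unassigned_threshold: float = 0.5,
    seed: int = 0,
    scale: bool = False,
) -> DAPCResult:
    """DAPC over a K grid with BIC-based selection of the cluster number.

    ``n_pcs`` is either a fixed count of retained principal components or a
    cumulative-variance target in (0, 1) (smallest count reaching it, capped
    at n/3). Ties in the BIC argmin resolve to the smaller K.
    """
    k_grid = [int(k) for k in k_grid]
    n = g.n_samples
    if max(k_grid) >= n:
        raise ValueError(f"max(k_grid)={max(k_grid)} must be < n_samples={n}")
    X = _impute_center(g, scale=scale)
    pca = PCA(n_components=min(n - 1, g.n_loci), svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    if isinstance(n_pcs, float) and 0 < n_pcs < 1:
        keep = int(np.searchsorted(cumvar, n_pcs) + 1)
        keep = min(keep, max(1, n // 3))
    else:
        keep = int(n_pcs)
    if keep < 1 or keep > scores.shape[1]:
        raise ValueError(f"retained PC count {keep} out of range")
    S = scores[:, :keep]
    varexp = float(cumvar[keep - 1])

    rng = np.random.default_rng(seed)
    bic = np.empty(len(k_grid))
    labelings = []
    for i, k in enumerate(k_grid):
        km = KMeans(
            n_clusters=k, n_init=10, max_iter=300,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(S)
        wss = float(km.inertia_)
        bic[i] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        labelings.append(km.labels_)
    best = int(np.argmin(bic))  # first minimum -> smaller K on ties
    k_star = k_grid[best]
    labels = labelings[best]

    lda = LinearDiscriminantAnalysis()
    lda.fit(S, labels)
    post = lda.predict_proba(S)
    coords = lda.transform(S)
    group_names = [str(c + 1) for c in lda.classes_]
    argmax = post.argmax(axis=1)
    hard = np.array([group_names[a] for a in argmax], dtype=object)
    hard[post.max(axis=1) < unassigned_threshold] = UNASSIGNED

    return DAPCResult(
        k_grid=k_grid,
        bic=bic,
        k_star=k_star,
        n_pcs_retained=keep,
        variance_explained=varexp,
        assignments=pd.Series(hard, index=g.sample_ids, name="cluster"),
        posteriors=pd.DataFrame(post, index=g.sample_ids, columns=group_names),
        da_coords=pd.DataFrame(
            coords[:, : min(2, coords.shape[1])],
            index=g.sample_ids,
            columns=[f"DA{i + 1}" for i in range(min(2, coords.shape[1]))],
        ),
        da_loadings=lda.scalings_,
    )


class Tree:
    """Unrooted tree stored as an adjacency list with branch lengths."""

    def __init__(self) -> None:
        self.adj: dict[int, list[tuple[int, float]]] = {}
        self.names: dict[int, str] = {}  # leaves only
        self.root: int | None = None

    def _add_edge(self, a: int, b: int, length: float) -> None:
        self.adj.setdefault(a, []).append((b, length))
        self.adj.setdefault(b, []).append((a, length))

    @property
    def leaves(self) -> list[str]:
        return [self.names[i] for i in sorted(self.names)]

    def to_newick(self) -> str:
        assert self.root is not None

        def rec(node: int, parent: int | None) -> str:
            children = [(c, w) for c, w in self.adj.get(node, []) if c != parent]
            if not children:
                return self.names[node]
            inner = ",".join(f"{rec(c, node)}:{w:.10g}" for c, w in children)
            return f"({inner})"

        return rec(self.root, None) + ";"

    def path_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix (sum of branch lengths)."""
        leaf_ids = sorted(self.names)
        names = [self.names[i] for i in leaf_ids]
        out = pd.DataFrame(0.0, index=names, columns=names)
        for start in leaf_ids:
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in self.adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for other in leaf_ids:
                out.loc[self.names[start], self.names[other]] = dist[other]
        return out


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; branch lengths
    use the standard split formula, negative lengths are clamped to 0 with
    the deficit moved to the sister branch. Ties resolve to the lowest
    (i, j) index pair, making the topology deterministic.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    if np.isnan(d.values).any():
        raise ValueError(
            "distance matrix contains missing entries; prune those samples first"
        )

    tree = Tree()
    for i, name in enumerate(d.sample_ids):
        tree.names[i] = name
        tree.adj.setdefault(i, [])
    next_id = n
    active = list(range(n))
    D = {i: {j: float(d.values[i, j]) for j in range(n) if j != i} for i in range(n)}

    while len(active) > 3:
        r = len(active)
        rowsum = {i: sum(D[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for bj in range(ai + 1, r):
                i, j = active[ai], active[bj]
                q = (r - 2) * D[i][j] - rowsum[i] - rowsum[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2.0 * (r - 2))
        lj = dij - li
        # clamp negatives, shifting the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        tree._add_edge(u, i, li)
        tree._add_edge(u, j, lj)
        D[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D[i][k] + D[j][k] - dij)
            D[u][k] = duk
            D[k][u] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # resolve the final three nodes around a central vertex
    i, j, k = active
    li = 0.5 * (D[i][j] + D[i][k] - D[j][k])
    lj = 0.5 * (D[i][j] + D[j][k] - D[i][k])
    lk = 0.5 * (D[i][k] + D[j][k] - D[i][j])
    center = next_id
    for node, ln in ((i, li), (j, lj), (k, lk)):
        tree._add_edge(center, node, max(ln, 0.0))
    tree.root = center
    return tree


def cluster_composition(
    assignments: pd.Series | dict,
    meta: pd.DataFrame | None = None,
    by: tuple[str, ...] = ("line_type", "ecotype", "origin"),
) -> pd.DataFrame:
    """Per-cluster counts and 2-decimal percentages, overall and by metadata.

    Returns a long table with columns (grouping, category, cluster, n, pct);
    the 'overall' rows give each cluster's share of all samples.
    """
    if isinstance(assignments, dict):
        assignments = pd.Series(assignments, name="cluster")
    total = len(assignments)
    rows = []
    for cluster, cnt in assignments.value_counts().sort_index().items():
        rows.append(
            {
                "grouping": "overall", "category": "all", "cluster": cluster,
                "n": int(cnt), "pct": round(100.0 * cnt / total, 2),
            }
        )
    if meta is not None:
        meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
        for col in by:
            if col not in meta.columns:
                continue
            joined = pd.DataFrame(
                {"cluster": assignments, "category": meta.loc[assignments.index, col]}
            )
            for (cat, cluster), cnt in (
                joined.groupby(["category", "cluster"]).size().items()
            ):
                cat_total = int((joined["category"] == cat).sum())
                rows.append(
                    {
                        "grouping": col, "category": cat, "cluster": cluster,
                        "n": int(cnt), "pct": round(100.0 * cnt / cat_total, 2),
                    }
                )
    return pd.DataFrame(rows)
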