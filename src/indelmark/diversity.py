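"""Genetic distances, hierarchical trees and PCA for accession panels.

The default distance between two accessions is simple-matching dissimilarity
on band codes with pairwise deletion of missing cells:

    d = 1 - (markers with identical non-missing codes) / (markers non-missing in both)

which is a natural choice for codominant gel-band data. UPGMA
(average-linkage agglomeration, ultrametric output) and neighbor-joining
(Saitou-Nei Q-criterion, exact on additive matrices) are implemented with a
deterministic lexicographic tie-break on the smallest leaf label of each
cluster; trees are returned as :class:`skbio.TreeNode` and serialised as
newick. PCA operates on dosage-coded genotypes (reference 0, heterozygote 1,
InDel alleles 2; missing imputed to the column mean).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.tree import TreeNode
from sklearn.decomposition import PCA

from ._util import dosage_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "genetic_distance",
    "upgma",
    "neighbor_joining",
    "pca",
    "PcaResult",
    "to_newick",
    "tip_distances",
    "cut_ultrametric",
]


def genetic_distance(matrix: pd.DataFrame, metric: str = "simple_matching") -> pd.DataFrame:
    """Pairwise accession dissimilarities from a band-code matrix.

    Missing cells (code 0) are dropped pairwise; a pair with no comparable
    markers gets NaN (flagged undefined, logged). Output is a symmetric
    labels x labels DataFrame with zero diagonal.
    """
    if metric != "simple_matching":
        raise ValueError(f"unknown metric {metric!r}")
    if len(matrix) < 2:
        raise ValueError("need at least 2 accessions")
    codes = matrix.to_numpy()
    observed = codes != 0
    n = len(matrix)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = observed[i] & observed[j]
            m = int(both.sum())
            if m == 0:
                logger.warning(
                    "no comparable markers between %s and %s; distance undefined",
                    matrix.index[i], matrix.index[j],
                )
                d[i, j] = d[j, i] = np.nan
                continue
            same = int((codes[i][both] == codes[j][both]).sum())
            d[i, j] = d[j, i] = 1.0 - same / m
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _as_dist(dist: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    labels = [str(x) for x in dist.index]
    d = dist.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    return labels, d


def upgma(dist: pd.DataFrame) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    At each step the pair of clusters with the smallest average distance is
    merged at height d/2; ties are broken by the lexicographically smallest
    (min leaf label, min leaf label) pair, so the result is deterministic.
    """
    labels, d0 = _as_dist(dist)
    nodes = {i: TreeNode(name=labels[i]) for i in range(len(labels))}
    heights = {i: 0.0 for i in nodes}
    sizes = {i: 1 for i in nodes}
    reps = {i: labels[i] for i in nodes}
    d = {(i, j): d0[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))}
    next_id = len(labels)

    while len(nodes) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]])))),
        )
        (a, b), dab = best
        h = dab / 2.0
        for child in (a, b):
            nodes[child].length = h - heights[child]
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[a] + sizes[b]
        reps[next_id] = min(reps[a], reps[b])
        for k in list(nodes):
            if k in (a, b, next_id):
                continue
            dak = d.pop((min(a, k), max(a, k)))
            dbk = d.pop((min(b, k), max(b, k)))
            d[(k, next_id)] = (sizes[a] * dak + sizes[b] * dbk) / (sizes[a] + sizes[b])
        del d[(a, b)], nodes[a], nodes[b]
        next_id += 1

    root = nodes.popitem()[1]
    root.length = None
    return root


def neighbor_joining(dist: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining; recovers additive matrices exactly.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sibling branch (their sum is preserved). Tie-breaks are by the
    lexicographically smallest leaf-label pair, as in :func:`upgma`. The
    unrooted NJ tree is returned rooted at the final join.
    """
    labels, d0 = _as_dist(dist)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = {i: TreeNode(name=labels[i]) for i in range(n)}
    reps = {i: labels[i] for i in range(n)}
    d = {(i, j): d0[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    def dget(i, j):
        return d[(min(i, j), max(i, j))]

    while len(nodes) > 3:
        ids = sorted(nodes)
        m = len(ids)
        r = {i: sum(dget(i, k) for k in ids if k != i) for i in ids}
        best_key, best_pair = None, None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = ids[ai], ids[bi]
                q = (m - 2) * dget(i, j) - r[i] - r[j]
                key = (q, tuple(sorted((reps[i], reps[j]))))
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        dij = dget(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        if lj < 0:
            li, lj = dij, 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        for k in ids:
            if k in (i, j):
                continue
            duk = max(0.0, (dget(i, k) + dget(j, k) - dij) / 2.0)
            d[(min(k, next_id), max(k, next_id))] = duk
        for k in ids:
            for pair in ((min(i, k), max(i, k)), (min(j, k), max(j, k))):
                d.pop(pair, None)
        reps[next_id] = min(reps[i], reps[j])
        nodes[next_id] = parent
        del nodes[i], nodes[j]
        next_id += 1

    ids = sorted(nodes)
    if len(ids) == 3:
        i, j, k = ids
        li = (dget(i, j) + dget(i, k) - dget(j, k)) / 2.0
        lj = dget(i, j) - li
        lk = dget(i, k) - li
        for node_id, length in ((i, li), (j, lj), (k, lk)):
            nodes[node_id].length = max(0.0, length)
        root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    else:
        i, j = ids
        half = dget(i, j) / 2.0
        nodes[i].length = nodes[j].length = half
        root = TreeNode(children=[nodes[i], nodes[j]])
    return root


def to_newick(tree: TreeNode) -> str:
    """Serialise a tree as a newick string with branch lengths."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tip_distances(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip path-length (cophenetic/patristic) distance matrix."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def cut_ultrametric(tree: TreeNode, k: int) -> dict[str, int]:
    """Cut an ultrametric tree into k clusters by removing the k-1 highest
    internal nodes; returns tip label -> cluster index (0-based, in order of
    first appearance)."""
    internal = [n for n in tree.traverse(include_self=True) if not n.is_tip()]

    def height(node):  # ultrametric: distance to any descendant tip
        h, cur = 0.0, node
        while not cur.is_tip():
            cur = cur.children[0]
            h += cur.length or 0.0
        return h

    if k < 1 or k > len(list(tree.tips())):
        raise ValueError("k out of range")
    cut = set(sorted(internal, key=height, reverse=True)[: k - 1])
    clusters: dict[str, int] = {}
    idx = 0
    stack = [tree]
    roots = []
    while stack:
        node = stack.pop(0)
        if node in cut:
            stack = list(node.children) + stack
        else:
            roots.append(node)
    for node in roots:
        members = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        for m in members:
            clusters[m] = idx
        idx += 1
    return clusters


@dataclass(frozen=True)
class PcaResult:
    """PCA coordinates (accessions x components) and the explained-variance
    fraction per component (non-increasing, summing to <= 1)."""

    coordinates: pd.DataFrame
    explained_variance_fraction: np.ndarray


def pca(matrix: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """PCA of the dosage-coded genotype matrix.

    Band codes map to alternate-allele dosage (1 -> 0, 3 -> 1, 2/4 -> 2);
    missing cells are imputed to the marker mean. Columns are centred and the
    accession covariance eigendecomposed (via SVD); each component's sign is
    fixed by making its largest-magnitude loading positive. An all-constant
    matrix yields zero coordinates and zero explained variance.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 accessions")
    X = dosage_matrix(matrix)
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = col_mean[inds[1]]

    n_components = min(n_components, len(matrix) - 1, X.shape[1])
    if np.allclose(X, X[0]):
        coords = np.zeros((len(matrix), n_components))
        fractions = np.zeros(n_components)
    else:
        model = PCA(n_components=n_components, svd_solver="full")
        coords = model.fit_transform(X)
        # sign convention: largest-magnitude loading of each component positive
        for c in range(coords.shape[1]):
            loading = model.components_[c]
            top = np.argmax(np.abs(loading))
            if loading[top] < 0:
                coords[:, c] *= -1
        fractions = model.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=matrix.index, columns=cols),
        explained_variance_fraction=np.asarray(fractions),
    )
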