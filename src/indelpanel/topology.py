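"""Distance-based comparative topology: neighbor-joining trees and
classical (Torgerson) metric multidimensional scaling.

The NJ implementation follows Saitou-Nei with the Studier-Keppler
Q-criterion and the standard branch-length formulas; it is exact on
additive matrices.  Ties in the Q-matrix argmin are broken
lexicographically on the joined labels so results are platform-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .types import DistanceMatrix

logger = logging.getLogger(__name__)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> TreeNode:
    """Unrooted neighbor-joining tree from a distance matrix.

    With ``clamp_negative`` a negative branch length is set to zero and the
    deficit transferred to the adjacent branch of the joined pair.
    Returns a scikit-bio :class:`TreeNode` (trifurcating root, unrooted
    semantics) with all input labels as leaves.
    """
    if dm.size < 3:
        raise ValueError("neighbor joining requires at least three taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    # sort key for deterministic tie-breaking: smallest leaf label under node
    keys: list[str] = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # all (i, j) achieving the minimum, tie-broken on sorted label pair
        cands = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        best = min(
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in cands
            if i < j
        )
        _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if clamp_negative:
            if li < 0:
                lj += li
                li = 0.0
            if lj < 0:
                li += lj
                lj = 0.0
        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.extend([nodes[i], nodes[j]])
        d_new = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep][None, :]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final trifurcation
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode()
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    root.extend([a, b, c])
    return root


def tree_path_distances(tree: TreeNode, labels: list[str]) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree, in the given label order."""
    tip_dm = tree.tip_tip_distances()
    order = [list(tip_dm.ids).index(lab) for lab in labels]
    vals = np.asarray(tip_dm.data)[np.ix_(order, order)]
    return DistanceMatrix(labels, vals)


@dataclass
class MDSConfig:
    """Settings for classical metric MDS."""

    n_dims: int = 2


@dataclass
class MDSResult:
    coordinates: pd.DataFrame  # labels x dims
    eigenvalues: np.ndarray  # all eigenvalues, descending


def classical_mds(dm: DistanceMatrix, cfg: MDSConfig | None = None) -> MDSResult:
    """Classical (Torgerson) metric scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and embeds on
    the top ``n_dims`` axes with positive eigenvalues.  Negative
    eigenvalues (non-Euclidean input) are dropped with a logged warning;
    if fewer positive axes exist than requested, the embedding dimension
    is reduced with a warning.
    """
    cfg = cfg or MDSConfig()
    if dm.size < 2:
        raise ValueError("need at least two labels")
    if cfg.n_dims < 1 or cfg.n_dims > dm.size - 1:
        raise ValueError("n_dims must be between 1 and size - 1")
    d2 = dm.values**2
    k = dm.size
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10 * max(abs(eigvals[0]), 1.0), 1e-12)
    n_pos = int(np.sum(eigvals > tol))
    if np.any(eigvals < -tol):
        logger.warning(
            "distance matrix is not Euclidean-embeddable; %d negative "
            "eigenvalues dropped",
            int(np.sum(eigvals < -tol)),
        )
    dims = min(cfg.n_dims, n_pos)
    if dims < cfg.n_dims:
        logger.warning(
            "only %d positive eigenvalues available; embedding reduced "
            "from %d to %d dimensions",
            n_pos,
            cfg.n_dims,
            dims,
        )
    if dims == 0:  # all points coincide
        coords = np.zeros((k, cfg.n_dims))
        dims = cfg.n_dims
    else:
        coords = eigvecs[:, :dims] * np.sqrt(eigvals[:dims])
    frame = pd.DataFrame(
        coords, index=dm.labels, columns=[f"dim_{i + 1}" for i in range(dims)]
    )
    return MDSResult(frame, eigvals)


def group_separation_score(coords: pd.DataFrame, group_labels: list[str]) -> float:
    """Silhouette-style separation of labelled groups in an embedding.

    For each point, a = distance to its own group centroid and b = distance
    to the nearest other-group centroid; the score is the mean of
    (b - a) / max(a, b), zero when all points coincide.
    """
    groups = pd.Series(list(group_labels), index=coords.index)
    uniq = groups.unique()
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    centroids = {g: coords[groups == g].mean(axis=0).to_numpy() for g in uniq}
    scores = []
    x = coords.to_numpy()
    for idx in range(len(coords)):
        g = groups.iloc[idx]
        a = float(np.linalg.norm(x[idx] - centroids[g]))
        b = min(
            float(np.linalg.norm(x[idx] - centroids[h])) for h in uniq if h != g
        )
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))
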