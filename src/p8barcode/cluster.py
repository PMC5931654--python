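"""Qualitative similarity and UPGMA (SAHN) clustering of binary site data.

The similarity coefficient over 0/1 feature rows is selectable:

* ``simple_matching`` (default) — shared presences *and* shared absences
  over all features; the usual choice for qualitative restriction data.
* ``jaccard`` — shared presences over features present in either taxon.
* ``dice`` — 2 x shared presences over the summed presence counts.

Clustering agglomerates on distance ``1 - similarity`` with
size-weighted arithmetic average linkage (UPGMA), which yields an
ultrametric dendrogram: every pair of leaves coalesces at the distance at
which their clusters merged.  Ties on the minimal distance are broken
deterministically toward the lexicographically smallest pair of input
indices, so repeated runs produce byte-identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, TextIO

import numpy as np
import pandas as pd

from .matrix import BinaryMatrix

__all__ = [
    "SimilarityMatrix",
    "TreeNode",
    "Dendrogram",
    "similarity",
    "similarity_range",
    "upgma",
    "write_newick",
    "cophenetic_distances",
    "write_similarity",
]

Coefficient = Literal["simple_matching", "jaccard", "dice"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric taxa x taxa similarity coefficients in [0, 1]."""

    taxa: tuple[str, ...]
    values: np.ndarray
    coefficient_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError(f"values shape {v.shape} does not match {n} taxa")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1.0")
        object.__setattr__(self, "values", v)


def similarity(matrix: BinaryMatrix, coefficient: Coefficient = "simple_matching") -> SimilarityMatrix:
    """Pairwise similarity between taxa of a binary matrix.

    Degenerate denominators (no features, or a pair with no presences)
    resolve to 1.0 when the two rows are identical all-zero rows and 0.0
    otherwise, so "no data" taxa compare as identical to each other.
    """
    n, m = matrix.cells.shape
    if n < 2:
        raise ValueError("similarity needs at least 2 taxa")
    x = matrix.cells.astype(np.int64)
    a = x @ x.T                      # shared presences
    r = x.sum(axis=1)                # presences per row
    if coefficient == "simple_matching":
        if m == 0:
            vals = np.ones((n, n))
        else:
            both0 = m - r[:, None] - r[None, :] + a
            vals = (a + both0) / m
    elif coefficient == "jaccard":
        denom = r[:, None] + r[None, :] - a
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(denom > 0, a / np.where(denom > 0, denom, 1), 1.0)
    elif coefficient == "dice":
        denom = r[:, None] + r[None, :]
        vals = np.where(denom > 0, 2.0 * a / np.where(denom > 0, denom, 1), 1.0)
    else:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    np.fill_diagonal(vals, 1.0)
    vals = np.clip(vals, 0.0, 1.0)
    return SimilarityMatrix(taxa=matrix.taxa, values=vals, coefficient_name=coefficient)


def similarity_range(sim: SimilarityMatrix) -> tuple[float, float]:
    """(min, max) similarity over unordered distinct taxon pairs."""
    n = len(sim.taxa)
    if n < 2:
        raise ValueError("similarity_range needs at least 2 taxa")
    iu = np.triu_indices(n, k=1)
    off = sim.values[iu]
    return float(off.min()), float(off.max())


@dataclass
class TreeNode:
    """Node of an ultrametric dendrogram.

    ``join_height`` is the 1-similarity distance at which the node's
    children merged (0 for leaves); branch lengths in Newick output are
    differences of half-heights (midpoint-split convention).
    """

    taxon: Optional[str] = None
    join_height: float = 0.0
    children: tuple["TreeNode", "TreeNode"] | None = None
    # smallest original input index under this node; drives tie-breaking
    min_index: int = 0
    size: int = 1

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary UPGMA tree over a set of taxa."""

    root: TreeNode
    taxa: tuple[str, ...]

    def leaf_names(self) -> list[str]:
        return [leaf.taxon for leaf in self.root.leaves()]


#: Distances closer than this are treated as tied during agglomeration.
_TIE_TOL = 1e-9


def _closer(cand: tuple, best: tuple) -> bool:
    if cand[0] < best[0] - _TIE_TOL:
        return True
    if cand[0] > best[0] + _TIE_TOL:
        return False
    return cand[1:3] < best[1:3]


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """Agglomerate on distance 1 - similarity with UPGMA linkage.

    At each step the pair of clusters at minimal distance merges; the new
    cluster's distance to every other is the size-weighted mean of its
    parents' distances (equivalently, the unweighted mean of original
    leaf-pair distances).  Tie-break: smallest (min input index of first
    cluster, min input index of second cluster).
    """
    n = len(sim.taxa)
    dist = 1.0 - sim.values
    nodes: dict[int, TreeNode] = {
        i: TreeNode(taxon=sim.taxa[i], min_index=i) for i in range(n)
    }
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    # distances within _TIE_TOL count as tied, so index tie-breaking is not
    # derailed by last-ulp float noise in the running average
    while len(active) > 1:
        best: tuple[float, int, int, int, int] | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                dij = d[key]
                mi, mj = sorted((nodes[i].min_index, nodes[j].min_index))
                cand = (dij, mi, mj, i, j)
                if best is None or _closer(cand, best):
                    best = cand
        dij, _, _, i, j = best
        left, right = nodes[i], nodes[j]
        if right.min_index < left.min_index:
            left, right = right, left
        merged = TreeNode(
            join_height=dij,
            children=(left, right),
            min_index=left.min_index,
            size=left.size + right.size,
        )
        nodes[next_id] = merged
        heights[next_id] = dij
        ni, nj = nodes[i].size, nodes[j].size
        for k in active:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(min(next_id, k), max(next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return Dendrogram(root=nodes[active[0]], taxa=sim.taxa)


def _format_length(x: float) -> str:
    return f"{x:.10g}"


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Dendrogram) -> str:
    """Serialize to Newick with branch lengths reconstructing join heights.

    A node joined at distance h sits at ultrametric height h/2; each
    branch length is the parent half-height minus the child half-height,
    so leaf-to-leaf path lengths equal merge distances.  Labels with
    spaces or Newick metacharacters are single-quoted.
    """

    def render(node: TreeNode, parent_uheight: float) -> str:
        uheight = node.join_height / 2.0
        bl = _format_length(parent_uheight - uheight)
        if node.is_leaf:
            return f"{_quote_label(node.taxon)}:{bl}"
        inner = ",".join(render(c, uheight) for c in node.children)
        return f"({inner}):{bl}"

    root = tree.root
    root_uheight = root.join_height / 2.0
    if root.is_leaf:
        return f"{_quote_label(root.taxon)}:0;"
    inner = ",".join(render(c, root_uheight) for c in root.children)
    return f"({inner});"


def cophenetic_distances(tree: Dendrogram) -> tuple[tuple[str, ...], np.ndarray]:
    """Leaf-pair merge distances implied by the dendrogram.

    Returns taxa in the dendrogram's input order and the symmetric matrix
    of join heights at each pair's lowest common ancestor.
    """
    order = {t: i for i, t in enumerate(tree.taxa)}
    n = len(tree.taxa)
    out = np.zeros((n, n))

    def walk(node: TreeNode) -> list[int]:
        if node.is_leaf:
            return [order[node.taxon]]
        left = walk(node.children[0])
        right = walk(node.children[1])
        for i in left:
            for j in right:
                out[i, j] = out[j, i] = node.join_height
        return left + right

    walk(tree.root)
    return tree.taxa, out


def write_similarity(sim: SimilarityMatrix, path: str | Path | TextIO) -> None:
    """Tab-delimited square similarity table (taxa as index and columns)."""
    df = pd.DataFrame(sim.values, index=pd.Index(sim.taxa, name="taxon"), columns=sim.taxa)
    df.to_csv(path, sep="\t", float_format="%.6f")
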