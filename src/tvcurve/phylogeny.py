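"""All-pairs structural distances and UPGMA tree construction.

The distance matrix holds 1 - multiscale similarity for every pair of a set
of RNA records; UPGMA (unweighted pair-group method with arithmetic mean)
then agglomerates it into a rooted ultrametric tree. Averaging is
size-weighted — the distance between merged clusters always equals the mean
of the raw inter-cluster entries, i.e. classical UPGMA, not WPGMA. Ties for
the minimum distance are broken on the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf label), so the
tree is deterministic.

UPGMA is implemented here rather than delegated so the tie-break and the
exact merge bookkeeping are under control; the test suite cross-checks it
against SciPy's average-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import encode_tvcurve
from .errors import ValidationError
from .folding import FoldingBackend, ensure_structure
from .records import RnaRecord, validate_record
from .similarity import SimilarityConfig, multiscale_similarity, similarity_to_distance


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise structural distances with row/column labels."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(values, values.T, atol=0, rtol=0):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(values < 0):
            raise ValidationError("distance matrix entries must be nonnegative")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class TreeNode:
    """One node of a UPGMA dendrogram (leaf or binary internal node)."""

    height: float
    label: Optional[str] = None
    children: Tuple["TreeNode", "TreeNode"] = None  # type: ignore[assignment]
    _leaves: Optional[List[str]] = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaf_labels(self) -> List[str]:
        if self._leaves is None:
            if self.is_leaf:
                self._leaves = [self.label]  # type: ignore[list-item]
            else:
                self._leaves = [
                    lab for child in self.children for lab in child.leaf_labels()
                ]
        return self._leaves


@dataclass(frozen=True)
class Dendrogram:
    """A rooted ultrametric tree plus its merge history.

    ``merges`` records, per agglomeration round, the two merged clusters
    (as sorted leaf-label tuples) and the merge height; heights are
    non-decreasing along the sequence.
    """

    root: TreeNode
    merges: List[Tuple[Tuple[str, ...], Tuple[str, ...], float]]

    @property
    def leaves(self) -> List[str]:
        return self.root.leaf_labels()

    def cophenetic_matrix(self, labels: Optional[Sequence[str]] = None) -> np.ndarray:
        """Pairwise cophenetic distances: twice the height of the lowest
        common ancestor of each leaf pair."""
        labels = list(labels) if labels is not None else sorted(self.leaves)
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        out = np.zeros((n, n))

        def visit(node: TreeNode) -> List[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            left = visit(node.children[0])
            right = visit(node.children[1])
            for a in left:
                for b in right:
                    i, j = index[a], index[b]
                    out[i, j] = out[j, i] = 2.0 * node.height
            return left + right

        visit(self.root)
        return out

    def cut(self, k: int) -> Dict[str, int]:
        """Cut the tree into ``k`` clusters at the k-1 deepest merges.

        Replays the merge history, stopping before the last k-1 merges;
        returns leaf label -> cluster index (0-based, ordered by smallest
        member label).
        """
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"cannot cut a {n}-leaf tree into {k} clusters")
        clusters: Dict[str, frozenset] = {lab: frozenset([lab]) for lab in self.leaves}
        for left, right, _height in self.merges[: n - k]:
            merged = frozenset(left) | frozenset(right)
            for lab in merged:
                clusters[lab] = merged
        distinct = sorted({c for c in clusters.values()}, key=min)
        rank = {c: i for i, c in enumerate(distinct)}
        return {lab: rank[clusters[lab]] for lab in self.leaves}


def pairwise_distance_matrix(
    records: Sequence[RnaRecord],
    backend: FoldingBackend,
    cfg: Optional[SimilarityConfig] = None,
) -> DistanceMatrix:
    """Structural distance 1 - similarity for every pair of records.

    Requires at least three records (the phylogeny entry-point contract);
    records lacking structures are folded first. Each pair is computed once
    and mirrored.
    """
    if len(records) < 3:
        raise ValidationError("at least three RNA sequences are required")
    cfg = cfg or SimilarityConfig()
    records = [ensure_structure(validate_record(r), backend) for r in records]
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise ValidationError("record ids must be unique for a distance matrix")
    curves = [encode_tvcurve(r) for r in records]
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = similarity_to_distance(multiscale_similarity(curves[i], curves[j], cfg))
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=labels, values=D)


def upgma(matrix: DistanceMatrix) -> Dendrogram:
    """Classical (size-weighted) UPGMA agglomeration of a distance matrix.

    Merges the minimum-distance cluster pair at height d/2; the distance
    from the merged cluster to any other is the size-weighted mean of the
    two constituent distances, which keeps every cluster-to-cluster
    distance equal to the mean of the raw leaf-to-leaf entries.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValidationError("UPGMA requires at least two taxa")

    nodes: Dict[str, TreeNode] = {
        lab: TreeNode(height=0.0, label=lab) for lab in matrix.labels
    }
    sizes: Dict[str, int] = {lab: 1 for lab in matrix.labels}
    # cluster key = smallest leaf label it contains
    dist: Dict[Tuple[str, str], float] = {}
    active = sorted(matrix.labels)
    idx = {lab: i for i, lab in enumerate(matrix.labels)}
    for a_pos, a in enumerate(active):
        for b in active[a_pos + 1 :]:
            dist[(a, b)] = float(matrix.values[idx[a], idx[b]])

    merges: List[Tuple[Tuple[str, ...], Tuple[str, ...], float]] = []
    while len(active) > 1:
        best: Optional[Tuple[float, str, str]] = None
        for a_pos, a in enumerate(active):
            for b in active[a_pos + 1 :]:
                d = dist[(a, b)]
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d_min, a, b = best  # type: ignore[misc]
        height = d_min / 2.0
        node = TreeNode(height=height, children=(nodes[a], nodes[b]))
        merges.append(
            (tuple(sorted(nodes[a].leaf_labels())),
             tuple(sorted(nodes[b].leaf_labels())),
             height)
        )
        size_a, size_b = sizes[a], sizes[b]
        new_key = min(a, b)
        for other in active:
            if other in (a, b):
                continue
            da = dist[tuple(sorted((a, other)))]
            db = dist[tuple(sorted((b, other)))]
            merged_d = (size_a * da + size_b * db) / (size_a + size_b)
            dist[tuple(sorted((new_key, other)))] = merged_d
        active = sorted(set(active) - {a, b} | {new_key})
        nodes[new_key] = node
        sizes[new_key] = size_a + size_b

    return Dendrogram(root=nodes[active[0]], merges=merges)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t(),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram, precision: int = 6) -> str:
    """Serialize a dendrogram to Newick with branch lengths.

    Branch length = parent height - child height; children are ordered by
    their smallest descendant label, so output is deterministic. Labels
    containing spaces or Newick metacharacters are single-quoted.
    """

    def render(node: TreeNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            body = _quote_label(node.label)  # type: ignore[arg-type]
        else:
            kids = sorted(node.children, key=lambda c: min(c.leaf_labels()))
            body = "(" + ",".join(render(c, node.height) for c in kids) + ")"
        return f"{body}:{length:.{precision}f}"

    root = tree.root
    if root.is_leaf:
        return _quote_label(root.label) + ";"  # type: ignore[arg-type]
    kids = sorted(root.children, key=lambda c: min(c.leaf_labels()))
    return "(" + ",".join(render(c, root.height) for c in kids) + ");"
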