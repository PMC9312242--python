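"""UPGMA dendrogram construction from a labelled distance matrix.

Classic size-weighted average linkage (true UPGMA, not WPGMA): the closest
pair of clusters is merged at a node of height d/2, and the distance from
the merged cluster to any other is the size-weighted mean of its members'
distances. Ties are broken by the lexicographic order of cluster
representatives so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "TreeNode", "upgma", "to_newick"]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("matrix must be symmetric (tolerance 1e-12)")

    @classmethod
    def from_tsv(cls, path: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(x) for x in df.index], values=df.values)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


@dataclass
class TreeNode:
    """Ultrametric tree node: a labelled leaf (height 0) or an internal node
    of height = merge distance / 2 with two children."""

    height: float = 0.0
    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise leaf distances implied by the tree (2 x node height)."""
        labels = sorted(self.leaves())
        ix = {l: i for i, l in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    m[ix[a], ix[b]] = m[ix[b], ix[a]] = 2.0 * node.height
            return left + right

        walk(self)
        return DistanceMatrix(labels=labels, values=m)

    def topology(self) -> object:
        """Nested frozensets of leaf labels; equal iff topologies match."""
        if self.is_leaf:
            return self.label
        return frozenset({self.children[0].topology(), self.children[1].topology()})


def upgma(d: DistanceMatrix) -> TreeNode:
    """Build the UPGMA tree for *d* (>= 2 labels required)."""
    n = len(d.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(d.labels)
    }
    sizes = {i: 1 for i in range(n)}
    reps = {i: d.labels[i] for i in range(n)}  # lexicographic tie-break key
    dist = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n

    while len(nodes) > 1:
        # closest pair; ties broken by sorted representative labels
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((reps[kv[0][0]], reps[kv[0][1]])))),
        )
        (i, j), dij = best
        merged = TreeNode(height=dij / 2.0, children=(nodes[i], nodes[j]))
        others = [k for k in nodes if k not in (i, j)]
        for k in others:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(k, next_id)] = dnew
        for key in [key for key in dist if i in key or j in key]:
            if next_id not in key:
                del dist[key]
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        reps[next_id] = min(reps[i], reps[j])
        for k in (i, j):
            del nodes[k], sizes[k], reps[k]
        next_id += 1

    return nodes[next_id - 1]


def to_newick(t: TreeNode) -> str:
    """Serialize with branch lengths = parent height - child height."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.label
        else:
            body = "(" + ",".join(
                render(c, node.height) for c in node.children
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:g}"

    return render(t, None) + ";"
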