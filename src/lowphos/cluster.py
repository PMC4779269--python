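"""Two-way hierarchical clustering of expression profiles.

Genes are clustered on correlation distance (1 - Pearson r), samples on
Euclidean distance, both with average linkage by default. Items are sorted
lexicographically by id before agglomeration, so the dendrogram is
deterministic and invariant to the input row/column order even when
distances tie. Dendrograms serialize to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix


@dataclass
class DendrogramNode:
    """A rooted binary dendrogram: leaves carry ids, internal nodes a height."""

    id: int
    height: float
    left: "DendrogramNode | None" = None
    right: "DendrogramNode | None" = None
    leaf_name: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_name is not None

    @property
    def member_count(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.member_count + self.right.member_count

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_name]
        return self.left.leaves() + self.right.leaves()

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of every internal node (including the root)."""
        out: set[frozenset[str]] = set()

        def walk(node: "DendrogramNode") -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.leaf_name])
            s = walk(node.left) | walk(node.right)
            out.add(s)
            return s

        walk(self)
        return out


def distance_matrix(
    matrix: ExpressionMatrix, axis: str = "genes", metric: str = "correlation"
) -> pd.DataFrame:
    """Symmetric distance matrix over genes (rows) or samples (columns).

    ``correlation`` distance is 1 - Pearson r; a zero-variance profile has
    no defined correlation and raises, naming the offending item.
    """
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    data = matrix.values if axis == "genes" else matrix.values.T
    if len(data) < 2:
        raise ValueError(f"need >=2 {axis} to compute distances")
    X = data.to_numpy(dtype=float)
    ids = list(data.index)
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    elif metric == "correlation":
        sd = X.std(axis=1)
        flat = [ids[i] for i in np.nonzero(sd == 0)[0]]
        if flat:
            raise ValueError(
                f"zero-variance profile(s) under correlation metric: {flat[:5]}"
            )
        D = 1.0 - np.corrcoef(X)
        np.fill_diagonal(D, 0.0)
        D = np.clip(D, 0.0, 2.0)
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    D = 0.5 * (D + D.T)  # enforce exact symmetry against round-off
    return pd.DataFrame(D, index=ids, columns=ids)


def hierarchical_cluster(
    distances: pd.DataFrame, linkage: str = "average"
) -> DendrogramNode:
    """Agglomerative clustering of a distance matrix into a dendrogram.

    Items are pre-sorted by id so the merge order (and any tie-break) does
    not depend on the order of the input matrix.
    """
    if distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances.to_numpy(), distances.to_numpy().T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    order = sorted(distances.index)
    D = distances.loc[order, order].to_numpy(dtype=float)
    condensed = squareform(D, checks=False)
    Z = scipy_linkage(condensed, method=linkage)
    return _tree_from_linkage(Z, order)


def _tree_from_linkage(Z: np.ndarray, labels: list[str]) -> DendrogramNode:
    n = len(labels)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(id=i, height=0.0, leaf_name=labels[i]) for i in range(n)
    }
    for i, (a, b, h, _) in enumerate(Z):
        nodes[n + i] = DendrogramNode(
            id=n + i, height=float(h), left=nodes[int(a)], right=nodes[int(b)]
        )
    return nodes[n + len(Z) - 1]


def to_newick(node: DendrogramNode) -> str:
    """Serialize a dendrogram as a Newick string with branch lengths."""

    def render(n: DendrogramNode, parent_height: float) -> str:
        length = max(parent_height - n.height, 0.0)
        if n.is_leaf:
            return f"{_escape(n.leaf_name)}:{length:.10g}"
        inner = ",".join(render(c, n.height) for c in (n.left, n.right))
        return f"({inner}):{length:.10g}"

    return render(node, node.height) + ";"


def _escape(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def replicate_clade_fraction(
    sample_tree: DendrogramNode, sheet
) -> float:
    """Fraction of design cells whose replicates form a clade of the
    sample dendrogram (replicate coherence of the clustering)."""
    clades = sample_tree.clades()
    present = set(sample_tree.leaves())
    cells = 0
    coherent = 0
    for (a, t, tr), grp in sheet.frame.groupby(
        ["accession", "tissue", "treatment"], sort=True
    ):
        members = frozenset(grp["sample_id"]) & present
        if len(members) < 2:
            continue
        cells += 1
        if members in clades or members == present:
            coherent += 1
    return coherent / cells if cells else float("nan")
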