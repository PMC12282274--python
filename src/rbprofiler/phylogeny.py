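"""Distance-based phylogeny of RBP head domains.

The tree's job is visual grouping: leaves of the same RBP group should fall
together.  Distances are 100 − percent identity (a p-distance analogue; no
evolutionary-model correction, since the classification itself thresholds
raw identity), and the tree is built by canonical neighbor joining with the
Q-criterion.  Ties in Q are broken on the lexicographically smallest pair of
node labels (a node is labelled by the smallest leaf beneath it), so the
topology is deterministic and independent of input order.  Negative
estimated branch lengths — an NJ artefact on non-additive input — are
clamped to zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .grouping import IdentityMatrix


class NegativeBranchWarning(UserWarning):
    """Emitted when an estimated branch length is negative and clamped to 0."""


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal, in [0, 100]."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix dimensions must match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    @classmethod
    def from_identity(cls, m: IdentityMatrix) -> "DistanceMatrix":
        return cls(ids=list(m.ids), d=100.0 - m.identity)


@dataclass
class TreeNode:
    """A node of the inferred tree; the root is the final NJ join."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted leaf-name pairs."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            # distance from every leaf under `node` to `node`
            if node.is_leaf:
                return {node.name or "": 0.0}
            below: list[dict[str, float]] = []
            for child, blen in node.children:
                sub = walk(child)
                below.append({leaf: dist + blen for leaf, dist in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i].items():
                        for lb, db in below[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return dists


def _clamp(length: float) -> float:
    if length < 0:
        warnings.warn(
            f"negative branch length {length:.6g} clamped to 0",
            NegativeBranchWarning,
            stacklevel=3,
        )
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with deterministic tie-breaking.

    At each step the pair minimising Q(i, j) = (n−2)·d(i,j) − r_i − r_j is
    joined; exact ties go to the lexicographically smallest (label_i,
    label_j) pair.  For two taxa the single edge is split evenly.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    # tie-break label of a working node = smallest leaf name beneath it
    labels: list[str] = list(dm.ids)
    d = dm.d.copy()

    if n == 2:
        half = dm.d[0, 1] / 2.0
        root = TreeNode(children=[(nodes[0], _clamp(half)), (nodes[1], _clamp(half))])
        return PhyloTree(root=root)

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best: tuple[float, str, str, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                la, lb = sorted((labels[i], labels[j]))
                key = (q, la, lb, i, j)
                if best is None or key[:3] < best[:3]:
                    best = key
        assert best is not None
        _, _, _, i, j = best
        m2 = m - 2
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * m2)
        lj = d[i, j] - li
        new = TreeNode(children=[(nodes[i], _clamp(li)), (nodes[j], _clamp(lj))])
        # distances from the new node to the remainder
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [new_idx]

    # final star join of the last three nodes
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    order = sorted([(labels[i], i, li), (labels[j], j, lj), (labels[k], k, lk)])
    root = TreeNode(children=[(nodes[idx], _clamp(length)) for _, idx, length in order])
    return PhyloTree(root=root)


_NEWICK_RESERVED = set("(),:;'[] \t\n")


def _quote(name: str) -> str:
    if set(name) & _NEWICK_RESERVED:
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: PhyloTree) -> str:
    """Serialise with branch lengths in 6-decimal fixed format."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name or "")
        inner = ",".join(
            f"{render(child)}:{length:.6f}" for child, length in node.children
        )
        return f"({inner})"

    return render(tree.root) + ";"


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(to_newick(tree) + "\n")
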