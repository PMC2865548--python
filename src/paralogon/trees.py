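"""Phylogenetic tree and distance-matrix containers shared across modules.

Leaf labels follow the ``species|gene_id|chromosome`` convention when they
come from simulated or tabulated genomes; plain labels are also accepted
(species parses as the part before the first ``|``, or the whole label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import dendropy
import numpy as np


@dataclass
class TreeNode:
    """Node of a (possibly rooted) phylogenetic tree."""

    name: str = ""
    length: float = 0.0
    support: Optional[float] = None  # percentage in [0, 100]
    annotation: Optional[str] = None  # "speciation" | "duplication"
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def species(self) -> str:
        """Species component of a leaf label (text before the first '|')."""
        return self.name.split("|")[0]

    def copy(self) -> "TreeNode":
        return TreeNode(
            name=self.name,
            length=self.length,
            support=self.support,
            annotation=self.annotation,
            children=[c.copy() for c in self.children],
        )

    def find(self, predicate: Callable[["TreeNode"], bool]) -> list["TreeNode"]:
        return [n for n in self.postorder() if predicate(n)]


@dataclass
class PhyloTree:
    """A tree plus its rootedness flag.

    Unrooted trees are stored with an arbitrary trifurcating (or higher)
    top-level node; ``rooted`` records whether the top-level split is
    meaningful.
    """

    root: TreeNode
    rooted: bool = False

    def __post_init__(self) -> None:
        names = self.root.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")
        for n in self.root.postorder():
            if n.support is not None and not 0 <= n.support <= 100:
                raise ValueError("supports must lie in [0, 100]")

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions (both sides with >= 2 leaves), each in the
        canonical form of the side not containing the lexicographically first
        leaf. Topology-comparison currency for bootstrap and NJ-recovery tests."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.root.postorder():
            if node is self.root or node.is_leaf():
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def internal_edges(self) -> list[TreeNode]:
        """Internal (non-root, non-leaf) nodes, each defining one edge/bipartition."""
        return [
            n for n in self.root.postorder()
            if n is not self.root and not n.is_leaf()
        ]

    def to_newick(self) -> str:
        def fmt(node: TreeNode, top: bool = False) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = str(int(round(node.support)))
            elif node.name:
                label = node.name
            if top:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.6g}"

        return fmt(self.root, top=True) + ";"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, text: str, rooted: bool | None = None) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

        def convert(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon else (dnode.label or "")
            support = None
            if dnode.label and not dnode.is_leaf():
                try:
                    support = float(dnode.label)
                    name = ""
                except ValueError:
                    support = None
            return TreeNode(
                name=name,
                length=float(dnode.edge.length or 0.0),
                support=support,
                children=[convert(c) for c in dnode.child_nodes()],
            )

        root = convert(dt.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root=root, rooted=rooted)

    @classmethod
    def read(cls, path, rooted: bool | None = None) -> "PhyloTree":
        with open(path, encoding="utf-8") as fh:
            return cls.from_newick(fh.read(), rooted=rooted)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])
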