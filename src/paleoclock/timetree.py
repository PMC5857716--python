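"""Rooted, dated phylogenies stored in a flat array layout.

A :class:`TimeTree` is a rooted binary topology whose nodes carry absolute
ages in millions of years (Ma) — leaves at 0, every parent strictly older
than its children — and, optionally, per-node substitution rates in
substitutions per site per Ma.  The flat (parent-array) layout keeps the
MCMC inner loops simple and fast; Newick input/output goes through dendropy
so that standard tooling can read and write the trees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree", "TreeStructureError"]


class TreeStructureError(ValueError):
    """Raised when a tree violates the chronogram contract."""


@dataclass
class TimeTree:
    """Rooted binary tree with node ages (Ma) and optional branch rates.

    Attributes
    ----------
    parent:
        ``parent[i]`` is the index of node *i*'s parent, ``-1`` for the root.
    children:
        ``children[i]`` lists the child indices of node *i* (empty for leaves).
    labels:
        Leaf names, and internal-node labels where present (else ``""``).
    ages:
        Node ages in Ma, or ``None`` for a bare topology.  Leaves must be 0.
    rates:
        Per-node substitution rates (subs/site/Ma), or ``None``.
    """

    parent: np.ndarray
    children: list[list[int]]
    labels: list[str]
    ages: np.ndarray | None = None
    rates: np.ndarray | None = None
    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def leaves(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents (root last)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=int)
        return self._postorder

    def ancestors(self, node: int) -> list[int]:
        """Ancestors of ``node`` from its parent up to the root."""
        out = []
        p = int(self.parent[node])
        while p >= 0:
            out.append(p)
            p = int(self.parent[p])
        return out

    def node_by_label(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def copy(self) -> "TimeTree":
        return TimeTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            labels=list(self.labels),
            ages=None if self.ages is None else self.ages.copy(),
            rates=None if self.rates is None else self.rates.copy(),
        )

    # -------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check the chronogram invariants; raise TreeStructureError if broken."""
        n_children = np.array([len(c) for c in self.children])
        internal = n_children > 0
        if not np.all(n_children[internal] == 2):
            raise TreeStructureError("tree must be strictly binary")
        n_leaves = int((~internal).sum())
        if internal.sum() != n_leaves - 1:
            raise TreeStructureError("rooted binary tree needs n-1 internal nodes")
        if self.ages is not None:
            if np.any(self.ages[~internal] != 0.0):
                raise TreeStructureError("leaf ages must all be 0")
            root = self.root
            if self.ages[root] <= 0:
                raise TreeStructureError("root age must be positive")
            for i in range(self.n_nodes):
                p = self.parent[i]
                if p >= 0 and self.ages[p] <= self.ages[i]:
                    raise TreeStructureError(
                        f"parent age must exceed child age (node {i})"
                    )
        if self.rates is not None and np.any(self.rates <= 0):
            raise TreeStructureError("branch rates must be positive")

    # ----------------------------------------------------------------- branches
    def branch_durations(self) -> np.ndarray:
        """Duration (Ma) of the branch above each node; 0 for the root."""
        if self.ages is None:
            raise TreeStructureError("tree has no ages")
        dur = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        dur[has_parent] = self.ages[self.parent[has_parent]] - self.ages[has_parent]
        return dur

    # ------------------------------------------------------------------ Newick
    @classmethod
    def from_newick(cls, source: str, ages_from_lengths: bool = True) -> "TimeTree":
        """Parse a rooted Newick string or file path.

        If ``ages_from_lengths`` and branch lengths are present, they are read
        as time (Ma) and converted to node ages with leaves pinned at 0.
        """
        text = source
        if "(" not in source:  # path, not a Newick string
            with open(source) as fh:
                text = fh.read()
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
        return cls.from_dendropy(dtree, ages_from_lengths=ages_from_lengths)

    @classmethod
    def from_dendropy(
        cls, dtree: dendropy.Tree, ages_from_lengths: bool = True
    ) -> "TimeTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        labels = []
        for i, nd in enumerate(nodes):
            lbl = ""
            if nd.taxon is not None and nd.taxon.label:
                lbl = nd.taxon.label
            elif nd.label:
                lbl = nd.label
            labels.append(lbl)
            for ch in nd.child_nodes():
                j = index[id(ch)]
                parent[j] = i
                children[i].append(j)
        ages = None
        has_lengths = any(
            nd.edge.length is not None for nd in nodes if nd.parent_node is not None
        )
        if ages_from_lengths and has_lengths:
            depth = np.zeros(n)
            for nd in dtree.preorder_node_iter():
                i = index[id(nd)]
                if nd.parent_node is None:
                    depth[i] = 0.0
                else:
                    el = nd.edge.length or 0.0
                    depth[i] = depth[index[id(nd.parent_node)]] + el
            ages = depth.max() - depth
            ages[[i for i in range(n) if not children[i]]] = 0.0
        tree = cls(parent=parent, children=children, labels=labels, ages=ages)
        return tree

    def to_newick(self, include_ages_comment: bool = False) -> str:
        """Serialise to Newick; branch lengths are Ma durations when aged."""
        dur = self.branch_durations() if self.ages is not None else None

        def render(i: int) -> str:
            if self.children[i]:
                inner = ",".join(render(c) for c in self.children[i])
                s = f"({inner}){self.labels[i]}"
            else:
                s = self.labels[i]
            if include_ages_comment and self.ages is not None:
                s += f"[&age={self.ages[i]:.6g}]"
            if dur is not None and self.parent[i] >= 0:
                s += f":{dur[i]:.8g}"
            return s

        return render(self.root) + ";"

    def write_newick(self, path: str, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")
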