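"""Array-backed rooted phylogeny.

The diversity kernel needs exactly one thing from a tree: a post-order walk
over edges with branch lengths, so that per-edge descendant abundance mass
can be accumulated in a single linear pass (and, for whole tables, as one
matrix accumulation).  Parsing is delegated to dendropy; the parsed tree is
flattened into parallel arrays (``parent``, ``length``, ``postorder``) that
make the kernel a few numpy lines.

Conventions
-----------
* The tree is rooted; the root may carry an edge ("root edge") whose length
  defaults to 0 when the Newick string omits it.
* Every non-root edge must have an explicit branch length; a missing length
  is an error, never silently 0.
* Leaf labels are unique and are the taxon identifiers of the feature table.
* Internal node labels (e.g. support values) are read but ignored.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

from .errors import FormatError

__all__ = ["Phylogeny"]


class Phylogeny:
    """Rooted tree with branch lengths, stored as parallel node arrays.

    Node ``i`` has parent ``parent[i]`` (−1 for the root) and an edge of
    length ``length[i]`` leading to that parent (for the root, the root-edge
    length).  ``postorder`` lists all node indices children-first, so a
    bottom-up accumulation is a simple loop.
    """

    def __init__(
        self,
        parent: np.ndarray,
        length: np.ndarray,
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.size
        if self.length.size != n or len(self.labels) != n:
            raise ValueError("parent, length and labels must have equal size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise FormatError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(~np.isfinite(self.length)) or np.any(self.length < 0):
            raise FormatError("all branch lengths must be finite and >= 0")

        # children lists -> postorder + leaf bookkeeping
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                children[p].append(i)
        self._children = children
        self.is_leaf = np.array([len(c) == 0 for c in children], dtype=bool)

        order = np.empty(n, dtype=np.int64)
        stack = [(self.root, False)]
        k = 0
        while stack:
            node, done = stack.pop()
            if done:
                order[k] = node
                k += 1
            else:
                stack.append((node, True))
                for c in children[node]:
                    stack.append((c, False))
        if k != n:
            raise FormatError("tree contains nodes unreachable from the root")
        self.postorder = order

        leaf_nodes = np.flatnonzero(self.is_leaf)
        for i in leaf_nodes:
            if self.labels[i] is None or self.labels[i] == "":
                raise FormatError(f"unlabeled leaf at node index {i}")
        self.leaf_nodes = leaf_nodes
        self.leaf_labels = [self.labels[i] for i in leaf_nodes]
        if len(set(self.leaf_labels)) != len(self.leaf_labels):
            seen: set[str] = set()
            dup = next(x for x in self.leaf_labels if x in seen or seen.add(x))
            raise FormatError(f"duplicate leaf label: {dup!r}")
        self.leaf_index = {lab: int(node) for lab, node in zip(self.leaf_labels, leaf_nodes)}

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n, dtype=np.float64)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise FormatError(
                        "missing branch length on a non-root edge "
                        f"(node {nd.taxon.label if nd.taxon else i})"
                    )
                length[i] = float(nd.edge.length)
            else:
                length[i] = float(nd.edge.length or 0.0)  # root edge defaults to 0
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None and nd.is_leaf():
                labels[i] = nd.label
        return cls(parent, length, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    # ------------------------------------------------------------------ #
    # basic queries
    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_leaves(self) -> int:
        return self.leaf_nodes.size

    def children(self, node: int) -> list[int]:
        return self._children[node]

    def total_length(self) -> float:
        """Sum of all branch lengths, root edge included."""
        return float(self.length.sum())

    def to_newick(self) -> str:
        """Serialize deterministically (children in stored order)."""
        parts: dict[int, str] = {}
        for node in self.postorder:
            node = int(node)
            if self.is_leaf[node]:
                parts[node] = f"{self.labels[node]}:{self.length[node]:.10g}"
            else:
                inner = ",".join(parts.pop(c) for c in self._children[node])
                parts[node] = f"({inner}):{self.length[node]:.10g}"
        return parts[self.root] + ";"

    # ------------------------------------------------------------------ #
    # pruning
    # ------------------------------------------------------------------ #
    def prune_to(self, keep: Sequence[str]) -> "Phylogeny":
        """Restrict the tree to the given leaf labels.

        Internal nodes left with a single child are collapsed by summing the
        two adjacent branch lengths, so every pairwise path length among the
        retained leaves (and every leaf-to-root path) is preserved.
        """
        keep_set = set(keep)
        missing = keep_set - set(self.leaf_labels)
        if missing:
            raise FormatError(f"labels not in tree: {sorted(missing)[:5]}")
        n = self.n_nodes
        kept_below = np.zeros(n, dtype=np.int64)
        for node in self.postorder:
            node = int(node)
            if self.is_leaf[node]:
                kept_below[node] = 1 if self.labels[node] in keep_set else 0
            else:
                kept_below[node] = sum(kept_below[c] for c in self._children[node])
        if kept_below[self.root] == 0:
            raise FormatError("pruning would remove every leaf")

        new_parent: list[int] = []
        new_length: list[float] = []
        new_labels: list[str | None] = []
        # stack entries: (old node, parent index in new tree, length accrued
        # from collapsed ancestors)
        stack: list[tuple[int, int, float]] = [(self.root, -1, 0.0)]
        while stack:
            node, parent_idx, acc = stack.pop()
            kept_children = [c for c in self._children[node] if kept_below[c] > 0]
            if self.is_leaf[node] or len(kept_children) >= 2:
                idx = len(new_parent)
                new_parent.append(parent_idx)
                new_length.append(acc + self.length[node])
                new_labels.append(self.labels[node] if self.is_leaf[node] else None)
                for c in reversed(kept_children):
                    stack.append((c, idx, 0.0))
            else:  # unifurcation: collapse into the single kept child
                stack.append((kept_children[0], parent_idx, acc + self.length[node]))
        return Phylogeny(
            np.array(new_parent, dtype=np.int64),
            np.array(new_length, dtype=np.float64),
            new_labels,
        )

    # ------------------------------------------------------------------ #
    # utilities (mainly for validation / testing)
    # ------------------------------------------------------------------ #
    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """All pairwise leaf-to-leaf path lengths (quadratic; small trees)."""
        paths = {}
        for lab, node in self.leaf_index.items():
            d = {}
            cur, acc = node, 0.0
            while cur != -1:
                d[cur] = acc
                acc += self.length[cur]
                cur = int(self.parent[cur]) if self.parent[cur] >= 0 else -1
            paths[lab] = d
        labs = self.leaf_labels
        m = np.zeros((len(labs), len(labs)))
        for a, la in enumerate(labs):
            for b, lb in enumerate(labs):
                if a < b:
                    pa, pb = paths[la], paths[lb]
                    shared = set(pa) & set(pb)
                    lca_depth = min((pa[s], s) for s in shared)
                    m[a, b] = m[b, a] = pa[lca_depth[1]] + pb[lca_depth[1]]
        return labs, m
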