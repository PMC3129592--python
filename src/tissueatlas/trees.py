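"""Dendrogram container shared by the clustering and I/O layers.

Wraps a scipy linkage matrix together with leaf labels and optional
per-clade bootstrap supports (fractions in [0, 1], keyed by the frozenset
of leaf labels under the internal node).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy


@dataclass
class Dendrogram:
    labels: list
    linkage: np.ndarray
    supports: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(self.labels) == 0:
            raise ValueError("empty tree: no leaves")
        if len(self.labels) < 2:
            raise ValueError("a dendrogram needs at least two leaves")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate leaf labels")
        self.linkage = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError(
                f"linkage shape {self.linkage.shape} inconsistent with {n} leaves"
            )
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clades(self):
        """Yield (frozenset of leaf labels, merge height) per internal node, in merge order."""
        n = self.n_leaves
        leafsets = {i: frozenset([self.labels[i]]) for i in range(n)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            s = leafsets[int(a)] | leafsets[int(b)]
            leafsets[n + i] = s
            yield s, float(h)

    def bipartitions(self):
        """Canonical non-trivial unrooted leaf bipartitions implied by the tree.

        Each internal clade S defines the split S | L\\S; the canonical form is
        the side containing the lexicographically smallest label. Splits with a
        side of fewer than two leaves are trivial and omitted.
        """
        full = frozenset(self.labels)
        anchor = min(self.labels)
        out = set()
        for clade, _ in self.clades():
            other = full - clade
            if len(clade) < 2 or len(other) < 2:
                continue
            out.add(clade if anchor in clade else other)
        return out

    def to_newick(self, support_percent: bool = True) -> str:
        """Render as a Newick string; supports become internal-node labels in percent."""
        for lab in self.labels:
            if lab is None or str(lab) == "":
                raise ValueError("unlabelled leaf")
        root = hierarchy.to_tree(self.linkage)
        labels = self.labels
        supports = self.supports or {}

        def leafset(node):
            return frozenset(labels[i] for i in node.pre_order(lambda x: x.id))

        def min_leaf(node):
            return min(labels[i] for i in node.pre_order(lambda x: x.id))

        def fmt(node, is_root):
            if node.is_leaf():
                return str(labels[node.id])
            kids = sorted((node.left, node.right), key=min_leaf)
            s = f"({fmt(kids[0], False)},{fmt(kids[1], False)})"
            if not is_root:
                sup = supports.get(leafset(node))
                if sup is not None:
                    s += str(int(round(sup * 100))) if support_percent else f"{sup:g}"
            return s

        return fmt(root, True) + ";"
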