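"""Rooted, labeled phylogenies.

A thin container over :class:`skbio.TreeNode` that adds the conveniences the
rest of the package needs: branch addressing by the label of the node a
branch leads into, clade tip sets, cached patristic distances, and
ultrametricity checks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode


class TreeError(ValueError):
    """Raised for malformed trees or unknown node/branch references."""


@dataclass
class LabeledTree:
    """A rooted phylogeny with branch lengths and unique tip labels.

    Branches are addressed by the label of their *child* node; the branch
    above the root is addressed by the root's own label (or ``"root"``).
    """

    root: TreeNode
    _patristic: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for node in self.root.traverse(include_self=False):
            if node.length is None:
                raise TreeError(f"branch leading to {node.name!r} has no length")
            if node.length < 0:
                raise TreeError(f"negative branch length at {node.name!r}")
        if self.root.length is None:
            self.root.length = 0.0

    # -- construction / serialization ------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "LabeledTree":
        tree = TreeNode.read(io.StringIO(text), format="newick")
        return cls(tree)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf, format="newick")
        return buf.getvalue().strip()

    def copy(self) -> "LabeledTree":
        return LabeledTree(self.root.copy())

    # -- basic accessors --------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [t.name for t in self.root.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.root.tips())

    def node(self, label: str) -> TreeNode:
        if label == "root" or label == self.root.name:
            return self.root
        for n in self.root.traverse(include_self=False):
            if n.name == label:
                return n
        raise TreeError(f"no node labeled {label!r} in tree")

    def has_node(self, label: str) -> bool:
        try:
            self.node(label)
            return True
        except TreeError:
            return False

    def clade_tips(self, branch_label: str) -> list[str]:
        """Tip labels descending from the branch leading into *branch_label*."""
        n = self.node(branch_label)
        if n.is_tip():
            return [n.name]
        return [t.name for t in n.tips()]

    # -- distances ---------------------------------------------------------
    def patristic(self) -> pd.DataFrame:
        """Symmetric tip-to-tip patristic distance matrix (cached)."""
        if self._patristic is None:
            dm = self.root.tip_tip_distances()
            self._patristic = pd.DataFrame(
                np.asarray(dm.data, dtype=float), index=list(dm.ids), columns=list(dm.ids)
            )
        return self._patristic

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            for child in node.children:
                d = acc + (child.length or 0.0)
                if child.is_tip():
                    depths[child.name] = d
                else:
                    walk(child, d)

        walk(self.root, 0.0)
        return depths

    def height(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.tip_depths().values())
        return max(depths) - min(depths) <= tol

    # -- editing -----------------------------------------------------------
    def scaled(self, factor: float) -> "LabeledTree":
        """A copy with every branch length multiplied by *factor*."""
        if factor <= 0:
            raise TreeError("scale factor must be positive")
        new = self.root.copy()
        for node in new.traverse(include_self=True):
            if node.length is not None:
                node.length *= factor
        return LabeledTree(new)

    def rename_tips(self, mapping: dict[str, str]) -> "LabeledTree":
        new = self.root.copy()
        for t in new.tips():
            if t.name in mapping:
                t.name = mapping[t.name]
        return LabeledTree(new)
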