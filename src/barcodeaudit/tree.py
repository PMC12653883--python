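"""Minimal rooted-tree container for the neighbor-joining identification tree.

Leaves are labeled with record ids; internal nodes are unlabeled.  The
Newick dialect is fixed: rooted, branch lengths always printed to six
decimals, no internal labels, trailing semicolon; a single-leaf tree is
serialized as ``(label:len);``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TreeNode:
    label: str | None = None
    #: (child, branch length to child) pairs.
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_path_lengths(self) -> dict[frozenset[str], float]:
        """Sum of branch lengths between every pair of leaf labels."""

        def collect(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label or "", 0.0)]
            subs = []
            for child, length in node.children:
                subs.append([(lab, d + length) for lab, d in collect(child)])
            # pairs joining at this node
            for i in range(len(subs)):
                for j in range(i + 1, len(subs)):
                    for la, da in subs[i]:
                        for lb, db in subs[j]:
                            paths[frozenset((la, lb))] = da + db
            return [x for sub in subs for x in sub]

        paths: dict[frozenset[str], float] = {}
        collect(self)
        return paths
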