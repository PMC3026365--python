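"""Minimal tree container used by the built-in neighbor-joining stage."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ValidationError


@dataclass(eq=False)  # identity semantics: nodes live in recursive structures
class TreeNode:
    label: str | None = None
    length: float | None = None  # branch length to the parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """A (conventionally unrooted) tree; the root is just the serialization
    anchor. NJ output has a degree-3 root for n >= 3 taxa."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        names = [n.label for n in self.leaves()]
        if any(n is None for n in names):
            raise ValidationError("tree has unlabeled leaves")
        return names


def leaf_distance_matrix(tree: Tree):
    """Path-length matrix between all leaf pairs.

    Computed by direct root-path comparison — independent of any
    inference code, so it can serve as an oracle for additivity checks.
    """
    import numpy as np

    from .distance import DistanceMatrix

    paths: dict[str, list[tuple[TreeNode, float]]] = {}

    def walk(node: TreeNode, trail: list[tuple[TreeNode, float]]):
        trail = trail + [(node, node.length or 0.0)]
        if node.is_leaf:
            paths[node.label] = trail
        for c in node.children:
            walk(c, trail)

    walk(tree.root, [])
    ids = sorted(paths)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[ids[i]], paths[ids[j]]
            shared = 0
            while shared < min(len(pi), len(pj)) and pi[shared][0] is pj[shared][0]:
                shared += 1
            dist = sum(x[1] for x in pi[shared:]) + sum(x[1] for x in pj[shared:])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=ids, d=d)
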