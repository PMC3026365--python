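"""Newick serialization and parsing.

Writing is done in-package so that output bytes are deterministic
(shortest round-tripping float representation, fixed child order).
Parsing delegates to dendropy, whose reader reports line/column positions
for malformed input, and converts into the package's Tree.
"""

from __future__ import annotations

import io
import re

import dendropy

from ..errors import ParseError
from .tree import Tree, TreeNode

#: Characters that break unquoted Newick labels.
_UNSAFE = re.compile(r"[ (),:;'\[\]]")


def sanitize_label(label: str) -> str:
    return _UNSAFE.sub("_", label)


def _fmt_length(x: float) -> str:
    return repr(float(x)) if x is not None else None


def _node_str(node: TreeNode, name_map: dict[str, str]) -> str:
    if node.is_leaf:
        text = name_map.get(node.label, node.label or "")
    else:
        text = "(" + ",".join(_node_str(c, name_map) for c in node.children) + ")"
        if node.label:
            text += name_map.get(node.label, node.label)
    if node.length is not None:
        text += f":{_fmt_length(node.length)}"
    return text


def write_newick(tree: Tree, stream=None) -> dict[str, str]:
    """Serialize ``tree``; returns the sanitization map (original ->
    written) for any label containing Newick metacharacters."""
    name_map: dict[str, str] = {}
    for leaf in tree.leaves():
        safe = sanitize_label(leaf.label)
        if safe != leaf.label:
            name_map[leaf.label] = safe
    text = _node_str(tree.root, name_map) + ";\n"
    if stream is not None:
        stream.write(text)
    return name_map


def newick_string(tree: Tree) -> str:
    buf = io.StringIO()
    write_newick(tree, buf)
    return buf.getvalue()


def _convert(dnode) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.children.append(_convert(child))
    return node


def parse_newick(stream) -> Tree:
    """Parse one Newick tree; errors carry dendropy's position info."""
    text = stream if isinstance(stream, str) else stream.read()
    if not text.strip():
        raise ParseError("empty Newick input")
    if not text.strip().endswith(";"):
        raise ParseError(
            f"Newick statement not terminated by ';' (at position {len(text.rstrip())})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc
    root = _convert(dtree.seed_node)
    root.length = dtree.seed_node.edge.length  # usually None
    return Tree(root=root)
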