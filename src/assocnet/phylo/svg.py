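"""Minimal rectangular-edge cladogram rendering of a tree to SVG text."""

from __future__ import annotations

from .tree import Tree, TreeNode

_ROW_H = 18
_CHAR_W = 7
_PAD = 10


def render_svg(tree: Tree, width: int = 640) -> str:
    leaves = tree.leaves()
    n = len(leaves)
    depth: dict[int, float] = {}
    y: dict[int, float] = {}
    next_row = [0]

    def walk(node: TreeNode, x: float):
        x += node.length or 0.0
        depth[id(node)] = x
        if node.is_leaf:
            y[id(node)] = next_row[0] * _ROW_H + _ROW_H / 2
            next_row[0] += 1
        else:
            for c in node.children:
                walk(c, x)
            ys = [y[id(c)] for c in node.children]
            y[id(node)] = (min(ys) + max(ys)) / 2

    walk(tree.root, 0.0)
    max_depth = max(depth.values()) or 1.0
    label_w = max((len(l.label or "") for l in leaves), default=0) * _CHAR_W
    plot_w = max(width - label_w - 2 * _PAD, 50)
    sx = plot_w / max_depth

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{n * _ROW_H + 2 * _PAD}">',
        '<g stroke="black" fill="none" stroke-width="1">',
    ]

    def draw(node: TreeNode):
        x1 = _PAD + (depth[id(node)] - (node.length or 0.0)) * sx
        x2 = _PAD + depth[id(node)] * sx
        yy = y[id(node)] + _PAD
        parts.append(f'<path d="M {x1:.2f} {yy:.2f} H {x2:.2f}"/>')
        if not node.is_leaf:
            ys = [y[id(c)] + _PAD for c in node.children]
            parts.append(
                f'<path d="M {x2:.2f} {min(ys):.2f} V {max(ys):.2f}"/>'
            )
            for c in node.children:
                draw(c)

    draw(tree.root)
    parts.append("</g>")
    parts.append('<g font-family="monospace" font-size="11">')
    for leaf in leaves:
        parts.append(
            f'<text x="{_PAD + depth[id(leaf)] * sx + 4:.2f}" '
            f'y="{y[id(leaf)] + _PAD + 4:.2f}">{leaf.label or ""}</text>'
        )
    parts.append("</g></svg>")
    return "\n".join(parts) + "\n"
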