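"""Neighbor-joining tree inference (Saitou & Nei, Studier-Keppler Q).

At each step the pair (i, j) minimizing

    Q(i, j) = (n - 2) d(i, j) - R_i - R_j,     R_i = sum_k d(i, k)

is joined into a new node u with branch lengths

    l_i = d(i, j)/2 + (R_i - R_j) / (2 (n - 2)),   l_j = d(i, j) - l_i

and d(u, k) = (d(i, k) + d(j, k) - d(i, j)) / 2. On additive input the
generating tree is recovered exactly. Ties in Q are broken by the
lexicographically smallest (cluster id_i, cluster id_j), where a
cluster's id is the smallest leaf label it contains; together with the
fixed child order this makes output bytes a pure function of the input.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from .distance import DistanceMatrix
from .tree import Tree, TreeNode


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> Tree:
    """Infer an unrooted NJ tree from a distance matrix.

    Negative branch lengths (possible on non-additive input) are kept by
    default; ``clamp_negative`` floors them at zero. For two taxa the
    single branch is split evenly.
    """
    n0 = len(dm.ids)
    if n0 < 2:
        raise ValidationError("neighbor joining needs at least 2 taxa")
    d = np.array(dm.d, dtype=float)
    if not np.allclose(d, d.T, atol=0.0, rtol=0.0):
        raise ValidationError("neighbor joining requires a symmetric matrix")

    def bl(x: float) -> float:
        return max(0.0, x) if clamp_negative else x

    nodes: list[TreeNode] = [TreeNode(label=name) for name in dm.ids]
    # Cluster id = smallest contained leaf label; used only for tie-breaks
    # and deterministic child ordering.
    cids: list[str] = list(dm.ids)

    if n0 == 2:
        half = bl(float(d[0, 1]) / 2.0)
        order = sorted(range(2), key=lambda k: cids[k])
        for k in order:
            nodes[k].length = half
        return Tree(root=TreeNode(children=[nodes[k] for k in order]))

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # q is not bitwise symmetric (summation order differs per triangle);
        # minimize over the same upper triangle the tie-break scan visits.
        qmin = q[np.triu_indices(m, 1)].min()
        best: tuple[str, str] | None = None
        bi = bj = -1
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] == qmin:
                    key = tuple(sorted((cids[i], cids[j])))
                    if best is None or key < best:
                        best, bi, bj = key, i, j
        i, j = bi, bj
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = bl(float(li))
        nodes[j].length = bl(float(lj))
        children = sorted([i, j], key=lambda k: cids[k])
        new_node = TreeNode(children=[nodes[k] for k in children])
        new_cid = min(cids[i], cids[j])

        du = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = du[keep]
        d_new[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [new_node]
        cids = [cids[k] for k in keep] + [new_cid]
        d = d_new

    # Final three-way join: closed-form branch lengths.
    (x, y, z) = (0, 1, 2)
    lx = (d[x, y] + d[x, z] - d[y, z]) / 2.0
    ly = (d[x, y] + d[y, z] - d[x, z]) / 2.0
    lz = (d[x, z] + d[y, z] - d[x, y]) / 2.0
    for k, lk in ((x, lx), (y, ly), (z, lz)):
        nodes[k].length = bl(float(lk))
    order = sorted(range(3), key=lambda k: cids[k])
    return Tree(root=TreeNode(children=[nodes[k] for k in order]))
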