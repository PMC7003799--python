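"""Brute-force reference implementations used as independent oracles.

These deliberately avoid the library's code paths: patristic distances come
from root-path algebra (depth(i) + depth(j) - 2*depth(MRCA)), nearest-taxon
statistics from explicit double loops, and weighted UniFrac from a manual
branch walk accumulating descendant tip sets.
"""

from __future__ import annotations

import numpy as np


def _root_paths(tree):
    """Map tip name -> list of (node id, branch length) from root to tip."""
    paths = {}

    def walk(node, acc):
        acc = acc + [(id(node), node.length or 0.0)]
        if node.is_tip():
            paths[node.name] = acc
        else:
            for child in node.children:
                walk(child, acc)

    for child in tree.children:
        walk(child, [])
    return paths


def patristic(tree, a: str, b: str) -> float:
    """Tip-to-tip distance via shared-prefix removal of root paths."""
    paths = _root_paths(tree)
    pa, pb = paths[a], paths[b]
    i = 0
    while i < min(len(pa), len(pb)) and pa[i][0] == pb[i][0]:
        i += 1
    return sum(l for _, l in pa[i:]) + sum(l for _, l in pb[i:])


def patristic_matrix(tree) -> tuple[list[str], np.ndarray]:
    tips = sorted(t.name for t in tree.tips())
    n = len(tips)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = patristic(tree, tips[i], tips[j])
    return tips, out


def mntd(taxa, dist_of) -> float:
    """Unweighted MNTD by exhaustive double loop; dist_of(a, b) -> float."""
    taxa = list(taxa)
    vals = []
    for a in taxa:
        vals.append(min(dist_of(a, b) for b in taxa if b != a))
    return float(np.mean(vals))


def mntd_weighted(abund: dict, dist_of) -> float:
    taxa = [t for t, x in abund.items() if x > 0]
    total = sum(abund[t] for t in taxa)
    return float(
        sum(
            abund[a] / total * min(dist_of(a, b) for b in taxa if b != a)
            for a in taxa
        )
    )


def beta_mntd(taxa_a, taxa_b, dist_of) -> float:
    a_to_b = [min(dist_of(x, y) for y in taxa_b) for x in taxa_a]
    b_to_a = [min(dist_of(y, x) for x in taxa_a) for y in taxa_b]
    return float(np.mean(a_to_b + b_to_a))


def beta_mntd_weighted(ab_a: dict, ab_b: dict, dist_of) -> float:
    ta = [t for t, x in ab_a.items() if x > 0]
    tb = [t for t, x in ab_b.items() if x > 0]
    wa = np.array([ab_a[t] for t in ta], dtype=float)
    wb = np.array([ab_b[t] for t in tb], dtype=float)
    na = np.array([min(dist_of(x, y) for y in tb) for x in ta])
    nb = np.array([min(dist_of(y, x) for x in ta) for y in tb])
    return 0.5 * (float((na * wa / wa.sum()).sum()) + float((nb * wb / wb.sum()).sum()))


def weighted_unifrac(tree, counts_a: dict, counts_b: dict):
    """(raw, normalized) weighted UniFrac by explicit branch enumeration."""
    ta = sum(counts_a.values())
    tb = sum(counts_b.values())
    num = 0.0
    den = 0.0

    def tipset(node):
        return {t.name for t in node.tips()} if not node.is_tip() else {node.name}

    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        tips = tipset(node)
        pa = sum(counts_a.get(t, 0) for t in tips) / ta
        pb = sum(counts_b.get(t, 0) for t in tips) / tb
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    return num, (num / den if den > 0 else 0.0)
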