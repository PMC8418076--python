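"""Independent brute-force oracles used by the test suite.

Deliberately written from the definitions, not from the library code paths
they check: a quadratic crossing enumerator over explicit index pairs, and
an exhaustive valid-edit-mapping search for the ordered tree edit distance.
"""

from __future__ import annotations

from itertools import combinations


def brute_force_token_crossings(links, n_src, n_tgt):
    """Per-token crossing sums by explicit enumeration over link pairs.

    Two links cross when their source order is inverted on the target side.
    Returns (source_counts, target_counts) with None for unaligned tokens.
    """
    links = sorted(set(map(tuple, links)))
    src = [None] * n_src
    tgt = [None] * n_tgt
    for i, j in links:
        src[i] = 0 if src[i] is None else src[i]
        tgt[j] = 0 if tgt[j] is None else tgt[j]
    for (i1, j1), (i2, j2) in combinations(links, 2):
        inverted = (i1 < i2 and j1 > j2) or (i1 > i2 and j1 < j2)
        if inverted:
            src[i1] += 1
            src[i2] += 1
            tgt[j1] += 1
            tgt[j2] += 1
    return src, tgt


def _postorder(tree):
    order = []

    def walk(node):
        for c in node.children:
            walk(c)
        order.append(node.token_index)

    walk(tree.root)
    return {tok: rank for rank, tok in enumerate(order)}


def _ancestors(tree):
    anc = {}
    for node in tree.nodes:
        chain = set()
        cur = node.head_index
        while cur is not None:
            chain.add(cur)
            cur = tree.nodes[cur].head_index
        anc[node.token_index] = chain
    return anc


def brute_force_ted(a, b):
    """Minimal ordered-tree edit cost by exhaustive search over valid mappings.

    A mapping is a partial one-to-one pairing of a-nodes with b-nodes that
    preserves postorder and ancestry on both sides. Its cost is
    (#renamed pairs) + (#unmapped a-nodes) + (#unmapped b-nodes).
    Feasible only for tiny trees; used as the ground truth for the dynamic
    program. ``a`` and ``b`` are RelabeledTrees.
    """
    po_a, po_b = _postorder(a.tree), _postorder(b.tree)
    anc_a, anc_b = _ancestors(a.tree), _ancestors(b.tree)
    a_nodes = [n.token_index for n in a.tree.nodes]
    b_nodes = [n.token_index for n in b.tree.nodes]
    best = len(a_nodes) + len(b_nodes)  # delete all, insert all

    def consistent(pairs, na, nb):
        for pa, pb in pairs:
            if (po_a[pa] < po_a[na]) != (po_b[pb] < po_b[nb]):
                return False
            if (pa in anc_a[na]) != (pb in anc_b[nb]):
                return False
            if (na in anc_a[pa]) != (nb in anc_b[pb]):
                return False
        return True

    def search(idx, pairs, used_b):
        nonlocal best
        if idx == len(a_nodes):
            cost = (
                sum(
                    1
                    for pa, pb in pairs
                    if a.match_labels[pa] != b.match_labels[pb]
                )
                + (len(a_nodes) - len(pairs))
                + (len(b_nodes) - len(pairs))
            )
            best = min(best, cost)
            return
        na = a_nodes[idx]
        search(idx + 1, pairs, used_b)  # leave na unmapped (deletion)
        for nb in b_nodes:
            if nb in used_b:
                continue
            if consistent(pairs, na, nb):
                search(idx + 1, pairs + [(na, nb)], used_b | {nb})

    search(0, [], frozenset())
    return best
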