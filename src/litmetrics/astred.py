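"""Aligned Syntactic Tree Edit Distance (ASTrED) over Universal Dependencies.

A source sentence and its translation are parsed into UD dependency trees.
A naive tree edit distance between them would happily match nodes that merely
share a dependency label, ignoring which words actually translate which.
ASTrED therefore relabels both trees first so that *only aligned words can
match*: every node of an aligned word carries its alignment group's
identifier (shared across the two trees), while unaligned words get
side-prefixed labels that can never match anything in the other tree. The
ordered tree edit distance is then computed with unit costs — match 0,
rename 1, delete 1, insert 1 — so the optimal script matches aligned words
wherever the tree structures allow and edits the rest.

Per-source-word output: ``astred_change`` is False when the word's node is a
match in the optimal script and True when an edit operation (rename or
delete; insertion only ever applies to target-tree nodes) touches it.

The edit distance is the classic ordered-tree edit distance (the
Zhang–Shasha cost model) implemented as a memoized forest edit distance with
full backtracking, so the per-node operations — not just the total cost —
are recovered. Ties between equal-cost scripts are broken deterministically:
pairing (match/rename) is preferred over deletion, deletion over insertion,
resolved right-to-left over the forest sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, TextIO

from .alignments import AlignmentLink, SentencePair, Token
from .entropy import alignment_components


class ConlluError(ValueError):
    """Ill-formed CoNLL-U input (cycles, multiple roots, bad columns)."""


@dataclass
class DepNode:
    """One word in a dependency tree (0-based sentence position)."""

    token_index: int
    form: str
    deprel: str
    head_index: Optional[int]  # None marks the root
    children: list["DepNode"] = field(default_factory=list)


@dataclass
class DepTree:
    """A single-rooted ordered dependency tree covering one sentence.

    ``nodes`` is indexed by token position; children are ordered by token
    index, so sibling order equals word order.
    """

    nodes: list[DepNode]
    root: DepNode
    sent_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_heads(
        cls,
        heads: Iterable[int],
        deprels: Iterable[str] | None = None,
        forms: Iterable[str] | None = None,
        sent_id: Optional[str] = None,
    ) -> "DepTree":
        """Build a tree from 1-based head indices (0 = root), CoNLL-U style."""
        heads = list(heads)
        n = len(heads)
        deprels = list(deprels) if deprels is not None else ["dep"] * n
        forms = list(forms) if forms is not None else [f"w{i}" for i in range(n)]
        nodes = [
            DepNode(i, forms[i], deprels[i], heads[i] - 1 if heads[i] > 0 else None)
            for i in range(n)
        ]
        roots = [nd for nd in nodes if nd.head_index is None]
        if len(roots) != 1:
            raise ConlluError(
                f"sentence {sent_id or '?'}: expected exactly one root, found {len(roots)}"
            )
        for nd in nodes:
            if nd.head_index is not None:
                if not 0 <= nd.head_index < n:
                    raise ConlluError(
                        f"sentence {sent_id or '?'}: head of token {nd.token_index} out of range"
                    )
                nodes[nd.head_index].children.append(nd)
        for nd in nodes:
            nd.children.sort(key=lambda c: c.token_index)
        # reachability check rejects cycles hanging off the tree
        seen: set[int] = set()
        stack = [roots[0]]
        while stack:
            nd = stack.pop()
            if nd.token_index in seen:
                raise ConlluError(f"sentence {sent_id or '?'}: cycle detected")
            seen.add(nd.token_index)
            stack.extend(nd.children)
        if len(seen) != n:
            raise ConlluError(
                f"sentence {sent_id or '?'}: {n - len(seen)} token(s) unreachable from root (cycle)"
            )
        return cls(nodes, roots[0], sent_id)


def read_conllu(stream: TextIO | str) -> list[DepTree]:
    """Read dependency trees from CoNLL-U text (UD v2 conventions).

    Multiword-token ranges (``1-2``) and empty nodes (``1.1``) are tolerated
    and skipped — they carry no syntactic head. Token ids are converted to
    0-based positions. Sentences that do not form a single rooted tree raise
    :class:`ConlluError` with the sentence id.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    trees: list[DepTree] = []
    for block in text.strip().split("\n\n"):
        lines = [ln for ln in block.splitlines() if ln.strip()]
        if not lines:
            continue
        sent_id = None
        heads: list[int] = []
        deprels: list[str] = []
        forms: list[str] = []
        for ln in lines:
            if ln.startswith("#"):
                if ln[1:].strip().startswith("sent_id"):
                    sent_id = ln.split("=", 1)[-1].strip()
                continue
            cols = ln.split("\t")
            if len(cols) < 8:
                raise ConlluError(f"sentence {sent_id or '?'}: line has {len(cols)} columns: {ln!r}")
            tid = cols[0]
            if "-" in tid or "." in tid:  # multiword range / empty node
                continue
            try:
                head = int(cols[6])
            except ValueError:
                raise ConlluError(
                    f"sentence {sent_id or '?'}: non-integer head {cols[6]!r}"
                ) from None
            forms.append(cols[1])
            heads.append(head)
            deprels.append(cols[7])
        if heads:
            trees.append(DepTree.from_heads(heads, deprels, forms, sent_id))
    return trees


# ---------------------------------------------------------------------------
# label merging


@dataclass
class RelabeledTree:
    """A dependency tree whose nodes carry alignment-aware match labels."""

    tree: DepTree
    match_labels: dict[int, str]  # token index -> label


def merge_labels(
    src_tree: DepTree,
    tgt_tree: DepTree,
    links: set[AlignmentLink],
) -> tuple[RelabeledTree, RelabeledTree]:
    """Relabel both trees so that only aligned words can match.

    Nodes of aligned words receive their alignment component's identifier
    (identical in both trees); unaligned nodes receive side-prefixed labels
    unique to their token, which by construction never match across trees.
    """
    links = {AlignmentLink(s, t) for s, t in links}
    pair = SentencePair(
        source=[Token(n.token_index, n.form) for n in src_tree.nodes],
        target=[Token(n.token_index, n.form) for n in tgt_tree.nodes],
        links=links,
    )
    for link in links:
        if link.src >= len(src_tree) or link.tgt >= len(tgt_tree):
            raise ValueError(
                f"link {link.src}-{link.tgt} references a token absent from a tree"
            )
    src_labels: dict[int, str] = {}
    tgt_labels: dict[int, str] = {}
    for cid, comp in enumerate(alignment_components(pair)):
        label = f"C{cid}"
        for i in comp.src_indices:
            src_labels[i] = label
        for j in comp.tgt_indices:
            tgt_labels[j] = label
    for nd in src_tree.nodes:
        src_labels.setdefault(nd.token_index, f"S{nd.token_index}")
    for nd in tgt_tree.nodes:
        tgt_labels.setdefault(nd.token_index, f"T{nd.token_index}")
    return RelabeledTree(src_tree, src_labels), RelabeledTree(tgt_tree, tgt_labels)


# ---------------------------------------------------------------------------
# ordered tree edit distance with edit-script recovery


@dataclass(frozen=True)
class EditOp:
    """One operation of an edit script.

    ``op`` ∈ {match, rename, delete, insert}; ``src``/``tgt`` are token
    indices in their trees (``None`` for the side an insert/delete lacks).
    """

    op: str
    src: Optional[int]
    tgt: Optional[int]


@dataclass
class EditScript:
    ops: list[EditOp]
    total_cost: int

    def op_for_src(self, token_index: int) -> Optional[EditOp]:
        for op in self.ops:
            if op.src == token_index:
                return op
        return None


def tree_edit_distance(a: RelabeledTree, b: RelabeledTree) -> EditScript:
    """Minimal-cost ordered tree edit script from tree ``a`` to tree ``b``.

    Costs: match 0, rename 1, delete 1, insert 1. Deletions apply to
    ``a``-side (source) nodes only, insertions to ``b``-side (target) nodes
    only. Implemented as a memoized forest edit distance over root sequences;
    the reachable subforest set is polynomial, and sentence-sized trees stay
    tiny, so this is exact and fast. Deterministic tie-break: pairing is
    preferred over deletion over insertion.
    """
    la, lb = a.match_labels, b.match_labels

    @lru_cache(maxsize=None)
    def dist(fa: tuple, fb: tuple) -> int:
        # fa, fb: tuples of DepNode ids into their trees' node lists
        if not fa and not fb:
            return 0
        if not fa:
            v = b.tree.nodes[fb[-1]]
            return dist((), fb[:-1] + tuple(c.token_index for c in v.children)) + 1
        if not fb:
            v = a.tree.nodes[fa[-1]]
            return dist(fa[:-1] + tuple(c.token_index for c in v.children), ()) + 1
        v = a.tree.nodes[fa[-1]]
        w = b.tree.nodes[fb[-1]]
        vc = tuple(c.token_index for c in v.children)
        wc = tuple(c.token_index for c in w.children)
        pair_cost = (
            dist(fa[:-1], fb[:-1])
            + dist(vc, wc)
            + (0 if la[v.token_index] == lb[w.token_index] else 1)
        )
        del_cost = dist(fa[:-1] + vc, fb) + 1
        ins_cost = dist(fa, fb[:-1] + wc) + 1
        return min(pair_cost, del_cost, ins_cost)

    ops: list[EditOp] = []

    def backtrack(fa: tuple, fb: tuple) -> None:
        if not fa and not fb:
            return
        if not fa:
            v = b.tree.nodes[fb[-1]]
            ops.append(EditOp("insert", None, v.token_index))
            backtrack((), fb[:-1] + tuple(c.token_index for c in v.children))
            return
        if not fb:
            v = a.tree.nodes[fa[-1]]
            ops.append(EditOp("delete", v.token_index, None))
            backtrack(fa[:-1] + tuple(c.token_index for c in v.children), ())
            return
        v = a.tree.nodes[fa[-1]]
        w = b.tree.nodes[fb[-1]]
        vc = tuple(c.token_index for c in v.children)
        wc = tuple(c.token_index for c in w.children)
        total = dist(fa, fb)
        same = la[v.token_index] == lb[w.token_index]
        pair_cost = dist(fa[:-1], fb[:-1]) + dist(vc, wc) + (0 if same else 1)
        if pair_cost == total:
            ops.append(EditOp("match" if same else "rename", v.token_index, w.token_index))
            backtrack(vc, wc)
            backtrack(fa[:-1], fb[:-1])
            return
        if dist(fa[:-1] + vc, fb) + 1 == total:
            ops.append(EditOp("delete", v.token_index, None))
            backtrack(fa[:-1] + vc, fb)
            return
        ops.append(EditOp("insert", None, w.token_index))
        backtrack(fa, fb[:-1] + wc)

    root_a = (a.tree.root.token_index,)
    root_b = (b.tree.root.token_index,)
    total = dist(root_a, root_b)
    backtrack(root_a, root_b)
    ops.sort(key=lambda o: (o.src if o.src is not None else -1, o.tgt if o.tgt is not None else -1))
    script = EditScript(ops, total)
    assert sum(1 for o in ops if o.op != "match") == total
    return script


def astred_change(
    pair: SentencePair,
    src_tree: DepTree,
    tgt_tree: DepTree,
) -> dict[int, bool]:
    """Per-source-token change flags from the optimal aligned edit script.

    False = the word's node is a match (its aligned counterpart sits in a
    structurally compatible position); True = the node had to be renamed or
    deleted. Returns a map over all source token indices.
    """
    if len(src_tree) != pair.n_src or len(tgt_tree) != pair.n_tgt:
        raise ValueError("trees do not cover the pair's token sequences")
    ra, rb = merge_labels(src_tree, tgt_tree, pair.links)
    script = tree_edit_distance(ra, rb)
    flags: dict[int, bool] = {}
    for op in script.ops:
        if op.src is not None:
            flags[op.src] = op.op != "match"
    return flags
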