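"""Word-order distortion metrics on a single aligned sentence pair.

Three related metrics quantify how far a translation departs from the source
word order:

``Cross``
    Signed relative reordering of a word's translation with respect to the
    previous word's translation. In a perfectly literal translation (monotone,
    one-to-one) every word has Cross = 1: each translation sits one step past
    the previous one. Positive values mean the translation is placed after the
    previous word's translation, negative values before it.

``word_cross``
    The number of times a word's alignment links cross the alignment link of
    any other word in the pair. Two links (i, j) and (i', j') cross when the
    source order is inverted on the target side, i.e. (i - i')·(j - j') < 0.
    A word with several links sums the crossing counts of its links.

``seq_cross``
    The same crossing count computed between *word groups* rather than words.
    Aligned groups of consecutive tokens collapse their internal links into a
    single group-level link, so an m-to-n block that would generate m·n
    crossings against an outside link generates only one. Every member word
    inherits its group's value.

Group construction: a candidate group is a contiguous source span paired with
a contiguous target span such that (a) no member aligns outside the group,
(b) every member token is aligned, and (c) the internal alignment is monotone
one-to-one, or — the multi-word-group (MWG) alternative — fully bipartite
(every source member aligned to every target member). Groups are grown
greedily left to right, preferring larger source spans, so output is
deterministic. Aligned words that fit no group become singletons carrying
their original word links.

Unaligned tokens have no reordering value: every metric yields ``None`` for
them, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

from .alignments import AlignmentLink, SentencePair


@dataclass(frozen=True)
class CrossRecord:
    """Per-source-token signed Cross value; ``None`` when unaligned."""

    token_index: int
    cross: Optional[int]

    @property
    def abs_cross(self) -> Optional[int]:
        return None if self.cross is None else abs(self.cross)


@dataclass(frozen=True)
class SequenceGroup:
    """An aligned word group: contiguous source span × contiguous target span.

    ``kind`` is ``"singleton"`` for 1×1 groups and leftover words,
    ``"contiguous"`` for monotone one-to-one blocks larger than 1×1, and
    ``"mwg"`` for full-bipartite multi-word groups. ``group_links`` are the
    word-level links the group carries: all internal links for proper groups,
    the word's original links for leftover singletons.
    """

    src_span: tuple[int, ...]
    tgt_span: tuple[int, ...]
    kind: Literal["singleton", "contiguous", "mwg"]
    group_links: frozenset[AlignmentLink]
    proper: bool = True
    """True for groups that satisfy the group requirements (and hence own
    their target span exclusively); False for leftover singletons, whose
    tgt_span lists their aligned target indices, possibly shared or gapped."""


def count_link_crossings(links: Iterable[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Crossing count per link by direct O(L²) pair enumeration.

    Links (i, j) and (i', j') cross iff (i - i')·(j - j') < 0. L is small in
    sentence-pair work, so the quadratic definition is used verbatim for
    auditability.
    """
    link_list = sorted(set(tuple(l) for l in links))
    counts = {l: 0 for l in link_list}
    for a in range(len(link_list)):
        i, j = link_list[a]
        for b in range(a + 1, len(link_list)):
            i2, j2 = link_list[b]
            if (i - i2) * (j - j2) < 0:
                counts[(i, j)] += 1
                counts[(i2, j2)] += 1
    return counts


def cross_values(pair: SentencePair) -> list[CrossRecord]:
    """Signed Cross per source token, left to right.

    For each aligned source token let t be the 1-based index of its leftmost
    aligned target token; Cross = t − p where p is that quantity for the
    previous *aligned* source token (p = 0 before the first). Unaligned
    tokens yield ``None`` and are skipped by the pointer.
    """
    records: list[CrossRecord] = []
    prev = 0
    for tok in pair.source:
        tgts = pair.targets_of(tok.index)
        if not tgts:
            records.append(CrossRecord(tok.index, None))
            continue
        t = tgts[0] + 1
        records.append(CrossRecord(tok.index, t - prev))
        prev = t
    return records


def _per_token_crossings(
    links: Iterable[AlignmentLink], n_src: int, n_tgt: int
) -> tuple[list[Optional[int]], list[Optional[int]]]:
    """Sum link crossing counts onto the incident source and target tokens."""
    counts = count_link_crossings(links)
    src: list[Optional[int]] = [None] * n_src
    tgt: list[Optional[int]] = [None] * n_tgt
    for (i, j), c in counts.items():
        src[i] = (src[i] or 0) + c
        tgt[j] = (tgt[j] or 0) + c
    return src, tgt


def word_cross(pair: SentencePair, side: str = "source") -> list[Optional[int]]:
    """Per-token crossing counts over word-alignment links.

    A token's value is the sum over its incident links of each link's
    crossing count; unaligned tokens get ``None``. ``side`` selects the
    source or target sentence (the counts can differ under one-to-many
    alignments because a multiply-aligned token sums several links).
    """
    src, tgt = _per_token_crossings(pair.links, pair.n_src, pair.n_tgt)
    if side == "source":
        return src
    if side == "target":
        return tgt
    raise ValueError(f"side must be 'source' or 'target', got {side!r}")


def _span_is_valid_group(
    pair: SentencePair, src_span: range, tgt_span: range
) -> Optional[str]:
    """Return the group kind if (src_span, tgt_span) is a valid aligned group.

    Validity: phrase consistency (no member aligns outside the group), every
    member aligned, and internally monotone one-to-one OR fully bipartite
    (the MWG exemption). Returns ``None`` when invalid.
    """
    src_set, tgt_set = set(src_span), set(tgt_span)
    internal = {l for l in pair.links if l.src in src_set and l.tgt in tgt_set}
    # consistency + full alignment: each member's links exist and stay inside
    for i in src_set:
        tgts = pair.targets_of(i)
        if not tgts or not set(tgts) <= tgt_set:
            return None
    for j in tgt_set:
        srcs = pair.sources_of(j)
        if not srcs or not set(srcs) <= src_set:
            return None
    m, n = len(src_set), len(tgt_set)
    if m == n and len(internal) == n:
        # candidate monotone one-to-one: k-th source token to k-th target token
        if internal == {
            AlignmentLink(s, t) for s, t in zip(sorted(src_set), sorted(tgt_set))
        }:
            return "singleton" if m == 1 else "contiguous"
    if len(internal) == m * n:
        return "mwg" if m * n > 1 else "singleton"
    return None


def build_sequence_groups(pair: SentencePair) -> list[SequenceGroup]:
    """Partition the aligned tokens into maximal aligned word groups.

    Greedy left-to-right growth preferring larger source spans; the target
    span of a candidate is the convex hull of the source span's alignments.
    Aligned tokens that fit no valid group become singletons carrying their
    original word links. Output is ordered by source span start.
    """
    used_src: set[int] = set()
    used_tgt: set[int] = set()
    groups: list[SequenceGroup] = []
    aligned_src = pair.aligned_src()

    for start in range(pair.n_src):
        if start in used_src or start not in aligned_src:
            continue
        chosen: Optional[SequenceGroup] = None
        # largest source span first; stop growing at an already-grouped token
        max_end = start
        while max_end + 1 < pair.n_src and max_end + 1 not in used_src:
            max_end += 1
        for end in range(max_end, start - 1, -1):
            src_span = range(start, end + 1)
            tgts = sorted(
                {l.tgt for l in pair.links if l.src in set(src_span)}
            )
            if not tgts:
                continue
            tgt_span = range(tgts[0], tgts[-1] + 1)
            if any(j in used_tgt for j in tgt_span):
                continue
            kind = _span_is_valid_group(pair, src_span, tgt_span)
            if kind is not None:
                internal = frozenset(
                    l for l in pair.links if l.src in set(src_span) and l.tgt in set(tgt_span)
                )
                chosen = SequenceGroup(
                    tuple(src_span), tuple(tgt_span), kind, internal
                )
                break
        if chosen is not None:
            # a valid group owns its target span exclusively
            used_tgt.update(chosen.tgt_span)
        else:
            # leftover word: its own singleton sequence alignment, carrying
            # its word links; tgt_span here lists the aligned target indices
            # (shared, possibly non-contiguous)
            chosen = SequenceGroup(
                (start,),
                tuple(pair.targets_of(start)),
                "singleton",
                frozenset(l for l in pair.links if l.src == start),
                proper=False,
            )
        groups.append(chosen)
        used_src.update(chosen.src_span)
    return groups


def group_level_links(pair: SentencePair, groups: Optional[list[SequenceGroup]] = None):
    """Collapse word links to one link per proper group; singletons keep theirs.

    Source-side units are groups ordered by leftmost source index, target-side
    units by leftmost target index. A proper group (consistent on both sides)
    contributes a single (unit, unit) link; a leftover singleton contributes
    one link per original word link, routed to the unit containing the target
    token. Returns ``(links, src_unit_of_token, tgt_unit_of_token, groups)``.
    """
    if groups is None:
        groups = build_sequence_groups(pair)
    src_order = sorted(range(len(groups)), key=lambda g: groups[g].src_span[0])
    src_rank = {g: r for r, g in enumerate(src_order)}

    # target units: proper groups own their target span; leftover target
    # tokens (aligned but in no group's covered span) are their own unit
    covered: dict[int, int] = {}
    for g_id, g in enumerate(groups):
        if g.proper:
            for j in g.tgt_span:
                covered[j] = g_id
    units: dict[object, int] = {}  # unit key -> leftmost target index
    for j in sorted(pair.aligned_tgt()):
        key = ("g", covered[j]) if j in covered else ("t", j)
        units.setdefault(key, j)
    tgt_rank = {key: r for r, (key, _) in enumerate(sorted(units.items(), key=lambda kv: kv[1]))}

    links: set[AlignmentLink] = set()
    src_unit_of: dict[int, int] = {}
    tgt_unit_of_tok: dict[int, int] = {
        j: tgt_rank[("g", covered[j]) if j in covered else ("t", j)]
        for j in pair.aligned_tgt()
    }
    for g_id, g in enumerate(groups):
        r = src_rank[g_id]
        for i in g.src_span:
            src_unit_of[i] = r
        if ("g", g_id) in tgt_rank:
            links.add(AlignmentLink(r, tgt_rank[("g", g_id)]))
        else:
            for l in g.group_links:
                links.add(AlignmentLink(r, tgt_unit_of_tok[l.tgt]))
    return links, src_unit_of, tgt_unit_of_tok, groups


def seq_cross(pair: SentencePair, side: str = "source") -> list[Optional[int]]:
    """Per-token group-level crossing counts.

    Crossings are counted among group-level links exactly as in
    :func:`word_cross`; every member word inherits its group's value.
    Unaligned words yield ``None``.
    """
    links, src_unit_of, tgt_unit_of, _ = group_level_links(pair)
    counts = count_link_crossings(links)
    unit_src: dict[int, int] = {}
    unit_tgt: dict[int, int] = {}
    for (u, v), c in counts.items():
        unit_src[u] = unit_src.get(u, 0) + c
        unit_tgt[v] = unit_tgt.get(v, 0) + c
    if side == "source":
        return [
            unit_src.get(src_unit_of[i], 0) if i in src_unit_of else None
            for i in range(pair.n_src)
        ]
    if side == "target":
        return [
            unit_tgt.get(tgt_unit_of[j], 0) if j in tgt_unit_of else None
            for j in range(pair.n_tgt)
        ]
    raise ValueError(f"side must be 'source' or 'target', got {side!r}")
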