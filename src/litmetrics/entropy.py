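"""Entropy metrics over ensembles of alternative translations.

When several translators render the same source sentence, the variation in
their choices measures how pre-determined a source word's translation is.
Shannon entropy H(X) = −Σ p(x)·log2 p(x) (in bits) over per-version events
quantifies that agreement: 0 bits when all versions agree, up to
log2(#versions) when every version differs.

Three event families are implemented, all keyed per source token occurrence:

``HTra``   — lexical choice: the (normalized) string of target tokens the
             source token is aligned to in each version.
``HCross`` — reordering choice: the token's signed Cross value in each version.
``HSTC``   — joint source-target alignment/translation distortion: the triplet
             (source group, target group, group Cross) of the token's
             alignment group, where a group is a connected component of the
             bipartite alignment graph. HSTC subsumes both lexical and
             reordering variation in a single measure.

Probabilities are relative frequencies over the available versions, with no
smoothing. Versions in which the token is unaligned are dropped from that
token's distribution by default (``include_unaligned`` adds them as a
distinct null event instead); a token unaligned in every version has no
distribution and yields ``None``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Optional

import networkx as nx

from .alignments import SentencePair, Token
from .reordering import cross_values

#: event used for versions that leave the token untranslated, when requested
UNALIGNED_EVENT = ("<unaligned>",)


@dataclass
class EventDistribution:
    """Empirical distribution over opaque events (counts, not probabilities)."""

    counts: Counter = field(default_factory=Counter)

    @classmethod
    def from_events(cls, events) -> "EventDistribution":
        return cls(Counter(events))

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class StcTriplet:
    """(source group, target group, group Cross) — one HSTC event.

    ``s`` and ``t`` are lowercased, space-joined member forms in sentence
    order; ``c`` is the Cross value shared by the whole source group.
    """

    s: str
    t: str
    c: int


@dataclass(frozen=True)
class AlignmentComponent:
    """A connected component of the bipartite alignment graph.

    Every member token is aligned; by construction all source members share
    the component's ``group_cross`` value.
    """

    src_indices: frozenset[int]
    tgt_indices: frozenset[int]
    group_cross: int


@dataclass
class TranslationEnsemble:
    """One source sentence with N aligned translations of it.

    All versions must share the identical source token sequence; at least two
    versions are needed for any entropy to be non-degenerate.
    """

    source: list[Token]
    versions: list[tuple[str, SentencePair]]

    def __post_init__(self) -> None:
        src_forms = [t.form for t in self.source]
        for tid, pair in self.versions:
            if [t.form for t in pair.source] != src_forms:
                raise ValueError(
                    f"version {tid!r} does not share the ensemble's source tokens"
                )

    @property
    def n_versions(self) -> int:
        return len(self.versions)


def entropy_bits(dist: EventDistribution) -> float:
    """Shannon entropy of an empirical distribution, in bits (0·log 0 = 0)."""
    total = dist.total
    if total < 1:
        raise ValueError("entropy of an empty distribution is undefined")
    h = 0.0
    for count in dist.counts.values():
        p = count / total
        h -= p * math.log2(p)
    # clamp the -0.0 a single-event distribution produces
    return abs(h) if h == 0 else h


def normalize_translation(pair: SentencePair, token_index: int) -> Optional[tuple]:
    """The HTra event: aligned target forms, lowercased, in sentence order.

    Returned as a tuple of forms (joined with single spaces for display);
    ``None`` when the token is unaligned in this version.
    """
    tgts = pair.targets_of(token_index)
    if not tgts:
        return None
    return tuple(pair.target[j].form.strip().lower() for j in tgts)


def _collect(
    ensemble: TranslationEnsemble,
    token_index: int,
    event_fn,
    include_unaligned: bool,
) -> Optional[EventDistribution]:
    if not 0 <= token_index < len(ensemble.source):
        raise IndexError(f"token index {token_index} out of range")
    events: list[Hashable] = []
    for _, pair in ensemble.versions:
        ev = event_fn(pair)
        if ev is None:
            if include_unaligned:
                events.append(UNALIGNED_EVENT)
            continue
        events.append(ev)
    if not events:
        return None
    return EventDistribution.from_events(events)


def htra(
    ensemble: TranslationEnsemble,
    token_index: int,
    include_unaligned: bool = False,
) -> Optional[float]:
    """Word translation entropy (bits) of a source token across versions."""
    dist = _collect(
        ensemble,
        token_index,
        lambda pair: normalize_translation(pair, token_index),
        include_unaligned,
    )
    return None if dist is None else entropy_bits(dist)


def hcross(
    ensemble: TranslationEnsemble,
    token_index: int,
    include_unaligned: bool = False,
) -> Optional[float]:
    """Entropy (bits) of a source token's signed Cross values across versions."""

    def event(pair: SentencePair):
        return cross_values(pair)[token_index].cross

    dist = _collect(ensemble, token_index, event, include_unaligned)
    return None if dist is None else entropy_bits(dist)


def alignment_components(pair: SentencePair) -> list[AlignmentComponent]:
    """Connected components of the bipartite alignment graph, with group Cross.

    Components are ordered by leftmost source index. The group Cross value
    applies the word-level Cross pointer convention to the component
    sequence: a component's target position is the 1-based rank of its
    leftmost target index, and its Cross is that rank minus the previous
    component's rank (0 before the first).
    """
    graph = nx.Graph()
    for link in pair.links:
        graph.add_edge(("s", link.src), ("t", link.tgt))
    comps = []
    for nodes in nx.connected_components(graph):
        src = frozenset(i for side, i in nodes if side == "s")
        tgt = frozenset(j for side, j in nodes if side == "t")
        comps.append((src, tgt))
    comps.sort(key=lambda st: min(st[0]))
    tgt_rank = {
        c: r + 1
        for r, c in enumerate(sorted(range(len(comps)), key=lambda c: min(comps[c][1])))
    }
    out: list[AlignmentComponent] = []
    prev = 0
    for c, (src, tgt) in enumerate(comps):
        t = tgt_rank[c]
        out.append(AlignmentComponent(src, tgt, t - prev))
        prev = t
    return out


def stc_triplet(pair: SentencePair, token_index: int) -> Optional[StcTriplet]:
    """The (s, t, c) alignment-group triplet of a source token in one version."""
    for comp in alignment_components(pair):
        if token_index in comp.src_indices:
            s = " ".join(pair.source[i].form.strip().lower() for i in sorted(comp.src_indices))
            t = " ".join(pair.target[j].form.strip().lower() for j in sorted(comp.tgt_indices))
            return StcTriplet(s, t, comp.group_cross)
    return None


def hstc(
    ensemble: TranslationEnsemble,
    token_index: int,
    include_unaligned: bool = False,
) -> Optional[float]:
    """Joint source-target alignment/translation distortion entropy (bits)."""
    dist = _collect(
        ensemble,
        token_index,
        lambda pair: stc_triplet(pair, token_index),
        include_unaligned,
    )
    return None if dist is None else entropy_bits(dist)
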