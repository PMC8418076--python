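"""Tokenized, word-aligned sentence pairs and Pharaoh alignment I/O.

The sentence pair is the substrate of every product metric in this package:
a tokenized source sentence, a tokenized target sentence, and a set of
word-alignment links between them. A link connects one source token to one
target token; tokens may be unaligned (no link at all) or aligned to several
tokens on the other side. Alignments are consumed, never produced — the
package assumes manually or automatically word-aligned input.

Indexing is 0-based everywhere, including the Pharaoh ``i-j`` text format.
Any 1-based external table column must be converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple


class PharaohFormatError(ValueError):
    """Malformed or out-of-range Pharaoh alignment text."""


class AlignmentLink(NamedTuple):
    """A single word-alignment link: source token index -> target token index."""

    src: int
    tgt: int


@dataclass(frozen=True)
class Token:
    """A surface token at a fixed 0-based position in its sentence."""

    index: int
    form: str


@dataclass
class SentencePair:
    """A word-aligned source/target sentence pair.

    Parameters
    ----------
    source, target:
        Ordered token lists. Convenience constructor :meth:`from_strings`
        accepts plain string lists.
    links:
        Set of :class:`AlignmentLink`. Unaligned tokens are simply absent
        from the link set; no sentinel indices are used.
    """

    source: list[Token]
    target: list[Token]
    links: set[AlignmentLink] = field(default_factory=set)

    @classmethod
    def from_strings(
        cls,
        source: Iterable[str],
        target: Iterable[str],
        links: Iterable[tuple[int, int]] = (),
    ) -> "SentencePair":
        return cls(
            source=[Token(i, f) for i, f in enumerate(source)],
            target=[Token(i, f) for i, f in enumerate(target)],
            links={AlignmentLink(int(s), int(t)) for s, t in links},
        )

    @property
    def n_src(self) -> int:
        return len(self.source)

    @property
    def n_tgt(self) -> int:
        return len(self.target)

    def aligned_src(self) -> set[int]:
        """Indices of source tokens carrying at least one link."""
        return {l.src for l in self.links}

    def aligned_tgt(self) -> set[int]:
        return {l.tgt for l in self.links}

    def targets_of(self, src_index: int) -> list[int]:
        """Sorted target indices aligned to a source token (possibly empty)."""
        return sorted(l.tgt for l in self.links if l.src == src_index)

    def sources_of(self, tgt_index: int) -> list[int]:
        return sorted(l.src for l in self.links if l.tgt == tgt_index)


def parse_pharaoh(text: str, n_src: int, n_tgt: int) -> set[AlignmentLink]:
    """Parse whitespace-separated ``i-j`` alignment pairs (0-based).

    Duplicates collapse (links form a set); the empty string is a legal,
    empty alignment. Raises :class:`PharaohFormatError` naming the offending
    pair on malformed input or an index outside ``[0, n_src)`` / ``[0, n_tgt)``.
    """
    links: set[AlignmentLink] = set()
    for chunk in text.split():
        left, sep, right = chunk.partition("-")
        if not sep:
            raise PharaohFormatError(f"alignment pair {chunk!r} has no '-' separator")
        try:
            src, tgt = int(left), int(right)
        except ValueError:
            raise PharaohFormatError(f"alignment pair {chunk!r} is not integer-integer") from None
        if src < 0 or tgt < 0:
            raise PharaohFormatError(f"alignment pair {chunk!r} has a negative index")
        if src >= n_src:
            raise PharaohFormatError(
                f"alignment pair {chunk!r}: source index {src} out of range for {n_src} tokens"
            )
        if tgt >= n_tgt:
            raise PharaohFormatError(
                f"alignment pair {chunk!r}: target index {tgt} out of range for {n_tgt} tokens"
            )
        links.add(AlignmentLink(src, tgt))
    return links


def serialize_pharaoh(links: Iterable[AlignmentLink | tuple[int, int]]) -> str:
    """Canonical Pharaoh text: sorted, deduplicated ``i-j`` pairs."""
    return " ".join(f"{s}-{t}" for s, t in sorted(set(tuple(l) for l in links)))


def validate_pair(pair: SentencePair) -> list[str]:
    """Check pair invariants; return one human-readable diagnostic per violation.

    An empty list means the pair is valid. Checks: token indices consecutive
    from 0, non-empty token forms, link endpoints in range. Diagnostics are
    returned rather than raised so callers can batch-validate tables.
    """
    diagnostics: list[str] = []
    for side, tokens in (("source", pair.source), ("target", pair.target)):
        for pos, tok in enumerate(tokens):
            if tok.index != pos:
                diagnostics.append(
                    f"{side} token at position {pos} has index {tok.index} (expected {pos})"
                )
            if not tok.form:
                diagnostics.append(f"{side} token at position {pos} has an empty form")
    for link in sorted(pair.links):
        if not (0 <= link.src < pair.n_src):
            diagnostics.append(
                f"link {link.src}-{link.tgt}: source index out of range (sentence has {pair.n_src} tokens)"
            )
        if not (0 <= link.tgt < pair.n_tgt):
            diagnostics.append(
                f"link {link.src}-{link.tgt}: target index out of range (sentence has {pair.n_tgt} tokens)"
            )
    return diagnostics
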