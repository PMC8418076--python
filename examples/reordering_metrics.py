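"""Crossing-based reordering metrics on one aligned sentence pair.

Builds the multi-word-group showcase pair — English "called marine
sentinels" against Dutch "wachters van de zee genoemd", where the two-word
phrase is fully bipartitely aligned (2×4 = 8 word links) to the four-word
phrase — and prints the three reordering metrics per source token.
"""

from litmetrics import (
    SentencePair,
    build_sequence_groups,
    cross_values,
    seq_cross,
    word_cross,
)

pair = SentencePair.from_strings(
    ["called", "marine", "sentinels"],
    ["wachters", "van", "de", "zee", "genoemd"],
    [(0, 4)] + [(i, j) for i in (1, 2) for j in range(4)],
)

crosses = cross_values(pair)
wc = word_cross(pair)
sc = seq_cross(pair)

print(f"{'token':<12}{'Cross':>6}{'word_cross':>12}{'seq_cross':>11}")
for tok in pair.source:
    print(f"{tok.form:<12}{crosses[tok.index].cross:>6}{wc[tok.index]:>12}{sc[tok.index]:>11}")

print()
for g in build_sequence_groups(pair):
    src = " ".join(pair.source[i].form for i in g.src_span)
    tgt = " ".join(pair.target[j].form for j in g.tgt_span)
    print(f"group [{g.kind}]: '{src}' <-> '{tgt}'")

print(
    "\nThe 'called'-'genoemd' link crosses all 8 bipartite word links "
    "(word_cross = 8), but once the 2x4 block collapses into one multi-word "
    "group with a single group-level link, only that one link is crossed "
    "(seq_cross = 1)."
)
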