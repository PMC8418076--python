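"""Aligned syntactic tree edit distance and per-word change flags.

Parses a tiny English/Dutch pair from CoNLL-U, aligns it word by word minus
one untranslated adverb, and shows which source words survive as matches in
the optimal aligned edit script.
"""

from litmetrics import SentencePair, astred_change, read_conllu

SRC_CONLLU = """# sent_id = en-1
1\tThe\tthe\tDET\tDT\t_\t2\tdet\t_\t_
2\tcat\tcat\tNOUN\tNN\t_\t4\tnsubj\t_\t_
3\tquietly\tquietly\tADV\tRB\t_\t4\tadvmod\t_\t_
4\tsleeps\tsleep\tVERB\tVBZ\t_\t0\troot\t_\t_
"""

TGT_CONLLU = """# sent_id = nl-1
1\tDe\tde\tDET\tLID\t_\t2\tdet\t_\t_
2\tkat\tkat\tNOUN\tN\t_\t3\tnsubj\t_\t_
3\tslaapt\tslapen\tVERB\tWW\t_\t0\troot\t_\t_
"""

src_tree = read_conllu(SRC_CONLLU)[0]
tgt_tree = read_conllu(TGT_CONLLU)[0]

# "quietly" is left untranslated, so it has no alignment link
pair = SentencePair.from_strings(
    ["The", "cat", "quietly", "sleeps"],
    ["De", "kat", "slaapt"],
    [(0, 0), (1, 1), (3, 2)],
)

flags = astred_change(pair, src_tree, tgt_tree)
for tok in pair.source:
    print(f"{tok.form:<10} astred_change = {flags[tok.index]}")

print(
    "\nTRUE marks words whose tree node could not be matched: the unaligned "
    "'quietly' must be edited away, while every aligned word keeps its "
    "structural position across the two dependency trees."
)
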