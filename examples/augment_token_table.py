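"""Augmenting a per-token process table with the product metrics.

Builds a two-translator sentence bundle and a three-row token table in
memory, adds the metric columns, and prints the resulting TSV. The same
operation is available from the shell as
``litmetrics augment --table t.tsv --bundles b.jsonl --out out.tsv``.
"""

import io

from litmetrics import augment_table, read_bundles, read_table, write_table

BUNDLE = (
    '{"text_id": "T1", "sent_id": "1", '
    '"source": ["called", "marine", "sentinels"], '
    '"versions": ['
    '{"translator": "P1", "target": ["wachters", "van", "de", "zee", "genoemd"], '
    '"alignment": "0-4 1-0 1-1 1-2 1-3 2-0 2-1 2-2 2-3"}, '
    '{"translator": "P2", "target": ["zeewachters", "genoemd"], '
    '"alignment": "0-1 1-0 2-0"}]}'
)

TABLE = (
    "participant\ttext_id\tsent_id\tword_id\tSTid\ttoken\n"
    "P1\tT1\t1\t0\t17\tcalled\n"
    "P1\tT1\t1\t1\t18\tmarine\n"
    "P1\tT1\t1\t2\t19\tsentinels\n"
)

bundles = read_bundles(BUNDLE)
table = read_table(io.StringIO(TABLE))
augmented = augment_table(table, bundles)

out = io.StringIO()
write_table(augmented, out)
print(out.getvalue())
print(
    "Pair metrics (cross, word_cross, seq_cross) come from P1's own "
    "translation; the entropy columns (htra, hcross, hstc) pool both "
    "translators, so they are non-zero where P1 and P2 diverge."
)
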