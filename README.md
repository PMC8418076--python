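# litmetrics

Word-level translation (non-)literality metrics for translation process
research.

When translators work, the effort they spend on a source word shows up in
eye-tracking and keystroke data — and much of that effort tracks how
*literal* the translation of that word can be. This package computes, per
source token of a word-aligned sentence pair, the product metrics that
operationalize (non-)literality, together with the reading-time dependent
variables they are usually regressed against. It is meant for researchers
working with TPR-DB-style per-token tables (translation process research
databases) who want these metrics added to their data, and for anyone who
needs crossing-based word-order metrics or multi-translation entropies over
aligned text.

## The metrics

Let a sentence pair consist of source tokens *s₁…sₘ*, target tokens
*t₁…tₙ*, and a set of word-alignment links *(i, j)*.

**Cross** — signed relative reordering. For each aligned source word, let
*t* be the 1-based position of its leftmost aligned target token and *p*
the same quantity for the previous aligned source word (*p* = 0 at the
start); Cross = *t − p*. In a fully literal (monotone one-to-one)
translation every word has Cross = 1. The absolute value |Cross| is the
usual predictor.

**word_cross** — bidirectional absolute reordering. Two links *(i, j)* and
*(i′, j′)* cross iff *(i − i′)(j − j′) < 0*. A word's word_cross is the sum,
over its incident links, of the number of links each one crosses.

**seq_cross** — the same crossing count over *word groups*. Consecutive
source tokens aligned to consecutive target tokens form a group when no
member aligns outside the group, every member is aligned, and the internal
alignment is monotone one-to-one — or, the multi-word-group (MWG)
exemption, fully bipartite (every source member aligned to every target
member). Groups are maximal; each proper group contributes a single
group-level link, words outside any group stay singletons with their word
links, and every member word inherits its group's crossing count.

**HTra, HCross, HSTC** — entropies over *N* alternative translations of the
same source sentence, H(X) = −Σ p(x) log₂ p(x) in bits, with relative
frequencies as probabilities. The per-version event is, respectively: the
normalized target rendering of the word (HTra), its signed Cross value
(HCross), or the triplet (source group, target group, group Cross) of its
alignment group — a connected component of the bipartite alignment graph
(HSTC). 0 bits means all translators agree; log₂ N is maximal disagreement.

**astred_change** — aligned syntactic tree edit distance flags. Both
sentences are parsed into Universal Dependencies trees; node labels are
merged so that only aligned words can match (each aligned word carries its
alignment component's identifier, unaligned words get unmatchable labels),
and the ordered tree edit distance (match 0, rename/delete/insert 1) is
computed. A source word is flagged `TRUE` when the optimal script renames
or deletes its node instead of matching it.

**Process measures** — from token-attributed fixation and keystroke logs:
first fixation duration (FFDur), total reading time (TrtS), eye-key span
(EKS), first-pass duration (FPD) and regression-path duration (RPD), plus
the per-participant ±2.5 SD outlier screen and the log transform used
before mixed-effects modelling.

## Worked example

`python examples/reordering_metrics.py` prints:

```
token        Cross  word_cross  seq_cross
called           5           8          1
marine          -4          10          1
sentinels        0          10          1

group [singleton]: 'called' <-> 'genoemd'
group [mwg]: 'marine sentinels' <-> 'wachters van de zee'
```

English "… called marine sentinels" is translated as Dutch "… wachters van
de zee genoemd": "called" aligns with sentence-final "genoemd", while
"marine sentinels" is aligned as a 2×4 fully bipartite block to "wachters
van de zee". The "called"–"genoemd" link crosses all eight bipartite links,
so word_cross("called") = 8 — but the block qualifies as a multi-word
group carrying a single group-level link, so at the group level "called"
crosses only once: seq_cross("called") = 1. That is exactly the reduction
the sequence metric exists to capture.

The other examples (`translation_entropy.py`, `aligned_tree_distance.py`,
`reading_measures.py`, `augment_token_table.py`) each build a small input,
run one capability and explain the printed numbers.

## Library and command line

Everything is importable from `litmetrics` (see the module docstrings for
the data model). A thin CLI wraps the same functions:

```bash
litmetrics metrics  --pair pair.json            # Cross / word_cross / seq_cross
litmetrics entropy  --bundle sentences.jsonl    # HTra / HCross / HSTC
litmetrics astred   --pair pair.json --src-conllu s.conllu --tgt-conllu t.conllu
litmetrics measures --events log.tsv --n-tokens 12
litmetrics augment  --table tokens.tsv --bundles sentences.jsonl --out out.tsv
litmetrics simulate --seed 7 --kind ensemble
```

Token tables are TSV (UTF-8, header row, `NA` for missing); sentence
bundles are JSON lines, one source sentence per line with all translators'
targets and Pharaoh alignments (`"0-0 1-2"`, 0-based) and optional CoNLL-U
parses. Formats are documented in `litmetrics/tables_io.py` and
`docs/methods.md`.

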