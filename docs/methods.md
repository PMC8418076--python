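# Methods

This note records the modelling conventions, numerical choices and known
limitations behind the metrics. It complements the README's definitions;
nothing here states a result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and conventions

Token indices are 0-based everywhere, including the Pharaoh `i-j` alignment
dialect read and written by the package; 1-based external columns are
converted at the I/O boundary. Alignment links form a set: duplicates
collapse on input and all metrics are invariant under the order in which
links are supplied. Unaligned tokens are represented by the *absence* of
links and receive `None` (TSV `NA`) for every metric — a word without a
translation has no reordering or entropy value, and 0 would be a valid
metric value, not a missing one. Tokenization is taken as given; no
tokenizer or automatic aligner is shipped.

## Cross: pointer convention

The signed Cross value needs three decisions the bare definition leaves
open, fixed here once:

- a multiply-aligned source word uses its **leftmost** aligned target token;
- the reference point is the previous **aligned** source word (unaligned
  words are skipped, not treated as zeros);
- before the first aligned word the reference position is 0.

Under these choices a monotone one-to-one pair yields Cross = 1 for every
word (the literal-translation anchor) and a 2-token full swap yields
[2, −1]. These two anchors pin the convention; it is implemented in exactly
one place (`reordering.cross_values`).

## word_cross and seq_cross

Crossing counts use the O(L²) pair enumeration directly (L = number of
links; sentence pairs keep L small). This is deliberate: the quadratic
definition is auditable line by line, and an interval-tree optimization
would buy nothing at these sizes. A word with several links **sums** its
links' crossing counts, on the target side as well as the source side, so
the two sides of a one-to-many alignment can legitimately differ.

Sequence groups are grown greedily left to right, always preferring the
largest valid source span, with the candidate target span taken as the
convex hull of the span's alignments. Validity means: no member aligns
outside the group, every member token (both sides) is aligned, and the
internal alignment is monotone one-to-one or fully bipartite (the
multi-word-group exemption; complete 1×n and m×1 blocks qualify too, and
1×1 groups are classed as singletons). The greedy-largest rule plus a
deterministic scan order makes the output unique; maximality is probed in
the tests by checking that no proper group can be extended by its right
neighbour except where an earlier group already owns the target span.
Leftover aligned words become singletons carrying their original word
links; at the group level a proper group contributes exactly one link,
while singleton links are routed to the unit containing their target
token. Group-level units are ranked by leftmost index on each side, an
order-preserving reindexing, which is why a pair whose groups are all
singletons gets seq_cross identical to word_cross.

## Entropy family

Probabilities are relative frequencies over the available versions — no
smoothing, matching the conditional "in this context" reading of the
formulas; log base 2, results in bits, so values are bounded by
log₂(number of versions). Events are keyed per source token *occurrence*
(same position in the same sentence), not per word type.

HTra's event normalizes the target rendering: lowercase, outer whitespace
stripped, multi-token renderings joined with single spaces in target
sentence order. Entropy must not split on trivial casing or whitespace
variants; any further normalization (lemmatization, punctuation stripping)
is left to the caller because it would silently change published numbers.
Surface forms, not lemmas, are used in HSTC's group renderings for the
same reason.

HSTC's alignment group is the connected component of the bipartite
alignment graph. The component construction guarantees by itself that all
source words of a group share one group Cross value, computed by applying
the Cross pointer convention to the component sequence (components ordered
by leftmost source index; target position = rank of leftmost target
index).

Versions in which the token is unaligned are dropped from that token's
distribution by default; `include_unaligned=True` instead adds a distinct
null-translation event. Dropping is the default because an untranslated
word says nothing about the *choice between renderings*, but the switch is
exposed since the opposite reading (untranslated as one more option) is
defensible. A token unaligned in every version yields `None`.

## Aligned tree edit distance

The relabeling contract is: nodes of aligned words carry their alignment
component's identifier, identical across the two trees; unaligned nodes
carry side-prefixed labels (`S<i>` / `T<j>`) that cannot match anything.
This realizes the guarantee that only aligned words can match. The
component identifier deliberately ignores the dependency relation — after
relabeling, structure (tree shape and sibling order) plus alignment alone
decide matches, which is the point of the aligned variant. How a published
merging procedure would treat one-to-many alignments spread across
subtrees is not reconstructable from its stated guarantee alone; component
labelling is this package's documented realization of that guarantee.

The distance itself is the ordered tree edit distance under unit costs
(match 0, rename/delete/insert 1), computed by a memoized forest edit
distance over root sequences — the classic Zhang–Shasha cost model — with
full backtracking so the per-node operations are recovered, not just the
total. Deletions can only touch source-tree nodes and insertions only
target-tree nodes, which is why a source word's flag is `TRUE` exactly
when its node is renamed or deleted (the operation kind is retained in the
`EditScript` alongside the boolean). Equal-cost scripts are disambiguated
deterministically: pairing (match/rename) is preferred over deletion over
insertion, resolved right to left over the forest sequence. The dynamic
program is verified against an exhaustive search over all order- and
ancestry-consistent mappings on trees of up to 6 nodes.

CoNLL-U multiword-token ranges and empty nodes are skipped (they carry no
syntactic head); sentences that do not form a single rooted acyclic tree
are rejected with their sentence id, mirroring the practice of restricting
tree-based metrics to cleanly parsed one-sentence translations.

## Process measures

EKS is measured from the **onset** of the first fixation (not its offset):
the span is meant to cover processing from first visual contact to first
production, and the onset is the only timestamp guaranteed present for a
fixation. A contributing keystroke that precedes the first fixation makes
the span negative; such cases are returned as `None` with a diagnostic
rather than as negative durations, since they indicate attribution
artefacts (typing from memory or from context) rather than processing
time.

Outlier exclusion is single-pass: mean and sample SD (ddof = 1) are
computed once per participant from the raw data and points beyond
k·SD (default 2.5) are dropped. The exclusion is intentionally not
iterated — recomputing statistics after each removal is a different, more
aggressive procedure. A zero-variance group keeps all its points. On
standard-normal data the expected loss is the two-sided tail mass beyond
2.5 SD, ≈ 1.24%; the same operation applied to a model-residual column
covers residual-outlier screening, since model fitting itself is out of
scope. Note one counter-intuitive consequence of the rule: in very small
groups a single extreme point inflates the SD enough to keep itself (e.g.
five 1s and one 100 are all kept); that is the formula's behaviour, not a
bug. The log transform uses the natural log — the base only shifts the
scale of regression coefficients — and refuses non-positive input rather
than emitting −inf.

## Table augmentation

Augmentation adds `cross, abs_cross, word_cross, seq_cross, astred_change,
htra, hcross, hstc` to a per-token TSV table. Pair metrics come from the
row's participant's own translation; entropy metrics pool all translators
of the sentence and are therefore constant across participants for a
token. Sentence membership is carried by explicit `text_id`/`sent_id`
columns, never re-derived from punctuation. Missing bundles and
out-of-range `word_id`s are hard errors listing the offending rows;
existing metric columns are only overwritten under `force`. The TSV
dialect (UTF-8, header, `NA`, booleans as `TRUE`/`FALSE`) follows the
conventions of translation-process token tables.

## Synthetic data: what it does and does not emulate

The generators exist to exercise contracts with known ground truth, using
study-shaped defaults: ensembles of about ten translators per sentence,
10–25 token sentences, fixation durations around 220 ± 60 ms, and a
reordering rate of 0.15 (the expected inversion density of the sampled
permutation — 0 is monotone, 1 the full reversal). Multi-word groups are
planted as fully bipartite blocks over consecutive slots and returned as
gold labels. Ensemble translations are drawn token-wise from a known
distribution whose exact entropy is returned as the large-sample gold for
HTra. Event logs simulate a left-to-right pass with parameterized
regressions, refixations and typing bursts, recording gold measure values
from the emitted sequence.

What passing these tests shows: the metrics implement their definitions
exactly, at any input the data model admits. What it does not show: real
translators do not read monotonically with i.i.d. fixation durations, real
alignments are not independent random links, and real lexical choice is
not token-wise independent — so the synthetic distributions say nothing
about effect sizes or significance in real process data. One seed fans out
to per-component substreams, so adding a generator never changes existing
fixtures; identical seeds give byte-identical output.

## Problem sizes

Default test and acceptance runs use pairs of up to 15 tokens (500 random
instances against the crossing oracle), trees of up to 6 nodes (200
instances against the exhaustive edit-mapping oracle, whose cost grows
factorially), entropy recovery at 5 000 simulated versions × 10 seeds, and
100 000 draws for the outlier-rate check — sizes at which the brute-force
oracles remain exact and the whole suite runs in seconds.

## Known limitations

- Word alignment, sentence segmentation and keystroke-to-token attribution
  are inputs; their quality bounds every downstream metric.
- The group-construction requirements are implemented as stated above;
  corpora with heavily discontinuous alignments will see many singleton
  groups, and seq_cross then adds little over word_cross.
- The tree metrics require exactly one dependency tree per sentence;
  one-to-many sentence translations must be filtered upstream.
- Mixed-effects modelling, ANOVA-based model comparison and word-frequency
  covariates are intentionally out of scope: tables are emitted
  model-ready for any statistics backend.
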