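"""TPR-DB-style per-token tables: reading, metric augmentation, writing.

Translation-process studies exchange per-token TSV tables in which every row
is one source token as seen by one participant, carrying identifiers
(participant, text, sentence, token position), process measures, and product
metrics. This module re-creates the augmentation step: given such a table
and, per sentence, the aligned translations (and optionally dependency
parses) of every participant, it adds the word-level product metrics

    cross, abs_cross, word_cross, seq_cross, astred_change,
    htra, hcross, hstc

as new columns. Pair-level metrics use the row's own participant's
translation; entropy metrics use the whole ensemble and are therefore equal
across participants for the same token.

Table dialect: TSV, UTF-8, header row, ``NA`` for missing values. Required
identifier columns: ``participant``, ``text_id``, ``sent_id``, ``word_id``
(0-based token position in its sentence); ``STid`` (running token number in
the text) and ``token`` are carried through untouched. Sentence membership
comes from the explicit id columns, never from re-tokenizing.

Sentence bundles arrive as JSON lines, one object per source sentence::

    {"text_id": "T1", "sent_id": "1", "source": ["w", ...],
     "versions": [{"translator": "P1", "target": ["w", ...],
                   "alignment": "0-0 1-2"}, ...],
     "source_conllu": "...",            # optional, enables astred_change
     "target_conllu": {"P1": "..."}}    # optional, per translator
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO

import pandas as pd

from .alignments import SentencePair, Token, parse_pharaoh
from .astred import DepTree, astred_change, read_conllu
from .entropy import TranslationEnsemble, hcross, hstc, htra
from .reordering import cross_values, seq_cross, word_cross

METRIC_COLUMNS = [
    "cross",
    "abs_cross",
    "word_cross",
    "seq_cross",
    "astred_change",
    "htra",
    "hcross",
    "hstc",
]

ID_COLUMNS = ["participant", "text_id", "sent_id", "word_id"]


@dataclass
class SentenceBundle:
    """Everything known about one source sentence across all translators."""

    text_id: str
    sent_id: str
    ensemble: TranslationEnsemble
    src_tree: Optional[DepTree] = None
    tgt_trees: dict[str, DepTree] = field(default_factory=dict)

    def pair_of(self, participant: str) -> Optional[SentencePair]:
        for tid, pair in self.ensemble.versions:
            if tid == participant:
                return pair
        return None


def read_bundles(stream: TextIO | str) -> dict[tuple[str, str], SentenceBundle]:
    """Parse the JSON-lines bundle format into keyed SentenceBundles."""
    text = stream.read() if hasattr(stream, "read") else stream
    bundles: dict[tuple[str, str], SentenceBundle] = {}
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"bundle line {line_no}: invalid JSON ({exc})") from None
        source = [Token(i, f) for i, f in enumerate(obj["source"])]
        versions = []
        for v in obj["versions"]:
            links = parse_pharaoh(v.get("alignment", ""), len(source), len(v["target"]))
            pair = SentencePair(
                source=list(source),
                target=[Token(i, f) for i, f in enumerate(v["target"])],
                links=links,
            )
            versions.append((v["translator"], pair))
        src_tree = None
        if obj.get("source_conllu"):
            src_tree = read_conllu(obj["source_conllu"])[0]
        tgt_trees = {
            tid: read_conllu(text)[0]
            for tid, text in obj.get("target_conllu", {}).items()
        }
        key = (str(obj["text_id"]), str(obj["sent_id"]))
        bundles[key] = SentenceBundle(
            key[0], key[1], TranslationEnsemble(source, versions), src_tree, tgt_trees
        )
    return bundles


def write_bundles(bundles: Iterable[SentenceBundle], stream: TextIO) -> None:
    from .alignments import serialize_pharaoh

    for b in bundles:
        obj = {
            "text_id": b.text_id,
            "sent_id": b.sent_id,
            "source": [t.form for t in b.ensemble.source],
            "versions": [
                {
                    "translator": tid,
                    "target": [t.form for t in pair.target],
                    "alignment": serialize_pharaoh(pair.links),
                }
                for tid, pair in b.ensemble.versions
            ],
        }
        stream.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_table(path_or_stream) -> pd.DataFrame:
    """Read a per-token TSV table (``NA`` = missing)."""
    df = pd.read_csv(
        path_or_stream, sep="\t", dtype={"participant": str, "text_id": str, "sent_id": str},
        na_values=["NA"], keep_default_na=False,
    )
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"token table lacks required columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path_or_stream) -> None:
    """Write a per-token TSV table using the package dialect (``NA`` nulls)."""
    out = df.copy()
    # booleans print as TRUE/FALSE to match the study's table conventions
    for col in out.columns:
        if out[col].dtype == bool or col == "astred_change":
            out[col] = out[col].map(
                lambda v: "TRUE" if v is True else ("FALSE" if v is False else v)
            )
    out.to_csv(path_or_stream, sep="\t", index=False, na_rep="NA")


def _sentence_metrics(bundle: SentenceBundle, participant: str) -> dict[str, list]:
    """Per-source-token metric vectors for one participant's view of a sentence."""
    n = len(bundle.ensemble.source)
    out: dict[str, list] = {c: [None] * n for c in METRIC_COLUMNS}
    pair = bundle.pair_of(participant)
    if pair is not None:
        crosses = cross_values(pair)
        wc = word_cross(pair)
        sc = seq_cross(pair)
        for i in range(n):
            out["cross"][i] = crosses[i].cross
            out["abs_cross"][i] = crosses[i].abs_cross
            out["word_cross"][i] = wc[i]
            out["seq_cross"][i] = sc[i]
        if bundle.src_tree is not None and participant in bundle.tgt_trees:
            flags = astred_change(pair, bundle.src_tree, bundle.tgt_trees[participant])
            for i in range(n):
                out["astred_change"][i] = flags.get(i)
    for i in range(n):
        out["htra"][i] = htra(bundle.ensemble, i)
        out["hcross"][i] = hcross(bundle.ensemble, i)
        out["hstc"][i] = hstc(bundle.ensemble, i)
    return out


def augment_table(
    table: pd.DataFrame,
    bundles: dict[tuple[str, str], SentenceBundle],
    force: bool = False,
) -> pd.DataFrame:
    """Add the product-metric columns to a per-token table.

    Every (text_id, sent_id) appearing in the table must have a bundle;
    otherwise the missing sentence ids are listed in the error. Existing
    metric columns are never overwritten silently — pass ``force=True`` to
    replace them. Row order is preserved; rows whose sentence or participant
    lacks alignments keep ``None`` in the metric cells.
    """
    collisions = [c for c in METRIC_COLUMNS if c in table.columns]
    if collisions and not force:
        raise ValueError(
            f"columns already present: {collisions}; pass force=True to overwrite"
        )
    keys = set(zip(table["text_id"].astype(str), table["sent_id"].astype(str)))
    missing = sorted(k for k in keys if k not in bundles)
    if missing:
        raise KeyError(f"no bundle for sentence(s): {missing}")

    cache: dict[tuple[str, str, str], dict[str, list]] = {}
    new_cols: dict[str, list] = {c: [] for c in METRIC_COLUMNS}
    for _, row in table.iterrows():
        key = (str(row["text_id"]), str(row["sent_id"]))
        bundle = bundles[key]
        part = str(row["participant"])
        ck = key + (part,)
        if ck not in cache:
            cache[ck] = _sentence_metrics(bundle, part)
        word_id = int(row["word_id"])
        if not 0 <= word_id < len(bundle.ensemble.source):
            raise ValueError(
                f"row for participant {part}, sentence {key}: word_id {word_id} "
                f"out of range ({len(bundle.ensemble.source)} source tokens)"
            )
        for c in METRIC_COLUMNS:
            new_cols[c].append(cache[ck][c][word_id])
    out = table.copy()
    for c in METRIC_COLUMNS:
        out[c] = new_cols[c]
    return out
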