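"""Deterministic synthetic data: aligned pairs, translation ensembles,
dependency trees, and fixation/keystroke logs.

Nothing here downloads or models real behaviour; the generators exist so
every metric can be exercised against *known* ground truth:

- :func:`gen_pair` samples a permutation with a controlled inversion density
  and optionally plants full-bipartite multi-word groups, returning the
  generating group structure as gold labels;
- :func:`gen_ensemble` samples N translations token-wise from a known
  per-token distribution whose exact entropy is returned as gold;
- :func:`gen_tree` samples random dependency trees (random attachment to an
  earlier-visited node, UD-style labels);
- :func:`gen_event_log` emits a left-to-right reading pass with
  parameterized regressions and typing bursts, recording gold FFDur / TrtS /
  FPD / RPD / EKS per token at generation time.

All generators fan a single seed out to independent substreams
(`numpy.random.SeedSequence.spawn`), so adding a generator never perturbs
the output of existing ones. Mimicked study structure: ensembles of roughly
ten alternative translations per source sentence, sentence lengths in the
10–25 token range, fixation durations of a couple hundred milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignments import AlignmentLink, SentencePair, Token
from .astred import DepTree
from .entropy import TranslationEnsemble
from .process_measures import FixationEvent, KeyEvent
from .reordering import SequenceGroup


@dataclass
class SimConfig:
    """Knobs for the synthetic generators (defaults mirror the emulated
    study structure: ~10 translators per text, short news-style sentences)."""

    seed: int = 0
    n_src: int = 12
    reorder_rate: float = 0.15  # expected inversion density of the permutation
    mwg_prob: float = 0.1  # chance of planting a multi-word group at a position
    n_versions: int = 10
    #: per-token probability vectors over translation variants; ``None``
    #: means every token gets ``default_dist``
    translation_dist: Optional[list[list[float]]] = None
    default_dist: tuple[float, ...] = (0.7, 0.2, 0.1)
    # event-log timing (ms)
    fix_dur_mean: float = 220.0
    fix_dur_sd: float = 60.0
    saccade_ms: float = 30.0
    regression_prob: float = 0.15
    refix_prob: float = 0.2
    keystroke_delay_mean: float = 1500.0
    keys_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_src < 1 or self.n_versions < 1:
            raise ValueError("counts must be positive")
        for p in (self.reorder_rate, self.mwg_prob, self.regression_prob, self.refix_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.translation_dist is not None:
            for dist in self.translation_dist:
                if abs(sum(dist) - 1.0) > 1e-9:
                    raise ValueError("translation_dist rows must sum to 1")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _rng(cfg: SimConfig, component: int) -> np.random.Generator:
    # one fixed substream per generator component
    return _streams(cfg.seed, 8)[component]


def sample_permutation(rng: np.random.Generator, n: int, reorder_rate: float) -> list[int]:
    """Permutation of range(n) with ≈ reorder_rate · n(n−1)/2 inversions.

    Starts from the identity and applies inversion-increasing adjacent
    transpositions until the target count is reached; rate 0 is the identity
    and rate 1 the full reversal.
    """
    perm = list(range(n))
    target = round(reorder_rate * n * (n - 1) / 2)
    inversions = 0
    while inversions < target:
        candidates = [i for i in range(n - 1) if perm[i] < perm[i + 1]]
        i = int(rng.choice(candidates))
        perm[i], perm[i + 1] = perm[i + 1], perm[i]
        inversions += 1
    return perm


def gen_pair(cfg: SimConfig) -> tuple[SentencePair, list[SequenceGroup]]:
    """A synthetic aligned pair plus the gold group structure that built it.

    Source tokens ``s0..s{n-1}``; their translations are placed at permuted
    positions. With probability ``mwg_prob`` per position, a token (and its
    right neighbour) is expanded into an m×n full-bipartite multi-word group
    (m ∈ {1,2}, n ∈ {2,3,4}) occupying consecutive target slots.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_src
    perm = sample_permutation(rng, n, cfg.reorder_rate)  # target slot of source i

    # decide MWG memberships over source positions (non-overlapping)
    blocks: list[tuple[int, ...]] = []  # source index tuples
    i = 0
    mwg_of: dict[int, int] = {}
    while i < n:
        if rng.random() < cfg.mwg_prob:
            m = int(rng.integers(1, 3))
            members = tuple(range(i, min(i + m, n)))
            # an MWG must occupy consecutive target slots: only plant it when
            # the permuted slots of its members are consecutive
            slots = sorted(perm[j] for j in members)
            if len(members) > 1 and slots != list(range(slots[0], slots[-1] + 1)):
                i += 1
                continue
            for j in members:
                mwg_of[j] = len(blocks)
            blocks.append(members)
            i = members[-1] + 1
        else:
            i += 1

    # build target: each source slot becomes 1 token, MWG blocks expand the
    # leftmost slot into n_tgt tokens aligned to every member
    order = sorted(range(n), key=lambda j: perm[j])  # source indices in target order
    tgt_forms: list[str] = []
    links: set[AlignmentLink] = set()
    gold: dict[int, SequenceGroup] = {}
    emitted: set[int] = set()
    for j in order:
        if j in emitted:
            continue
        if j in mwg_of:
            members = blocks[mwg_of[j]]
            width = int(rng.integers(2, 5))
            start_t = len(tgt_forms)
            for w in range(width):
                tgt_forms.append(f"g{mwg_of[j]}_{w}")
            for s in members:
                for t in range(start_t, start_t + width):
                    links.add(AlignmentLink(s, t))
                emitted.add(s)
            gold[members[0]] = SequenceGroup(
                tuple(members),
                tuple(range(start_t, start_t + width)),
                "mwg" if len(members) * width > 1 else "singleton",
                frozenset(
                    AlignmentLink(s, t)
                    for s in members
                    for t in range(start_t, start_t + width)
                ),
            )
        else:
            t = len(tgt_forms)
            tgt_forms.append(f"t{j}")
            links.add(AlignmentLink(j, t))
            emitted.add(j)
    pair = SentencePair.from_strings(
        [f"s{i}" for i in range(n)], tgt_forms, [(l.src, l.tgt) for l in links]
    )
    return pair, sorted(gold.values(), key=lambda g: g.src_span[0])


def gen_ensemble(cfg: SimConfig) -> tuple[TranslationEnsemble, list[float]]:
    """A multi-translator ensemble plus the gold per-token entropy (bits).

    Each version translates token i independently by drawing a variant from
    ``translation_dist[i]`` (identity alignment, monotone word order with
    per-version reordering when ``reorder_rate`` > 0). The gold value is the
    generating distribution's exact entropy, the large-sample limit of HTra.
    """
    rng = _rng(cfg, 1)
    n = cfg.n_src
    dists = (
        cfg.translation_dist
        if cfg.translation_dist is not None
        else [list(cfg.default_dist)] * n
    )
    if len(dists) != n:
        raise ValueError("translation_dist must have one row per source token")
    source = [f"s{i}" for i in range(n)]
    versions = []
    for v in range(cfg.n_versions):
        perm = sample_permutation(rng, n, cfg.reorder_rate)
        forms = [""] * n
        for i in range(n):
            variant = int(rng.choice(len(dists[i]), p=dists[i]))
            forms[perm[i]] = f"t{i}_v{variant}"
        pair = SentencePair.from_strings(
            source, forms, [(i, perm[i]) for i in range(n)]
        )
        versions.append((f"P{v + 1}", pair))
    ensemble = TranslationEnsemble(
        [Token(i, f) for i, f in enumerate(source)], versions
    )
    gold = [
        -sum(p * math.log2(p) for p in dist if p > 0) for dist in dists
    ]
    return ensemble, gold


def gen_tree(rng: np.random.Generator, n: int) -> DepTree:
    """Random single-rooted dependency tree: each non-root token attaches to
    a uniformly chosen other token, resampled until acyclic."""
    labels = ["nsubj", "obj", "obl", "amod", "det", "advmod", "nmod", "case"]
    while True:
        root = int(rng.integers(n))
        heads = []
        for i in range(n):
            if i == root:
                heads.append(0)
            else:
                h = int(rng.integers(n))
                while h == i:
                    h = int(rng.integers(n))
                heads.append(h + 1)
        try:
            deprels = ["root" if i == root else str(rng.choice(labels)) for i in range(n)]
            return DepTree.from_heads(heads, deprels, [f"w{i}" for i in range(n)])
        except ValueError:
            continue  # cyclic draw; resample


@dataclass
class GoldMeasures:
    """Generation-time expected values of the process measures."""

    ffdur: dict[int, float] = field(default_factory=dict)
    trts: dict[int, float] = field(default_factory=dict)
    fpd: dict[int, float] = field(default_factory=dict)
    rpd: dict[int, float] = field(default_factory=dict)
    eks: dict[int, Optional[float]] = field(default_factory=dict)


def gen_event_log(
    cfg: SimConfig, pair: SentencePair, participant: str = "P1"
) -> tuple[list[FixationEvent], list[KeyEvent], GoldMeasures]:
    """A reading+typing pass over the pair's source with gold measures.

    The simulated reader moves left to right; after each token it may
    regress one token back (probability ``regression_prob``) before
    continuing, and may refixate the current token (``refix_prob``). Each
    source token gets one contributing keystroke ``keystroke_delay_mean`` ms
    (jittered) after its first fixation, unless keystrokes are disabled.
    Gold values are accumulated from the emitted sequence by the measure
    definitions as the events are produced.
    """
    rng = _rng(cfg, 2)
    n = pair.n_src
    clock = 1000.0
    fix_seq: list[tuple[int, float, float]] = []  # (token, onset, duration)

    def emit(token: int) -> None:
        nonlocal clock
        dur = max(40.0, rng.normal(cfg.fix_dur_mean, cfg.fix_dur_sd))
        fix_seq.append((token, clock, dur))
        clock += dur + cfg.saccade_ms

    for tok in range(n):
        emit(tok)
        while rng.random() < cfg.refix_prob:
            emit(tok)
        if tok > 0 and rng.random() < cfg.regression_prob:
            emit(tok - 1)
            emit(tok)

    fixations = [
        FixationEvent(participant, tok, onset, dur) for tok, onset, dur in fix_seq
    ]

    keys: list[KeyEvent] = []
    first_onset: dict[int, float] = {}
    for tok, onset, _ in fix_seq:
        first_onset.setdefault(tok, onset)
    if cfg.keys_enabled:
        for tok in range(n):
            delay = max(100.0, rng.normal(cfg.keystroke_delay_mean, 200.0))
            keys.append(KeyEvent(participant, first_onset[tok] + delay, tok))
        keys.sort(key=lambda k: k.time)

    gold = GoldMeasures()
    for tok in range(n):
        on_tok = [(o, d) for t, o, d in fix_seq if t == tok]
        gold.ffdur[tok] = on_tok[0][1]
        gold.trts[tok] = sum(d for _, d in on_tok)
        first_i = next(i for i, (t, _, _) in enumerate(fix_seq) if t == tok)
        fpd = 0.0
        for t, _, d in fix_seq[first_i:]:
            if t != tok:
                break
            fpd += d
        gold.fpd[tok] = fpd
        rpd = 0.0
        for t, _, d in fix_seq[first_i:]:
            if t > tok:
                break
            rpd += d
        gold.rpd[tok] = rpd
        if cfg.keys_enabled:
            key_time = next(k.time for k in keys if k.contributes_to == tok)
            gold.eks[tok] = key_time - first_onset[tok]
        else:
            gold.eks[tok] = None
    return fixations, keys, gold
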