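import numpy as np
import pytest

from litmetrics import SentencePair


@pytest.fixture
def example2_pair() -> SentencePair:
    """The hand-written "called / marine sentinels" configuration.

    English "... called marine sentinels" against Dutch "... wachters van de
    zee genoemd": "called" aligns with sentence-final "genoemd", while the
    2-token phrase "marine sentinels" is fully bipartitely aligned (2×4 = 8
    word links) with "wachters van de zee". The "called"–"genoemd" link
    crosses all eight bipartite links.
    """
    return SentencePair.from_strings(
        ["called", "marine", "sentinels"],
        ["wachters", "van", "de", "zee", "genoemd"],
        [(0, 4)] + [(i, j) for i in (1, 2) for j in range(4)],
    )


def random_pair(rng: np.random.Generator, max_tokens: int = 15) -> SentencePair:
    """A random aligned pair: random link set over random sentence sizes."""
    n_src = int(rng.integers(1, max_tokens + 1))
    n_tgt = int(rng.integers(1, max_tokens + 1))
    density = rng.uniform(0.05, 0.35)
    links = [
        (i, j)
        for i in range(n_src)
        for j in range(n_tgt)
        if rng.random() < density
    ]
    return SentencePair.from_strings(
        [f"s{i}" for i in range(n_src)],
        [f"t{j}" for j in range(n_tgt)],
        links,
    )


def monotone_pair(n: int) -> SentencePair:
    return SentencePair.from_strings(
        [f"s{i}" for i in range(n)],
        [f"t{i}" for i in range(n)],
        [(i, i) for i in range(n)],
    )
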