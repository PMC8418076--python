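"""Entropy metrics over an ensemble of alternative translations.

Four translators render "the big house"; they agree on "house", split evenly
on "big", and one of them reorders. HTra captures the lexical disagreement,
HCross the reordering disagreement, and HSTC both at once.
"""

from litmetrics import SentencePair, Token, TranslationEnsemble, hcross, hstc, htra

source = ["the", "big", "house"]


def version(tid, target, links):
    return tid, SentencePair.from_strings(source, target, links)


ensemble = TranslationEnsemble(
    [Token(i, f) for i, f in enumerate(source)],
    [
        version("P1", ["het", "grote", "huis"], [(0, 0), (1, 1), (2, 2)]),
        version("P2", ["het", "grote", "huis"], [(0, 0), (1, 1), (2, 2)]),
        version("P3", ["het", "forse", "huis"], [(0, 0), (1, 1), (2, 2)]),
        # P4 chooses a reordered rendering: "het huis, groot"
        version("P4", ["het", "huis", "groot"], [(0, 0), (1, 2), (2, 1)]),
    ],
)

print(f"{'token':<8}{'HTra':>8}{'HCross':>8}{'HSTC':>8}   (bits over 4 versions)")
for tok in ensemble.source:
    i = tok.index
    print(
        f"{tok.form:<8}{htra(ensemble, i):>8.3f}{hcross(ensemble, i):>8.3f}"
        f"{hstc(ensemble, i):>8.3f}"
    )

print(
    "\n0 bits = full agreement; log2(4) = 2 bits would be four distinct "
    "choices. 'big' carries both lexical variation (grote/forse/groot) and, "
    "for P4, a reordering, so its joint HSTC is the highest."
)
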