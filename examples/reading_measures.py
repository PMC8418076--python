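"""Eye-tracking reading measures from a simulated translation session.

Generates a deterministic fixation/keystroke log over a 6-token source
sentence (with regressions and refixations switched on), computes the five
reading measures per token, and applies the per-participant 2.5 SD outlier
screen to the total reading times.
"""

from litmetrics import (
    SimConfig,
    exclude_outliers,
    gen_event_log,
    gen_pair,
    process_records,
)

cfg = SimConfig(seed=11, n_src=6, regression_prob=0.3, refix_prob=0.3)
pair, _ = gen_pair(cfg)
fixations, keys, _ = gen_event_log(cfg, pair)

records = process_records(fixations, keys, "P1", pair.n_src)
print(f"{'token':>5}{'FFDur':>9}{'TrtS':>9}{'FPD':>9}{'RPD':>9}{'EKS':>9}  (ms)")
for rec in records:
    print(
        f"{rec.token_index:>5}{rec.ffdur:>9.0f}{rec.trts:>9.0f}"
        f"{rec.fpd:>9.0f}{rec.rpd:>9.0f}{rec.eks:>9.0f}"
    )

trts = [rec.trts for rec in records]
keep, loss = exclude_outliers(trts, ["P1"] * len(trts))
print(
    f"\nOutlier screen at 2.5 SD keeps {int(keep.sum())}/{len(trts)} total "
    f"reading times (loss rate {loss['P1']:.1%})."
)
print(
    "FFDur is the first fixation on the token; TrtS sums all fixations on "
    "it; FPD stops at the first fixation elsewhere; RPD also counts "
    "regressions until the gaze moves past the token; EKS runs from first "
    "fixation to the first keystroke of its translation."
)
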