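"""Eye-tracking and keystroke reading measures on source tokens.

The translation-process dependent variables computed here take a
token-attributed event log — fixations on source tokens and keystrokes
attributed to the source token whose translation they produce — and derive
the standard reading measures:

FFDur  first fixation duration: the duration of the first fixation on a
       source word (very early measure).
TrtS   total reading time: the sum of all fixation durations on the word,
       irrespective of when they occurred (very late measure).
EKS    eye-key span: first contributing keystroke time minus first fixation
       onset (late measure).
FPD    first-pass duration: sum of the first consecutive run of fixations on
       the word, before any fixation on another word.
RPD    regression-path duration: from the first fixation on the word, the
       sum of fixations on it and on any earlier word, until the first
       fixation strictly to its right.

Also here: the per-participant ±k·SD outlier exclusion used to clean raw
dependent variables before modelling (single pass, sample SD, default
k = 2.5), and the log transform applied to positively skewed duration data.
All measures return ``None`` for tokens without the relevant events and are
invariant under uniform time translation of a participant's log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FixationEvent:
    participant: str
    token_index: int
    onset: float  # ms
    duration: float  # ms, > 0


@dataclass(frozen=True)
class KeyEvent:
    participant: str
    time: float  # ms
    contributes_to: Optional[int]  # source token index, or None


@dataclass
class TokenProcessRecord:
    """All process measures for one (participant, source token) cell."""

    participant: str
    token_index: int
    ffdur: Optional[float] = None
    trts: Optional[float] = None
    eks: Optional[float] = None
    fpd: Optional[float] = None
    rpd: Optional[float] = None


def _participant_fixations(
    log: Sequence[FixationEvent], participant: str
) -> list[FixationEvent]:
    fixes = sorted(
        (f for f in log if f.participant == participant), key=lambda f: f.onset
    )
    for f in fixes:
        if f.duration <= 0:
            raise ValueError(f"fixation with non-positive duration: {f}")
    return fixes


def first_fixation_duration(
    log: Sequence[FixationEvent], participant: str, token: int
) -> Optional[float]:
    """Duration of the earliest fixation on the token; None if never fixated.

    Two fixations on the token sharing the minimal onset make "first"
    ambiguous and raise a ValueError.
    """
    fixes = [f for f in _participant_fixations(log, participant) if f.token_index == token]
    if not fixes:
        return None
    first_onset = fixes[0].onset
    if sum(1 for f in fixes if f.onset == first_onset) > 1:
        raise ValueError(
            f"ambiguous log: two fixations on token {token} share onset {first_onset}"
        )
    return fixes[0].duration


def total_reading_time(
    log: Sequence[FixationEvent], participant: str, token: int
) -> Optional[float]:
    """Sum of all fixation durations on the token; None if never fixated."""
    durs = [
        f.duration
        for f in log
        if f.participant == participant and f.token_index == token
    ]
    if durs:
        for d in durs:
            if d <= 0:
                raise ValueError("fixation with non-positive duration")
        return float(sum(durs))
    return None


def eye_key_span(
    fix_log: Sequence[FixationEvent],
    key_log: Sequence[KeyEvent],
    participant: str,
    token: int,
    diagnostics: Optional[list[str]] = None,
) -> Optional[float]:
    """Time from the first fixation on the token to the first keystroke that
    contributes to its translation.

    None when either event is absent. A contributing keystroke *preceding*
    the first fixation yields None and (if a diagnostics list is supplied) a
    message — such spans are artefacts of attribution, not processing time.
    """
    fixes = [f for f in _participant_fixations(fix_log, participant) if f.token_index == token]
    keys = sorted(
        (
            k
            for k in key_log
            if k.participant == participant and k.contributes_to == token
        ),
        key=lambda k: k.time,
    )
    if not fixes or not keys:
        return None
    span = keys[0].time - fixes[0].onset
    if span < 0:
        if diagnostics is not None:
            diagnostics.append(
                f"participant {participant}, token {token}: first contributing "
                f"keystroke at {keys[0].time} precedes first fixation at {fixes[0].onset}"
            )
        return None
    return float(span)


def first_pass_duration(
    log: Sequence[FixationEvent], participant: str, token: int
) -> Optional[float]:
    """Sum of the first consecutive fixations on the word, before any
    fixation on another word (in either direction)."""
    fixes = _participant_fixations(log, participant)
    for i, f in enumerate(fixes):
        if f.token_index == token:
            total = 0.0
            for g in fixes[i:]:
                if g.token_index != token:
                    break
                total += g.duration
            return total
    return None


def regression_path_duration(
    log: Sequence[FixationEvent], participant: str, token: int
) -> Optional[float]:
    """From the first fixation on the word, accumulate fixations on it and on
    earlier words, until the first fixation strictly to its right."""
    fixes = _participant_fixations(log, participant)
    started = False
    total = 0.0
    for f in fixes:
        if not started:
            if f.token_index == token:
                started = True
                total += f.duration
            continue
        if f.token_index > token:
            break
        total += f.duration
    return total if started else None


def process_records(
    fix_log: Sequence[FixationEvent],
    key_log: Sequence[KeyEvent],
    participant: str,
    n_tokens: int,
) -> list[TokenProcessRecord]:
    """All measures for every source token of one participant."""
    records = []
    for tok in range(n_tokens):
        records.append(
            TokenProcessRecord(
                participant,
                tok,
                ffdur=first_fixation_duration(fix_log, participant, tok),
                trts=total_reading_time(fix_log, participant, tok),
                eks=eye_key_span(fix_log, key_log, participant, tok),
                fpd=first_pass_duration(fix_log, participant, tok),
                rpd=regression_path_duration(fix_log, participant, tok),
            )
        )
    return records


def exclude_outliers(
    values: Sequence[float],
    group: Sequence,
    k: float = 2.5,
) -> tuple[np.ndarray, dict]:
    """Per-group ±k·SD outlier mask, single pass.

    For each group (typically a participant), observations farther than
    k sample standard deviations from the group mean are dropped. Returns a
    boolean keep-mask aligned with ``values`` and a per-group loss-rate dict.
    A zero-variance group keeps all its points; NaN observations are never
    kept (they carry no value to model). Statistics are computed once from
    the raw data — the exclusion is deliberately not iterated.
    """
    vals = np.asarray(values, dtype=float)
    grp = pd.Series(list(group))
    if len(vals) != len(grp):
        raise ValueError("values and group must have equal length")
    keep = np.zeros(len(vals), dtype=bool)
    loss: dict = {}
    for g, idx in grp.groupby(grp).groups.items():
        idx = np.asarray(idx)
        x = vals[idx]
        finite = ~np.isnan(x)
        if finite.sum() < 2:
            keep[idx[finite]] = True
            loss[g] = 0.0
            continue
        mean = x[finite].mean()
        sd = x[finite].std(ddof=1)
        ok = finite & (np.abs(x - mean) <= k * sd) if sd > 0 else finite
        keep[idx[ok]] = True
        loss[g] = 1.0 - ok.sum() / finite.sum()
    return keep, loss


def log_transform(values: Sequence[float]) -> np.ndarray:
    """Natural log of positive duration values; NaN propagates.

    Non-positive values are a caller error: they are listed (by position) in
    the raised ValueError rather than silently turned into -inf/NaN.
    """
    vals = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.where(~np.isnan(vals) & (vals <= 0))[0]
    if bad.size:
        raise ValueError(
            f"log transform requires positive values; offending rows: {bad.tolist()}"
        )
    return np.log(vals)
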