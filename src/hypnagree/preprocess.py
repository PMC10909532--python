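"""Analysis-period trimming and unscored-epoch coercion.

Whole-night recordings carry long stretches of scored wake before sleep
onset and after final waking, and scorers start/stop their analyses at
different epochs.  To make every agreement metric compare the same epochs
for every scorer, the pipeline (1) coerces every unscored or invalid code
to wake, then (2) trims the matrix to the analysis period: from the first
epoch any scorer marked non-wake through the last such epoch.  After
preprocessing every scorer has a scoreable stage at every retained epoch,
and the amount of scored wake is directly comparable between scorers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HypnogramSet
from .stages import INVALID, UNSCORED, WAKE


@dataclass(frozen=True)
class AnalysisPeriod:
    """Bookkeeping of what preprocessing removed or rewrote."""

    first_epoch: int
    last_epoch: int  # inclusive
    n_epochs_trimmed_head: int
    n_epochs_trimmed_tail: int
    unscored_coerced_count: int

    def __post_init__(self) -> None:
        if self.first_epoch > self.last_epoch:
            raise ValueError("first_epoch must not exceed last_epoch")
        if min(self.n_epochs_trimmed_head, self.n_epochs_trimmed_tail) < 0:
            raise ValueError("trim counts must be non-negative")


def coerce_unscored(hset: HypnogramSet) -> tuple[HypnogramSet, int]:
    """Replace every UNSCORED/INVALID code by wake; return the new set and count."""
    mask = np.isin(hset.stages, (UNSCORED, INVALID))
    count = int(mask.sum())
    if count == 0:
        return hset, 0
    stages = hset.stages.copy()
    stages[mask] = WAKE
    return hset.with_stages(stages), count


def trim_analysis_period(hset: HypnogramSet) -> tuple[HypnogramSet, AnalysisPeriod]:
    """Trim excess wake from both ends of the recording.

    The analysis period spans from the first epoch at which *any* scorer
    marked a non-wake stage to the last such epoch (both inclusive).
    Requires a fully wake-coerced matrix (run :func:`coerce_unscored`
    first); raises if no scorer ever scored sleep.
    """
    if np.isin(hset.stages, (UNSCORED, INVALID)).any():
        raise ValueError("unscored/invalid codes present; coerce before trimming")
    non_wake = (hset.stages != WAKE).any(axis=0)
    if not non_wake.any():
        raise ValueError("no sleep scored by any scorer; nothing to analyse")
    idx = np.flatnonzero(non_wake)
    first, last = int(idx[0]), int(idx[-1])
    period = AnalysisPeriod(
        first_epoch=first,
        last_epoch=last,
        n_epochs_trimmed_head=first,
        n_epochs_trimmed_tail=hset.n_epochs - 1 - last,
        unscored_coerced_count=0,
    )
    out = hset.with_stages(hset.stages[:, first : last + 1])
    if out.start_clock is not None and first > 0:
        # shift the clock so epoch 0 of the trimmed set keeps its wall time
        import datetime as _dt

        base = _dt.datetime.combine(_dt.date(2000, 1, 1), out.start_clock)
        shifted = base + _dt.timedelta(seconds=first * out.epoch_seconds)
        out = out.with_stages(out.stages, start_clock=shifted.time())
    return out, period


def preprocess(hset: HypnogramSet) -> tuple[HypnogramSet, AnalysisPeriod]:
    """Coerce unscored epochs to wake, then trim to the analysis period."""
    coerced, n_coerced = coerce_unscored(hset)
    trimmed, period = trim_analysis_period(coerced)
    return trimmed, AnalysisPeriod(
        first_epoch=period.first_epoch,
        last_epoch=period.last_epoch,
        n_epochs_trimmed_head=period.n_epochs_trimmed_head,
        n_epochs_trimmed_tail=period.n_epochs_trimmed_tail,
        unscored_coerced_count=n_coerced,
    )
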