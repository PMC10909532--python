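"""Stage coding shared by every module.

Sleep is scored per 30-s epoch into one of the five AASM stages: wake (W),
the three non-REM depths (N1, N2, N3) and REM (R).  Two bookkeeping codes
exist only on input: UNSCORED (a scorer left the epoch blank) and INVALID
(a scorer marked the segment as unusable signal).  Both are coerced to wake
during preprocessing and never survive into the analysis period.

The integer codes of the scoreable stages double as the consensus
tiebreaker: when two or more stages tie for the plurality at an epoch, the
stage with the lowest code wins (W before N1 before N2 before N3 before R).
"""

from __future__ import annotations

import numpy as np

# Scoreable stages, in tiebreaker order.
WAKE = 0
N1 = 1
N2 = 2
N3 = 3
REM = 4

# Input-only codes.
UNSCORED = 8
INVALID = 9

STAGE_LABELS: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
N_STAGES = len(STAGE_LABELS)

#: merged-category label set used by the light-sleep (N1+N2) variant
LIGHT_LABELS: tuple[str, ...] = ("W", "L", "N3", "R")

_CODE_TO_LABEL: dict[int, str] = {
    WAKE: "W",
    N1: "N1",
    N2: "N2",
    N3: "N3",
    REM: "R",
    UNSCORED: "U",
    INVALID: "A",
}
_LABEL_TO_CODE: dict[str, int] = {v: k for k, v in _CODE_TO_LABEL.items()}

DEFAULT_TIEBREAK: tuple[int, ...] = (WAKE, N1, N2, N3, REM)


def code_to_label(code: int) -> str:
    """Return the string label for a stage code."""
    try:
        return _CODE_TO_LABEL[int(code)]
    except KeyError:
        raise ValueError(f"unknown stage code {code!r}") from None


def label_to_code(label: str) -> int:
    """Return the stage code for a label (case-insensitive)."""
    key = str(label).strip().upper()
    try:
        return _LABEL_TO_CODE[key]
    except KeyError:
        raise ValueError(f"unknown stage label {label!r}") from None


def is_scoreable(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of codes in the scoreable range {W..R}."""
    arr = np.asarray(codes)
    return (arr >= WAKE) & (arr <= REM)
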