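"""Per-epoch stage counts and the majority (consensus) score.

The consensus hypnogram takes, at each epoch, the stage most scorers chose.
Ties between two or more stages are broken by a fixed stage order — wake,
N1, N2, N3, REM by default — with the earlier stage winning.  The counts
matrix built here (epochs x stages, entry = number of scorers voting that
stage) is also the raw ingredient of every multi-rater agreement statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HypnogramSet, validate_preprocessed
from .stages import DEFAULT_TIEBREAK


@dataclass
class MajorityResult:
    """Consensus labelling of one subject.

    counts[i, k] is the number of scorers assigning stage k at epoch i;
    majority[i] is the plurality stage after tiebreak; is_tie[i] flags
    epochs where two or more stages shared the maximum count.
    """

    counts: np.ndarray
    majority: np.ndarray
    is_tie: np.ndarray
    n_scorers: int
    stage_labels: tuple[str, ...]

    @property
    def n_epochs(self) -> int:
        return self.counts.shape[0]

    def hypnodensity(self) -> np.ndarray:
        """Per-epoch stage distribution across scorers (rows sum to 1)."""
        return self.counts / self.n_scorers


def stage_counts(hset: HypnogramSet) -> np.ndarray:
    """Tabulate scorer votes per epoch: (n_epochs, n_stages) count matrix."""
    validate_preprocessed(hset.stages, hset.n_stages)
    k = hset.n_stages
    counts = np.zeros((hset.n_epochs, k), dtype=np.int64)
    for s in range(k):
        counts[:, s] = (hset.stages == s).sum(axis=0)
    return counts


def majority_score(
    counts: np.ndarray, tiebreak: tuple[int, ...] = DEFAULT_TIEBREAK
) -> MajorityResult:
    """Plurality stage per epoch with deterministic tie-breaking.

    ``tiebreak`` lists every stage code of the alphabet in priority order;
    among tied maxima the stage appearing earliest in it wins.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (epochs x stages)")
    n_stages = counts.shape[1]
    if sorted(tiebreak) != list(range(n_stages)):
        raise ValueError(
            f"tiebreak must be a permutation of 0..{n_stages - 1}, got {tiebreak}"
        )
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("epoch with zero votes")
    if not (row_sums == row_sums[0]).all():
        raise ValueError("all epochs must have the same number of scorers")

    maxima = counts.max(axis=1)
    is_tie = (counts == maxima[:, None]).sum(axis=1) >= 2
    # evaluate stages in tiebreak priority; first to attain the max wins
    order = np.asarray(tiebreak)
    reordered = counts[:, order]
    majority = order[np.argmax(reordered == maxima[:, None], axis=1)]
    return MajorityResult(
        counts=counts,
        majority=majority.astype(np.int16),
        is_tie=is_tie,
        n_scorers=int(row_sums[0]),
        stage_labels=tuple(f"s{i}" for i in range(n_stages)),
    )


def compute_majority(
    hset: HypnogramSet, tiebreak: tuple[int, ...] | None = None
) -> MajorityResult:
    """stage_counts + majority_score with the alphabet's own labels."""
    counts = stage_counts(hset)
    if tiebreak is None:
        tiebreak = tuple(range(hset.n_stages))
    res = majority_score(counts, tiebreak)
    res.stage_labels = hset.stage_labels
    return res


def tie_fraction(mres: MajorityResult) -> float:
    """Fraction of epochs whose plurality needed the tiebreaker."""
    return float(np.mean(mres.is_tie))
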