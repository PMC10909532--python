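"""In-memory containers for multi-scorer hypnogram data."""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .stages import INVALID, N_STAGES, STAGE_LABELS, UNSCORED


@dataclass
class HypnogramSet:
    """One subject's night scored independently by several raters.

    Parameters
    ----------
    subject_id
        Identifier linking the set to covariates.
    stages
        Integer matrix of shape (n_scorers, n_epochs).  Entries are stage
        codes: indices into ``stage_labels``, plus the input-only codes
        UNSCORED (8) and INVALID (9).
    epoch_seconds
        Duration of one epoch; 30 s in standard scoring.
    start_clock
        Optional time of day at which epoch 0 starts.  Epoch ``i`` covers
        the half-open interval [i*epoch_seconds, (i+1)*epoch_seconds) after
        that instant.
    scorer_ids, centre_ids
        Per-row identifiers; ``centre_ids`` is optional metadata recording
        which sleep centre each scorer belongs to.
    stage_labels
        The label alphabet the codes index.  ("W","N1","N2","N3","R") for
        standard scoring, ("W","L","N3","R") after a light-sleep merge.
    """

    subject_id: str
    stages: np.ndarray
    epoch_seconds: float = 30.0
    start_clock: _dt.time | None = None
    scorer_ids: list[str] = field(default_factory=list)
    centre_ids: list[str] | None = None
    stage_labels: tuple[str, ...] = STAGE_LABELS

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int16)
        if self.stages.ndim != 2:
            raise ValueError("stages must be a 2-D scorer-by-epoch matrix")
        s, e = self.stages.shape
        if s < 2:
            raise ValueError(f"need at least 2 scorers, got {s}")
        if e < 1:
            raise ValueError("need at least 1 epoch")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if not self.scorer_ids:
            self.scorer_ids = [f"scorer_{i + 1}" for i in range(s)]
        if len(self.scorer_ids) != s:
            raise ValueError("scorer_ids length must match number of rows")
        if self.centre_ids is not None and len(self.centre_ids) != s:
            raise ValueError("centre_ids length must match number of rows")
        k = len(self.stage_labels)
        valid = ((self.stages >= 0) & (self.stages < k)) | np.isin(
            self.stages, (UNSCORED, INVALID)
        )
        if not valid.all():
            bad = np.unique(self.stages[~valid])
            raise ValueError(f"stage codes outside alphabet: {bad.tolist()}")

    @property
    def n_scorers(self) -> int:
        return self.stages.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.stages.shape[1]

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def duration_hours(self) -> float:
        return self.n_epochs * self.epoch_seconds / 3600.0

    def with_stages(self, stages: np.ndarray, **changes) -> "HypnogramSet":
        """Copy of this set with a replaced stage matrix (same metadata)."""
        return replace(self, stages=np.asarray(stages, dtype=np.int16), **changes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HypnogramSet):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and np.array_equal(self.stages, other.stages)
            and self.epoch_seconds == other.epoch_seconds
            and self.start_clock == other.start_clock
            and self.scorer_ids == other.scorer_ids
            and self.centre_ids == other.centre_ids
            and self.stage_labels == other.stage_labels
        )


@dataclass(frozen=True)
class SubjectCovariates:
    """Clinical indices used as per-subject covariates (never computed here).

    ahi, ari, odi are the apnea-hypopnea, arousal and oxygen-desaturation
    indices in events per hour of sleep.
    """

    subject_id: str
    ahi: float
    ari: float
    odi: float | None = None

    def __post_init__(self) -> None:
        for name in ("ahi", "ari", "odi"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


def validate_preprocessed(stages: np.ndarray, n_stages: int = N_STAGES) -> None:
    """Raise if a matrix still carries codes outside the scoreable alphabet."""
    arr = np.asarray(stages)
    if ((arr < 0) | (arr >= n_stages)).any():
        raise ValueError(
            "matrix contains unscored/invalid codes; run preprocessing first"
        )
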