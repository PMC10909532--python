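"""Synthetic multi-scorer hypnogram datasets with controllable agreement.

Raw multi-rater scorings of whole nights are rarely shareable, so the
pipeline is exercised on simulated cohorts built from two parts:

1. A *true* hypnogram per subject: a semi-Markov chain over the five
   stages.  Each visit to stage s lasts a geometrically distributed number
   of epochs (mean ``dwell_means[s]``), after which the next stage is
   drawn from the stationary entry distribution implied by the target
   stage marginals (entry probability of s proportional to
   marginal_s / dwell_s; self-draws merge into longer runs, so the
   epoch-level stage proportions equal the marginals exactly in
   expectation).  A fragmentation multiplier divides the dwell means,
   raising the transition hazard the way disturbed sleep does.  Nights
   begin and end with a wake run.

2. Per-scorer corruption of that truth, reproducing the two disagreement
   modes observed between human scorers: (a) *boundary jitter* — each
   scorer places every stage-transition boundary a few epochs early or
   late (rounded Gaussian shift, clamped so run order is preserved), the
   analogue of epochs that start as one stage and end as another; and
   (b) *stage misclassification* — each epoch's label is resampled through
   a scorer-specific row-stochastic confusion matrix, the analogue of
   systematically different rule interpretations.  A small rate of epochs
   is additionally overwritten as UNSCORED.

Default parameters emulate a ten-scorer cohort with realistic stage
proportions (~12% W, 7% N1, 43% N2, 18% N3, 19% R of the analysed night),
700-900 epochs per subject and a 0.2% unscored rate.  Simulated AHI/ArI
covariates are affine-plus-noise functions of each subject's realized
fragmentation, so the expected negative correlation between fragmentation
and agreement is recoverable by design.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import HypnogramSet, SubjectCovariates
from .stages import N_STAGES, STAGE_LABELS, UNSCORED, WAKE

#: stage marginals of the analysed night (W, N1, N2, N3, R)
DEFAULT_MARGINALS: tuple[float, ...] = (0.123, 0.068, 0.434, 0.183, 0.192)

#: mean run lengths in epochs; N1 visits are short, N2/N3/R runs long
DEFAULT_DWELL_MEANS: tuple[float, ...] = (6.0, 3.0, 25.0, 20.0, 22.0)

#: shared confusion template for scorer misclassification; off-diagonal
#: mass concentrates on the neighbouring-stage pairs human scorers mix up
#: (N1<->N2, N2<->N3, W<->N1), with REM the most reliably detected stage
DEFAULT_CONFUSION_TEMPLATE: tuple[tuple[float, ...], ...] = (
    # W      N1     N2     N3     R
    (0.945, 0.040, 0.008, 0.003, 0.004),  # W
    (0.090, 0.780, 0.110, 0.002, 0.018),  # N1
    (0.004, 0.040, 0.910, 0.040, 0.006),  # N2
    (0.002, 0.002, 0.070, 0.924, 0.002),  # N3
    (0.005, 0.020, 0.012, 0.003, 0.960),  # R
)


@dataclass
class SyntheticConfig:
    """Generative parameters for a synthetic scoring cohort."""

    n_subjects: int = 10
    n_scorers: int = 10
    epochs_per_subject: tuple[int, int] = (700, 900)
    epoch_seconds: float = 30.0
    stage_marginals: tuple[float, ...] = DEFAULT_MARGINALS
    dwell_means: tuple[float, ...] = DEFAULT_DWELL_MEANS
    misclass_matrices: np.ndarray | None = None  # (n_scorers, 5, 5); None -> drawn
    scorer_heterogeneity: float = 200.0  # Dirichlet concentration around template
    boundary_jitter_sd: float = 1.3
    unscored_rate: float = 0.002
    fragmentation: float = 1.0
    fragmentation_spread_sd: float = 0.35  # log-normal sd of per-subject multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_scorers < 2:
            raise ValueError("need >=1 subject and >=2 scorers")
        m = np.asarray(self.stage_marginals, dtype=float)
        if m.shape != (N_STAGES,) or (m <= 0).any() or abs(m.sum() - 1) > 1e-9:
            raise ValueError("stage_marginals must be a positive 5-simplex point")
        d = np.asarray(self.dwell_means, dtype=float)
        if d.shape != (N_STAGES,) or (d < 1).any():
            raise ValueError("dwell_means must be 5 values >= 1 epoch")
        if self.boundary_jitter_sd < 0:
            raise ValueError("boundary_jitter_sd must be >= 0")
        if not 0 <= self.unscored_rate <= 1:
            raise ValueError("unscored_rate must be a probability")
        if self.fragmentation <= 0:
            raise ValueError("fragmentation must be positive")
        if self.misclass_matrices is not None:
            mm = np.asarray(self.misclass_matrices, dtype=float)
            if mm.shape != (self.n_scorers, N_STAGES, N_STAGES):
                raise ValueError(
                    "misclass_matrices must have shape (n_scorers, 5, 5)"
                )
            if not np.allclose(mm.sum(axis=2), 1.0):
                raise ValueError("misclassification rows must sum to 1")
            self.misclass_matrices = mm


@dataclass
class SyntheticTruth:
    """Ground truth saved alongside a generated dataset."""

    true_hypnograms: dict[str, np.ndarray]
    misclass_matrices: np.ndarray
    realized_transition_rates: dict[str, float]
    realized_unscored_counts: dict[str, int]
    fragmentation_multipliers: dict[str, float] = field(default_factory=dict)


def _runs(config: SyntheticConfig, fragmentation: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-run dwell means and entry probabilities for one subject."""
    dwell = np.asarray(config.dwell_means, dtype=float) / fragmentation
    dwell = np.maximum(dwell, 1.0)
    marg = np.asarray(config.stage_marginals, dtype=float)
    entry = marg / dwell
    entry /= entry.sum()
    return dwell, entry


def generate_true_hypnogram(
    config: SyntheticConfig,
    rng: np.random.Generator,
    n_epochs: int,
    fragmentation: float | None = None,
) -> np.ndarray:
    """Sample one night's true hypnogram of exactly ``n_epochs`` epochs.

    Semi-Markov over the five stages with geometric dwell times; begins
    and ends with a wake run.
    """
    if n_epochs < 3:
        raise ValueError("need at least 3 epochs for wake-sleep-wake structure")
    frag = config.fragmentation if fragmentation is None else fragmentation
    dwell, entry = _runs(config, frag)

    stages: list[int] = []
    current = WAKE
    while len(stages) < n_epochs:
        length = rng.geometric(1.0 / dwell[current])
        stages.extend([current] * int(length))
        # next run drawn from the entry distribution *with* self-draws
        # allowed (consecutive same-stage runs merge): epoch-level stage
        # proportions are then exactly entry * dwell, i.e. the marginals
        current = int(rng.choice(N_STAGES, p=entry))
    hyp = np.asarray(stages[:n_epochs], dtype=np.int16)
    hyp[-1] = WAKE  # nights end awake; trimming removes the excess
    if (hyp != WAKE).sum() == 0:
        hyp[n_epochs // 2] = int(rng.integers(1, N_STAGES))
    return hyp


def _draw_misclass_matrices(
    config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-scorer confusion matrices: Dirichlet draws around the template."""
    template = np.asarray(DEFAULT_CONFUSION_TEMPLATE)
    out = np.empty((config.n_scorers, N_STAGES, N_STAGES))
    for s in range(config.n_scorers):
        for k in range(N_STAGES):
            out[s, k] = rng.dirichlet(template[k] * config.scorer_heterogeneity)
    return out


def _jitter_boundaries(
    truth: np.ndarray, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Shift each run boundary by a rounded Gaussian, preserving run order.

    Boundary b between runs r and r+1 may move anywhere inside the
    neighbouring runs (exclusive of their far ends), so no run vanishes
    or reorders; the scorer disagrees on *when* each transition happens,
    never on the sequence of stages.
    """
    if sd == 0:
        return truth.copy()
    change = np.flatnonzero(truth[1:] != truth[:-1]) + 1  # boundary positions
    if change.size == 0:
        return truth.copy()
    bounds = np.concatenate([[0], change, [truth.size]])
    shifts = np.rint(rng.normal(0.0, sd, size=change.size)).astype(int)
    new_bounds = bounds.copy()
    for i in range(1, len(bounds) - 1):
        lo = new_bounds[i - 1] + 1  # keep at least 1 epoch of the left run
        hi = bounds[i + 1] - 1  # and of the right run
        new_bounds[i] = min(max(bounds[i] + shifts[i - 1], lo), hi)
    run_stages = truth[bounds[:-1]]
    out = np.empty_like(truth)
    for i, stage in enumerate(run_stages):
        out[new_bounds[i] : new_bounds[i + 1]] = stage
    return out


def corrupt_to_scorers(
    true_hypnogram: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    misclass: np.ndarray | None = None,
    subject_id: str = "synthetic",
) -> HypnogramSet:
    """Derive one subject's multi-scorer matrix from its true hypnogram."""
    truth = np.asarray(true_hypnogram, dtype=np.int16)
    if misclass is None:
        misclass = (
            config.misclass_matrices
            if config.misclass_matrices is not None
            else _draw_misclass_matrices(config, rng)
        )
    e = truth.size
    stages = np.empty((config.n_scorers, e), dtype=np.int16)
    for s in range(config.n_scorers):
        jittered = _jitter_boundaries(truth, config.boundary_jitter_sd, rng)
        u = rng.random(e)
        cdf = np.cumsum(misclass[s], axis=1)
        labels = (u[:, None] < cdf[jittered]).argmax(axis=1)
        unscored = rng.random(e) < config.unscored_rate
        labels[unscored] = UNSCORED
        stages[s] = labels
    return HypnogramSet(
        subject_id=subject_id,
        stages=stages,
        epoch_seconds=config.epoch_seconds,
        scorer_ids=[f"scorer_{i + 1}" for i in range(config.n_scorers)],
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[HypnogramSet], dict[str, SubjectCovariates], SyntheticTruth]:
    """Generate a full cohort: hypnogram sets, covariates and ground truth.

    Per-subject fragmentation multipliers are log-normal around the
    configured level; the simulated AHI and ArI are affine functions of
    each subject's realized true transition rate plus Gaussian noise, so
    more fragmented (lower-agreement) subjects carry higher indices.
    """
    rng = np.random.default_rng(config.seed)
    misclass = (
        config.misclass_matrices
        if config.misclass_matrices is not None
        else _draw_misclass_matrices(config, rng)
    )
    lo, hi = config.epochs_per_subject
    hsets: list[HypnogramSet] = []
    covariates: dict[str, SubjectCovariates] = {}
    truth = SyntheticTruth(
        true_hypnograms={},
        misclass_matrices=misclass,
        realized_transition_rates={},
        realized_unscored_counts={},
    )
    for i in range(config.n_subjects):
        sid = f"subject_{i + 1:03d}"
        n_epochs = int(rng.integers(lo, hi + 1))
        frag = config.fragmentation * float(
            np.exp(rng.normal(0.0, config.fragmentation_spread_sd))
        )
        hyp = generate_true_hypnogram(config, rng, n_epochs, fragmentation=frag)
        hset = corrupt_to_scorers(hyp, config, rng, misclass=misclass, subject_id=sid)
        # start clock: sleep studies begin in the late evening
        start_minutes = 22 * 60 + int(rng.integers(0, 150))
        import datetime as _dt

        hset.start_clock = _dt.time(
            (start_minutes // 60) % 24, start_minutes % 60, 0
        )
        hours = n_epochs * config.epoch_seconds / 3600.0
        trans_rate = float((hyp[1:] != hyp[:-1]).sum() / hours)
        # AHI ~ 0.8 x transition rate + noise, floored at 0; ArI similar
        ahi = max(0.0, 0.8 * trans_rate - 2.0 + rng.normal(0.0, 3.0))
        ari = max(0.0, 0.6 * trans_rate + 2.0 + rng.normal(0.0, 2.5))
        odi = max(0.0, ahi - 1.0 + rng.normal(0.0, 2.0))
        covariates[sid] = SubjectCovariates(sid, ahi=ahi, ari=ari, odi=odi)
        hsets.append(hset)
        truth.true_hypnograms[sid] = hyp
        truth.realized_transition_rates[sid] = trans_rate
        truth.realized_unscored_counts[sid] = int((hset.stages == UNSCORED).sum())
        truth.fragmentation_multipliers[sid] = frag
    return hsets, covariates, truth
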