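"""Structure of scoring disagreement.

Beyond scalar agreement coefficients, the shape of disagreement matters:
which stage pairs get mixed up (confusion epochs), how often the consensus
hypnogram transitions between stages, how the full distribution of scoring
combinations looks, how each scorer's labels break down against the
consensus, how agreement evolves over the night, and how per-subject
agreement relates to clinical covariates.

A *confusion epoch* for the pair {a, b} is an epoch whose votes span
exactly two distinct stages, a and b — the level of the split is
irrelevant, a 3/7 split counts the same as a 6/4 split.  A *transition*
is a change of stage between consecutive epochs of a single hypnogram;
rates are reported per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .agreement import _check_counts
from .containers import HypnogramSet
from .majority import MajorityResult, compute_majority


def _pair_label(a: str, b: str) -> str:
    return f"{a}/{b}"


def detect_confusions(
    counts: np.ndarray, stage_labels: tuple[str, ...]
) -> dict[str, float]:
    """Percentage of analysed epochs forming a two-stage confusion, per pair.

    Keys are "A/B" labels in stage-code order; every unordered pair of the
    alphabet is present, zero-valued if never confused.
    """
    counts, _ = _check_counts(counts)
    k = counts.shape[1]
    nonzero = counts > 0
    two_stage = nonzero.sum(axis=1) == 2
    out: dict[str, float] = {}
    n_epochs = counts.shape[0]
    for a in range(k):
        for b in range(a + 1, k):
            hits = two_stage & nonzero[:, a] & nonzero[:, b]
            out[_pair_label(stage_labels[a], stage_labels[b])] = (
                100.0 * hits.sum() / n_epochs
            )
    return out


def transition_rate(
    hypnogram: np.ndarray,
    epoch_seconds: float,
    stage_labels: tuple[str, ...],
) -> tuple[dict[str, float], float]:
    """Transitions per hour, per unordered stage pair and in total.

    A pair's rate counts both directions (a->b and b->a).  The denominator
    is the hypnogram's full duration.
    """
    hyp = np.asarray(hypnogram)
    if hyp.ndim != 1 or hyp.size < 2:
        raise ValueError("need a 1-D hypnogram of at least 2 epochs")
    hours = hyp.size * epoch_seconds / 3600.0
    a, b = hyp[:-1], hyp[1:]
    moved = a != b
    lo = np.minimum(a, b)[moved]
    hi = np.maximum(a, b)[moved]
    k = len(stage_labels)
    rates: dict[str, float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            n = int(((lo == i) & (hi == j)).sum())
            rates[_pair_label(stage_labels[i], stage_labels[j])] = n / hours
    return rates, float(moved.sum() / hours)


def combination_distribution(
    counts: np.ndarray, stage_labels: tuple[str, ...]
) -> pd.DataFrame:
    """Distribution of scoring combinations over all epochs.

    Each epoch is keyed by its exact vote composition (stages with zero
    votes dropped), e.g. ``N1:3/N2:7``.  Rows carry the participating
    stages, the agreement level max-count/S, an agreement band (100%,
    50-90% for [50%, 100%), <50%), the epoch count and the proportion of
    all epochs.  Sorted by descending proportion.
    """
    counts, s = _check_counts(counts)
    keys: dict[tuple, int] = {}
    for row in counts:
        keys.setdefault(tuple(row), 0)
        keys[tuple(row)] += 1
    n_epochs = counts.shape[0]
    records = []
    for comp, n in keys.items():
        present = [i for i, c in enumerate(comp) if c > 0]
        agreement = max(comp) / s
        if agreement == 1.0:
            band = "100%"
        elif agreement >= 0.5:
            band = "50-90%"
        else:
            band = "<50%"
        records.append(
            {
                "composition": "/".join(
                    f"{stage_labels[i]}:{comp[i]}" for i in present
                ),
                "stages": "/".join(stage_labels[i] for i in present),
                "agreement": agreement,
                "band": band,
                "n_epochs": n,
                "proportion": n / n_epochs,
            }
        )
    df = pd.DataFrame.from_records(records)
    return df.sort_values("proportion", ascending=False, ignore_index=True)


def cumulative_agreement(counts: np.ndarray) -> pd.DataFrame:
    """Cumulative distribution of per-epoch agreement (max-count/S).

    Row at level x gives the proportion of epochs with agreement >= x;
    non-increasing in x, and the value at 1.0 is the unanimous fraction.
    """
    counts, s = _check_counts(counts)
    agreement = counts.max(axis=1) / s
    levels = np.unique(agreement)
    cum = [(agreement >= lv).mean() for lv in levels]
    return pd.DataFrame({"agreement_level": levels, "proportion_at_least": cum})


def confusion_matrix_vs_majority(
    hset: HypnogramSet, mres: MajorityResult, scorer: int
) -> np.ndarray:
    """Row-normalized confusion matrix of one scorer against the consensus.

    Entry (t, s) is the fraction of consensus-stage-t epochs the scorer
    labelled s.  Rows for consensus stages that never occur are NaN.
    """
    if not 0 <= scorer < hset.n_scorers:
        raise IndexError(f"scorer index {scorer} out of range")
    if hset.n_epochs != mres.majority.shape[0]:
        raise ValueError("hypnogram set and majority result are misaligned")
    k = hset.n_stages
    mat = np.full((k, k), np.nan)
    labels = hset.stages[scorer]
    for t in range(k):
        mask = mres.majority == t
        if mask.any():
            mat[t] = np.bincount(labels[mask], minlength=k) / mask.sum()
    return mat


# ---------------------------------------------------------------------------
# time-course and covariates


def agreement_timecourse(
    hsets: list[HypnogramSet],
    mode: str = "elapsed",
    bin_seconds: float | None = None,
    mres_list: list[MajorityResult] | None = None,
) -> pd.DataFrame:
    """Mean agreement-with-majority as a function of time.

    mode "elapsed" bins by time since analysis start (default bin: one
    epoch); mode "clock" bins by wall-clock time of day (default bin:
    30 min), wrapping over midnight, and requires start_clock on every
    subject.  Each (subject, epoch) pair contributes its per-epoch
    agreement to the bin its epoch starts in; empty bins are omitted.
    """
    if mode not in ("elapsed", "clock"):
        raise ValueError("mode must be 'elapsed' or 'clock'")
    if not hsets:
        raise ValueError("no subjects given")
    if mres_list is None:
        mres_list = [compute_majority(h) for h in hsets]
    if bin_seconds is None:
        bin_seconds = hsets[0].epoch_seconds if mode == "elapsed" else 1800.0

    starts: list[np.ndarray] = []
    agreements: list[np.ndarray] = []
    for hset, mres in zip(hsets, mres_list):
        e = hset.n_epochs
        agr = mres.counts[np.arange(e), mres.majority] / mres.n_scorers
        t = np.arange(e) * hset.epoch_seconds
        if mode == "clock":
            if hset.start_clock is None:
                raise ValueError(
                    f"subject {hset.subject_id} has no start_clock; "
                    "clock mode needs one on every subject"
                )
            sc = hset.start_clock
            offset = sc.hour * 3600 + sc.minute * 60 + sc.second
            t = (t + offset) % 86400.0
        starts.append(t)
        agreements.append(agr)
    t_all = np.concatenate(starts)
    a_all = np.concatenate(agreements)
    bins = np.floor(t_all / bin_seconds).astype(np.int64)
    df = pd.DataFrame({"bin": bins, "agreement": a_all})
    grouped = df.groupby("bin")["agreement"].agg(["mean", "size"]).reset_index()
    return pd.DataFrame(
        {
            "bin_start_seconds": grouped["bin"] * bin_seconds,
            "mean_agreement": grouped["mean"],
            "n_epochs": grouped["size"].astype(int),
        }
    )


def covariate_correlation(
    x: np.ndarray, y: np.ndarray, method: str = "pearson"
) -> tuple[float, float, float]:
    """Correlation between per-subject values plus the OLS line.

    Returns (r, slope, intercept); slope/intercept always come from a
    first-degree least-squares fit, whatever the correlation method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    if method == "pearson":
        r = float(_stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(_stats.spearmanr(x, y).statistic)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    fit = _stats.linregress(x, y)
    return r, float(fit.slope), float(fit.intercept)


@dataclass
class StructureSummary:
    """Disagreement-structure bundle for one subject or the pooled dataset."""

    scope: str
    confusion_pct: dict[str, float]
    transition_rate: dict[str, float]
    total_transition_rate: float
    combination_table: pd.DataFrame
    cumulative_agreement: pd.DataFrame
    confusion_matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "confusion_pct": self.confusion_pct,
            "transition_rate_per_h": self.transition_rate,
            "total_transition_rate_per_h": self.total_transition_rate,
            "combination_table": self.combination_table.to_dict("records"),
            "cumulative_agreement": self.cumulative_agreement.to_dict("records"),
            "confusion_matrices": {
                k: np.where(np.isnan(v), None, v).tolist()
                for k, v in self.confusion_matrices.items()
            },
        }


def structure_summary(
    hset: HypnogramSet,
    mres: MajorityResult | None = None,
    scope: str | None = None,
) -> StructureSummary:
    """All disagreement-structure metrics for one preprocessed subject.

    Transition rates are computed on the consensus hypnogram, the only
    scorer-independent choice.
    """
    if mres is None:
        mres = compute_majority(hset)
    rates, total = transition_rate(
        mres.majority, hset.epoch_seconds, hset.stage_labels
    )
    return StructureSummary(
        scope=scope if scope is not None else hset.subject_id,
        confusion_pct=detect_confusions(mres.counts, hset.stage_labels),
        transition_rate=rates,
        total_transition_rate=total,
        combination_table=combination_distribution(mres.counts, hset.stage_labels),
        cumulative_agreement=cumulative_agreement(mres.counts),
        confusion_matrices={
            sid: confusion_matrix_vs_majority(hset, mres, i)
            for i, sid in enumerate(hset.scorer_ids)
        },
    )
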