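"""Chance-corrected and raw agreement statistics for multi-rater staging.

Implements the full metric set used in multicentre scoring-agreement work:

* Cohen's kappa (two raters): kappa_c = (p_o - p_e) / (1 - p_e), where p_o
  is the fraction of epochs both raters labelled identically and p_e the
  chance agreement from the product of the raters' own stage marginals.
* Fleiss' kappa (S raters, fixed per epoch): with n_ik scorers voting
  stage k at epoch i, per-epoch pair agreement
  P_i = sum_k n_ik (n_ik - 1) / (S (S - 1)); kappa_f contrasts the mean
  P-bar_o of P_i with chance P-bar_e = sum_k p_k^2 from pooled marginals.
* Binary (one-vs-rest) Fleiss' kappa per stage — a detection-style
  agreement for each stage, obtained by collapsing the count matrix to
  "stage" vs "anything else".
* Observed agreement: agreeing rater pairs over all C(S,2) pairs, averaged
  over epochs, uncorrected for chance.
* Agreement with the majority score: the fraction of scorers matching the
  consensus stage, averaged over epochs.

All statistics accept an optional epoch mask so they can be restricted to
the epochs a given consensus stage occupies (per-stage breakdowns), and
everything works unchanged on merged alphabets such as the light-sleep
(N1+N2) variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import HypnogramSet, validate_preprocessed
from .majority import MajorityResult, compute_majority


# ---------------------------------------------------------------------------
# scalar statistics


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two raters' stage vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty vectors")
    p_o = float(np.mean(a == b))
    k = int(max(a.max(), b.max())) + 1
    ma = np.bincount(a, minlength=k) / n
    mb = np.bincount(b, minlength=k) / n
    p_e = float(ma @ mb)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def _check_counts(counts: np.ndarray) -> tuple[np.ndarray, int]:
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] == 0:
        raise ValueError("counts must be a non-empty 2-D matrix")
    sums = counts.sum(axis=1)
    if not (sums == sums[0]).all():
        raise ValueError("rows must all sum to the same number of raters")
    s = int(sums[0])
    if s < 2:
        raise ValueError("need at least 2 raters per epoch")
    return counts, s


def fleiss_kappa(counts: np.ndarray) -> float:
    """Fleiss' kappa from an epochs-by-stages vote-count matrix.

    Returns NaN (with a warning) in the degenerate case where every vote
    at every epoch falls on a single stage, since chance agreement is then
    1 and the statistic undefined.
    """
    counts, s = _check_counts(counts)
    p_i = (counts * (counts - 1)).sum(axis=1) / (s * (s - 1))
    p_bar_o = float(p_i.mean())
    p_k = counts.sum(axis=0) / counts.sum()
    p_bar_e = float(p_k @ p_k)
    if p_bar_e >= 1.0:
        warnings.warn(
            "all votes fall on one stage; Fleiss' kappa undefined (chance "
            "agreement = 1)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return (p_bar_o - p_bar_e) / (1.0 - p_bar_e)


def fleiss_kappa_binary(counts: np.ndarray, stage: int) -> float:
    """One-vs-rest Fleiss' kappa for a single stage.

    NaN with a warning when the stage is never (or always, unanimously)
    scored, where the collapsed statistic is undefined.
    """
    counts, s = _check_counts(counts)
    if not 0 <= stage < counts.shape[1]:
        raise ValueError(f"stage {stage} outside count matrix")
    pos = counts[:, stage]
    collapsed = np.column_stack([pos, s - pos])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        value = fleiss_kappa(collapsed)
    if np.isnan(value):
        warnings.warn(
            f"binary kappa undefined for stage {stage}: stage absent from "
            "(or exclusively present in) every vote",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


def observed_agreement(
    counts: np.ndarray, restrict_to: np.ndarray | None = None
) -> float:
    """Fraction of agreeing rater pairs out of all C(S,2) pairs, per epoch mean."""
    counts, s = _check_counts(counts)
    if restrict_to is not None:
        counts = counts[np.asarray(restrict_to)]
        if counts.shape[0] == 0:
            raise ValueError("epoch mask selects no epochs")
    pairs_agreeing = (counts * (counts - 1)).sum(axis=1) / 2
    return float(np.mean(pairs_agreeing / (s * (s - 1) / 2)))


def agreement_with_majority(
    counts: np.ndarray,
    mres: MajorityResult,
    restrict_to: np.ndarray | None = None,
) -> float:
    """Mean fraction of scorers matching the consensus stage."""
    counts, s = _check_counts(counts)
    if counts.shape[0] != mres.majority.shape[0]:
        raise ValueError("counts and majority result are misaligned")
    frac = counts[np.arange(counts.shape[0]), mres.majority] / s
    if restrict_to is not None:
        frac = frac[np.asarray(restrict_to)]
        if frac.size == 0:
            raise ValueError("epoch mask selects no epochs")
    return float(frac.mean())


def per_majority_stage_breakdown(
    counts: np.ndarray, mres: MajorityResult
) -> dict[str, tuple[float, float]]:
    """(mean agreement with majority, observed agreement) per consensus stage.

    Metrics for stage s are computed over exactly the epochs whose majority
    score is s; stages holding no majority epochs are omitted.
    """
    out: dict[str, tuple[float, float]] = {}
    for code, label in enumerate(mres.stage_labels):
        mask = mres.majority == code
        if not mask.any():
            continue
        out[label] = (
            agreement_with_majority(counts, mres, restrict_to=mask),
            observed_agreement(counts, restrict_to=mask),
        )
    return out


# ---------------------------------------------------------------------------
# stage merging (light-sleep variant)

LIGHT_SLEEP_MERGE: dict[str, str] = {"N1": "L", "N2": "L"}


def merge_stages(
    hset: HypnogramSet, mapping: dict[str, str] | None = None
) -> HypnogramSet:
    """Relabel stages under a merge map (default: N1+N2 -> light sleep L).

    The map sends old labels to merged labels; labels not mentioned map to
    themselves.  The merged alphabet keeps the tiebreaker order induced by
    the old codes (W, L, N3, R for the light-sleep merge).
    """
    if mapping is None:
        mapping = LIGHT_SLEEP_MERGE
    unknown = set(mapping) - set(hset.stage_labels)
    if unknown:
        raise ValueError(f"merge map names unknown stages: {sorted(unknown)}")
    total = [mapping.get(lab, lab) for lab in hset.stage_labels]
    new_labels = tuple(dict.fromkeys(total))  # first-occurrence order
    if len(new_labels) < 2:
        raise ValueError("merged alphabet must keep at least 2 stages")
    recode = np.array([new_labels.index(lab) for lab in total], dtype=np.int16)
    validate_preprocessed(hset.stages, hset.n_stages)
    return hset.with_stages(recode[hset.stages], stage_labels=new_labels)


# ---------------------------------------------------------------------------
# pairwise comparisons and the per-subject report


def pairwise_matrix(hset: HypnogramSet) -> np.ndarray:
    """S x S scorer comparison: Cohen's kappa above the diagonal, absolute
    (fraction-identical) agreement below it, ones on the diagonal."""
    validate_preprocessed(hset.stages, hset.n_stages)
    s = hset.n_scorers
    mat = np.eye(s)
    for i in range(s):
        for j in range(i + 1, s):
            mat[i, j] = cohen_kappa(hset.stages[i], hset.stages[j])
            mat[j, i] = float(np.mean(hset.stages[i] == hset.stages[j]))
    return mat


@dataclass
class AgreementReport:
    """Every agreement statistic for one subject (or the pooled dataset)."""

    scope: str
    kappa_fleiss: float
    kappa_fleiss_binary: dict[str, float]
    observed_agreement: float
    mean_agreement_with_majority: float
    per_majority_stage: dict[str, tuple[float, float]]
    pairwise_kappa: np.ndarray | None = None
    per_scorer_agreement_with_majority: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(x: float) -> float | None:
            return None if x != x else x  # NaN -> None for strict JSON

        d = {
            "scope": self.scope,
            "kappa_fleiss": _clean(self.kappa_fleiss),
            "kappa_fleiss_binary": {
                k: _clean(v) for k, v in self.kappa_fleiss_binary.items()
            },
            "observed_agreement": self.observed_agreement,
            "mean_agreement_with_majority": self.mean_agreement_with_majority,
            "per_majority_stage": {
                k: {"agreement_with_majority": v[0], "observed_agreement": v[1]}
                for k, v in self.per_majority_stage.items()
            },
            "per_scorer_agreement_with_majority": self.per_scorer_agreement_with_majority,
        }
        if self.pairwise_kappa is not None:
            d["pairwise_matrix"] = self.pairwise_kappa.tolist()
        return d


def agreement_report(
    hset: HypnogramSet,
    mres: MajorityResult | None = None,
    include_pairwise: bool = True,
    scope: str | None = None,
) -> AgreementReport:
    """Compute the full agreement report for one preprocessed subject."""
    if mres is None:
        mres = compute_majority(hset)
    counts = mres.counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kfb = {
            label: fleiss_kappa_binary(counts, code)
            for code, label in enumerate(hset.stage_labels)
        }
    per_scorer = {
        sid: float(np.mean(hset.stages[i] == mres.majority))
        for i, sid in enumerate(hset.scorer_ids)
    }
    return AgreementReport(
        scope=scope if scope is not None else hset.subject_id,
        kappa_fleiss=fleiss_kappa(counts),
        kappa_fleiss_binary=kfb,
        observed_agreement=observed_agreement(counts),
        mean_agreement_with_majority=agreement_with_majority(counts, mres),
        per_majority_stage=per_majority_stage_breakdown(counts, mres),
        pairwise_kappa=pairwise_matrix(hset) if include_pairwise else None,
        per_scorer_agreement_with_majority=per_scorer,
    )
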