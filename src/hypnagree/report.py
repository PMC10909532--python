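"""Summary tables and the end-to-end analysis bundle.

The headline deliverables mirror what a multicentre scoring-agreement
study reports: per-scorer (and consensus) minutes in each stage with total
sleep time, stage proportions, mean disagreement with the consensus in
minutes and percent, agreement reports per subject and pooled, the
disagreement-structure summary, and covariate correlations.

Conventions:

* minutes = epoch count x epoch_seconds / 60; TST = total analysed time
  minus wake.
* "Mean disagreement with majority, min" for stage s is the mean over
  scorers of the time where the scorer's label differs from the consensus,
  restricted to consensus-stage-s epochs; the percent column divides by
  the consensus minutes of s.  The TST row duplicates the wake row in
  minutes (TST = total - wake, so their absolute disagreement is
  identical) but divides by consensus TST.
* values are kept at double precision; presentation rounding (half-up,
  1 decimal for minutes/percent, 3 for kappa) happens only when writing
  tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import (
    AgreementReport,
    agreement_report,
    merge_stages,
)
from .containers import HypnogramSet, SubjectCovariates
from .majority import MajorityResult, compute_majority, tie_fraction
from .preprocess import AnalysisPeriod, preprocess
from .structure import (
    StructureSummary,
    agreement_timecourse,
    covariate_correlation,
    structure_summary,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), as printed tables use."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# stage-minutes arithmetic


def stage_minutes(
    stages: np.ndarray,
    epoch_seconds: float,
    stage_labels: tuple[str, ...],
    wake_label: str = "W",
) -> pd.Series:
    """Minutes per stage plus TST for one hypnogram (1-D) or several (2-D rows).

    For a 2-D input returns a DataFrame-backed Series per row stacked into
    a DataFrame by the caller; here a 1-D vector gives one Series.
    """
    hyp = np.asarray(stages)
    if hyp.ndim != 1:
        raise ValueError("stage_minutes expects a single 1-D hypnogram")
    per_epoch_min = epoch_seconds / 60.0
    minutes = {
        lab: float((hyp == code).sum() * per_epoch_min)
        for code, lab in enumerate(stage_labels)
    }
    total = hyp.size * per_epoch_min
    minutes["TST"] = total - minutes[wake_label]
    return pd.Series(minutes)


def stage_minutes_table(
    hset: HypnogramSet, mres: MajorityResult | None = None
) -> pd.DataFrame:
    """Per-scorer and consensus stage minutes: one row per scorer plus a
    'majority' row, columns the stage labels plus TST."""
    if mres is None:
        mres = compute_majority(hset)
    rows = {
        "majority": stage_minutes(mres.majority, hset.epoch_seconds, hset.stage_labels)
    }
    for i, sid in enumerate(hset.scorer_ids):
        rows[sid] = stage_minutes(hset.stages[i], hset.epoch_seconds, hset.stage_labels)
    return pd.DataFrame(rows).T


def stage_proportions(minutes: pd.Series, wake_label: str = "W") -> pd.Series:
    """Percentage of all analysed epochs per stage (and TST), from minutes."""
    stage_cols = [c for c in minutes.index if c != "TST"]
    total = float(sum(minutes[c] for c in stage_cols))
    if total <= 0:
        raise ValueError("total analysed minutes must be positive")
    out = {c: 100.0 * minutes[c] / total for c in minutes.index}
    return pd.Series(out)


def disagreement_with_majority(
    hset: HypnogramSet,
    mres: MajorityResult | None = None,
) -> pd.DataFrame:
    """Mean disagreement with the consensus per stage, in minutes and percent.

    Rows 'minutes' and 'pct'; columns the stage labels plus TST.  pct is
    NaN for a stage the consensus never contains.
    """
    if mres is None:
        mres = compute_majority(hset)
    per_epoch_min = hset.epoch_seconds / 60.0
    maj_minutes = stage_minutes(mres.majority, hset.epoch_seconds, hset.stage_labels)
    differs = hset.stages != mres.majority[None, :]  # S x E
    minutes: dict[str, float] = {}
    for code, lab in enumerate(hset.stage_labels):
        mask = mres.majority == code
        minutes[lab] = float(differs[:, mask].sum(axis=1).mean() * per_epoch_min)
    wake = hset.stage_labels[0]
    minutes["TST"] = minutes[wake]  # TST = total - wake: same absolute error
    pct = {
        lab: (100.0 * minutes[lab] / maj_minutes[lab] if maj_minutes[lab] > 0 else np.nan)
        for lab in minutes
    }
    return pd.DataFrame({"minutes": minutes, "pct": pct}).T


# ---------------------------------------------------------------------------
# full-pipeline orchestration


@dataclass
class AnalysisConfig:
    """Knobs for the end-to-end run.

    tiebreak_order: stage labels in consensus tiebreaker priority; None
    uses the alphabet order (W, N1, N2, N3, R).
    merge_light: also run the N1+N2 -> L merged variant.
    timecourse_mode/bin: see structure.agreement_timecourse.
    per_subject_average: average the pooled per-stage agreement table over
    subjects instead of pooling epochs directly.
    """

    tiebreak_order: tuple[str, ...] | None = None
    merge_light: bool = True
    timecourse_mode: str = "elapsed"
    timecourse_bin_seconds: float | None = None
    correlation_method: str = "pearson"
    per_subject_average: bool = False

    def tiebreak_codes(self, stage_labels: tuple[str, ...]) -> tuple[int, ...]:
        if self.tiebreak_order is None:
            return tuple(range(len(stage_labels)))
        if sorted(self.tiebreak_order) != sorted(stage_labels):
            raise ValueError(
                f"tiebreak order {self.tiebreak_order} does not permute "
                f"{stage_labels}"
            )
        return tuple(stage_labels.index(lab) for lab in self.tiebreak_order)


@dataclass
class SubjectResult:
    hset: HypnogramSet
    period: AnalysisPeriod
    mres: MajorityResult
    agreement: AgreementReport
    structure: StructureSummary
    minutes: pd.DataFrame
    disagreement: pd.DataFrame


def _pooled_hset(hsets: list[HypnogramSet]) -> HypnogramSet | None:
    """Concatenate subjects along epochs when scorer rosters coincide."""
    first = hsets[0]
    if any(
        h.scorer_ids != first.scorer_ids or h.stage_labels != first.stage_labels
        for h in hsets
    ):
        return None
    return HypnogramSet(
        subject_id="pooled",
        stages=np.concatenate([h.stages for h in hsets], axis=1),
        epoch_seconds=first.epoch_seconds,
        scorer_ids=list(first.scorer_ids),
        stage_labels=first.stage_labels,
    )


def _analyse_one(hset: HypnogramSet, tiebreak: tuple[int, ...]) -> SubjectResult:
    pre, period = preprocess(hset)
    mres = compute_majority(pre, tiebreak)
    return SubjectResult(
        hset=pre,
        period=period,
        mres=mres,
        agreement=agreement_report(pre, mres),
        structure=structure_summary(pre, mres),
        minutes=stage_minutes_table(pre, mres),
        disagreement=disagreement_with_majority(pre, mres),
    )


def run_full_analysis(
    hsets: list[HypnogramSet],
    covariates: dict[str, SubjectCovariates] | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    """Run the whole agreement pipeline over a cohort.

    Returns a bundle with per-subject results, the pooled report (epochs
    concatenated across subjects), the pooled disagreement structure,
    minutes tables, tie statistics, the agreement time-course, covariate
    correlations (when covariates are given) and, unless disabled, the
    light-sleep merged variant.  Deterministic given inputs and config.
    """
    if not hsets:
        raise ValueError("need at least one subject")
    if config is None:
        config = AnalysisConfig()
    tiebreak = config.tiebreak_codes(hsets[0].stage_labels)

    subjects: dict[str, SubjectResult] = {}
    for h in hsets:
        try:
            subjects[h.subject_id] = _analyse_one(h, tiebreak)
        except Exception as exc:
            raise RuntimeError(f"subject {h.subject_id}: {exc}") from exc

    pre_sets = [subjects[h.subject_id].hset for h in hsets]
    pooled_set = _pooled_hset(pre_sets)
    pooled: dict = {}
    if pooled_set is not None:
        pooled_mres = compute_majority(pooled_set, tiebreak)
        pooled_agreement = agreement_report(pooled_set, pooled_mres, scope="pooled")
        if config.per_subject_average:
            pooled_agreement.per_majority_stage = _per_subject_average_breakdown(
                subjects
            )
        pooled_struct = structure_summary(pooled_set, pooled_mres, scope="pooled")
        # pooling epochs would create phantom transitions at subject joins;
        # aggregate per-subject counts over per-subject durations instead
        hours = sum(s.hset.duration_hours for s in subjects.values())
        pair_rates = {
            k: sum(
                s.structure.transition_rate[k] * s.hset.duration_hours
                for s in subjects.values()
            )
            / hours
            for k in pooled_struct.transition_rate
        }
        pooled_struct.transition_rate = pair_rates
        pooled_struct.total_transition_rate = sum(pair_rates.values())
        pooled_minutes = sum(s.minutes for s in subjects.values())
        pooled_dis = _pooled_disagreement(pooled_set, pooled_mres)
        pooled = {
            "agreement": pooled_agreement,
            "structure": pooled_struct,
            "minutes": pooled_minutes,
            "proportions": stage_proportions(pooled_minutes.loc["majority"]),
            "disagreement": pooled_dis,
            "tie_fraction": tie_fraction(pooled_mres),
        }

    timecourse = agreement_timecourse(
        pre_sets,
        mode=config.timecourse_mode,
        bin_seconds=config.timecourse_bin_seconds,
        mres_list=[subjects[h.subject_id].mres for h in hsets],
    )

    correlations: dict[str, dict] = {}
    if covariates is not None and len(hsets) >= 3:
        ids = [h.subject_id for h in hsets]
        kappas = np.array([subjects[i].agreement.kappa_fleiss for i in ids])
        trans = np.array(
            [subjects[i].structure.total_transition_rate for i in ids]
        )
        series = {"transition_rate": trans}
        if all(i in covariates for i in ids):
            series["ahi"] = np.array([covariates[i].ahi for i in ids])
            series["ari"] = np.array([covariates[i].ari for i in ids])
        for name, x in series.items():
            try:
                r, slope, intercept = covariate_correlation(
                    x, kappas, method=config.correlation_method
                )
            except ValueError:
                continue
            correlations[f"{name}_vs_kappa_fleiss"] = {
                "r": r,
                "slope": slope,
                "intercept": intercept,
            }

    bundle = {
        "subjects": subjects,
        "pooled": pooled,
        "timecourse": timecourse,
        "correlations": correlations,
        "config": config,
    }

    if config.merge_light and "N1" in hsets[0].stage_labels:
        merged_sets = [merge_stages(s) for s in pre_sets]
        merged_cfg = AnalysisConfig(
            tiebreak_order=None,
            merge_light=False,
            timecourse_mode=config.timecourse_mode,
            timecourse_bin_seconds=config.timecourse_bin_seconds,
            correlation_method=config.correlation_method,
            per_subject_average=config.per_subject_average,
        )
        bundle["light_sleep"] = run_full_analysis(
            merged_sets, covariates, merged_cfg
        )
    return bundle


def _pooled_disagreement(
    pooled_set: HypnogramSet, pooled_mres: MajorityResult
) -> pd.DataFrame:
    return disagreement_with_majority(pooled_set, pooled_mres)


def _per_subject_average_breakdown(
    subjects: dict[str, SubjectResult],
) -> dict[str, tuple[float, float]]:
    """Average each stage's per-subject metrics across the subjects whose
    consensus contains the stage (alternative to pooled-epoch averaging)."""
    acc: dict[str, list[tuple[float, float]]] = {}
    for res in subjects.values():
        for lab, vals in res.agreement.per_majority_stage.items():
            acc.setdefault(lab, []).append(vals)
    return {
        lab: (
            float(np.mean([v[0] for v in vals])),
            float(np.mean([v[1] for v in vals])),
        )
        for lab, vals in acc.items()
    }


# ---------------------------------------------------------------------------
# serialization


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def bundle_to_json_dict(bundle: dict) -> dict:
    """Reduce a run_full_analysis bundle to plain JSON-compatible types."""
    out: dict = {
        "subjects": {},
        "correlations": bundle["correlations"],
        "config": asdict(bundle["config"]),
        "timecourse": bundle["timecourse"].to_dict("records"),
    }
    for sid, res in bundle["subjects"].items():
        out["subjects"][sid] = {
            "analysis_period": asdict(res.period),
            "tie_fraction": tie_fraction(res.mres),
            "agreement": res.agreement.to_dict(),
            "structure": res.structure.to_dict(),
            "minutes": res.minutes.round(6).to_dict("index"),
            "disagreement": _nan_to_none(res.disagreement.round(6)),
        }
    if bundle["pooled"]:
        p = bundle["pooled"]
        out["pooled"] = {
            "agreement": p["agreement"].to_dict(),
            "structure": p["structure"].to_dict(),
            "minutes": p["minutes"].round(6).to_dict("index"),
            "proportions": p["proportions"].round(6).to_dict(),
            "disagreement": _nan_to_none(p["disagreement"].round(6)),
            "tie_fraction": p["tie_fraction"],
        }
    if "light_sleep" in bundle:
        out["light_sleep"] = bundle_to_json_dict(bundle["light_sleep"])
    return out


def _nan_to_none(df: pd.DataFrame) -> dict:
    return {
        row: {k: (None if pd.isna(v) else v) for k, v in vals.items()}
        for row, vals in df.to_dict("index").items()
    }


def write_bundle(bundle: dict, outdir: str | Path) -> Path:
    """Write report.json, tables/*.csv and hypnodensity/*.csv for a bundle."""
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "hypnodensity").mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(bundle_to_json_dict(bundle), indent=1, sort_keys=True,
                   allow_nan=False, default=_json_default),
        encoding="utf-8",
    )
    for sid, res in bundle["subjects"].items():
        res.minutes.to_csv(outdir / "tables" / f"minutes_{sid}.csv")
        res.structure.combination_table.to_csv(
            outdir / "tables" / f"combinations_{sid}.csv", index=False
        )
        dens = pd.DataFrame(
            res.mres.hypnodensity(), columns=list(res.hset.stage_labels)
        )
        dens.insert(0, "majority", [
            res.hset.stage_labels[c] for c in res.mres.majority
        ])
        dens.to_csv(outdir / "hypnodensity" / f"{sid}.csv", index=False)
        pd.Series(
            [res.hset.stage_labels[c] for c in res.mres.majority], name="stage"
        ).to_csv(outdir / "hypnodensity" / f"{sid}_majority.csv", index=False)
    if bundle["pooled"]:
        p = bundle["pooled"]
        p["minutes"].to_csv(outdir / "tables" / "minutes_pooled.csv")
        p["structure"].combination_table.to_csv(
            outdir / "tables" / "combinations_pooled.csv", index=False
        )
        pd.DataFrame(
            p["agreement"].pairwise_kappa,
            index=bundle["subjects"][next(iter(bundle["subjects"]))].hset.scorer_ids,
            columns=bundle["subjects"][next(iter(bundle["subjects"]))].hset.scorer_ids,
        ).to_csv(outdir / "tables" / "pairwise_pooled.csv")
    bundle["timecourse"].to_csv(outdir / "tables" / "timecourse.csv", index=False)
    return outdir
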