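# hypnagree

Multi-rater sleep-stage scoring agreement analysis.

Sleep is staged by visually scoring each 30-s epoch of a polysomnography
recording as wake (W), one of three non-REM depths (N1, N2, N3) or REM (R).
Different experts applying the same rules produce noticeably different
hypnograms, and quantifying that disagreement — overall, per stage, per
scorer pair, and in its fine structure — is how scoring rules and automatic
staging models get evaluated. `hypnagree` is for sleep researchers and
methodologists who have several independent scorings of the same nights
and want the full agreement analysis: consensus construction, chance-
corrected agreement coefficients, and a dissection of where and why the
scorers disagree. A built-in simulator generates realistic multi-scorer
cohorts with known ground truth, so every part of the pipeline is testable
without access to clinical recordings.

## What it computes

Given S scorers and E epochs, with n_ik the number of scorers assigning
stage k at epoch i:

* **Majority (consensus) score** — the plurality stage per epoch; ties go
  to the earlier stage in a fixed order (W, N1, N2, N3, R by default).
* **Cohen's κ** for scorer pairs: κ_c = (p_o − p_e)/(1 − p_e), with p_o the
  fraction of identically labelled epochs and p_e = Σ_k m_a(k)·m_b(k) from
  the raters' stage marginals.
* **Fleiss' κ** for all S scorers at once: per-epoch pair agreement
  P_i = Σ_k n_ik(n_ik − 1) / [S(S − 1)], observed P̄_o = mean_i P_i, chance
  P̄_e = Σ_k p_k² from pooled marginals, κ_f = (P̄_o − P̄_e)/(1 − P̄_e).
* **Binary (one-vs-rest) κ per stage** — Fleiss' κ after collapsing the
  counts to "stage k vs everything else": a detection-style agreement.
* **Observed agreement** — agreeing rater pairs over all C(S,2) pairs,
  averaged over epochs; **agreement with majority** — the mean fraction of
  scorers matching the consensus; both also broken down by consensus stage,
  with an optional N1+N2 → light-sleep (L) merged variant.
* **Disagreement structure** — two-stage *confusion* epochs per stage pair,
  stage-transition rates per hour, the full distribution of scoring
  combinations with agreement bands, per-scorer confusion matrices against
  the consensus, the agreement time-course over the night (clock or
  elapsed time), and correlations of per-subject agreement with clinical
  covariates (AHI, ArI) including the least-squares line.
* **Summary tables** — per-scorer and consensus minutes per stage, total
  sleep time (TST), stage proportions, and mean disagreement with the
  consensus in minutes and percent.

Preprocessing follows standard practice for whole-night comparisons:
unscored and invalid epochs are coerced to wake (they are rare, ~0.2% of
epochs in practice) and excess wake is trimmed so the analysis period runs
from the first to the last epoch any scorer marked as sleep, making the
amount of scored wake directly comparable between scorers.

## Worked example

Simulate a ten-scorer cohort and run the full analysis:

```bash
hypnagree simulate --seed 9 --out data/
hypnagree run --input data/ --covariates data/covariates.csv --out report/
```

which prints

```
subjects analysed: 10
pooled Fleiss' kappa: 0.720
pooled mean agreement with majority: 0.877
tie fraction: 1.2%
report written to report/
```

Pooling all epochs of the ten simulated subjects, chance-corrected
ten-rater agreement is κ_f = 0.72 — substantial, but far from perfect —
while on average 87.7% of scorers match the consensus stage at any given
epoch; 1.2% of epochs needed the tiebreaker. `report/report.json` carries
the full bundle (per-subject and pooled κ values, binary per-stage κ,
confusion percentages, transition rates, combination distribution,
covariate correlations), and `report/tables/` and `report/hypnodensity/`
the CSV tables. The same pipeline is available as a library:

```python
from hypnagree import SyntheticConfig, generate_dataset, run_full_analysis

hsets, covariates, truth = generate_dataset(SyntheticConfig(seed=9))
bundle = run_full_analysis(hsets, covariates)
print(bundle["pooled"]["agreement"].kappa_fleiss)
```

Real data enter through one CSV per subject (header row; column 1 the
0-based epoch index, one column per scorer, cells W/N1/N2/N3/R plus U for
unscored and A for invalid/artefact) with an optional JSON sidecar for the
epoch length, start clock time and centre ids.

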