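# Methods

## The analysis model

One subject's data are an S × E matrix of stage codes: S scorers, E epochs
of `epoch_seconds` (default 30 s), stages W, N1, N2, N3, R plus the
input-only codes U (unscored) and A (invalid/artefact). All statistics
assume every scorer labels every epoch of a common analysis period, which
preprocessing establishes in a fixed order:

1. **Coercion.** Every U/A code becomes W. Unscored epochs are rare in
   practice (on the order of 0.2%) and arise either because a scorer
   started/ended their pass at a different epoch or marked a poor-signal
   segment invalid; wake is the closest stage for such epochs since they
   count toward neither sleep time nor event scoring. Mid-night invalid
   runs are wake-coerced under the same rule — excluding them instead
   would break the equal-raters assumption behind Fleiss' κ. Coercion
   precedes trimming so that boundary detection sees a fully scored
   matrix.
2. **Trimming.** The analysis period spans from the first epoch *any*
   scorer marked non-wake to the last such epoch, inclusive. Whole-night
   recordings contain long easy-to-score wake stretches before sleep
   onset and after waking; keeping them would inflate wake agreement,
   and trimming makes the amount of scored wake directly comparable
   between scorers. Both steps are idempotent, and trimming shifts the
   start clock time by the removed head so epoch timestamps stay honest.

**Consensus.** The majority score takes the plurality stage per epoch.
Ties are broken by a fixed stage order, default (W, N1, N2, N3, R) — the
ascending stage codes. The order is configurable because it is arbitrary:
the mean agreement with the majority is provably identical under any
tiebreak permutation (the consensus count is the row maximum whichever
tied stage is chosen), which the suite asserts exactly. No smoothing is
applied across epochs; every epoch is scored independently.

**Agreement statistics.** Cohen's κ (pairwise), Fleiss' κ (all raters),
binary one-vs-rest Fleiss' κ per stage, observed pairwise agreement and
agreement-with-majority are implemented from their defining formulas in
double precision (see README for notation). Degenerate cases: when chance
agreement is exactly 1 (a stage absent from every vote, or every vote on
one stage) the κ statistic is undefined and is returned as NaN with a
RuntimeWarning rather than 0 — chance and observed agreement coincide and
no discrimination signal exists. Perfect unanimous agreement over at
least two distinct stages yields exactly 1.0. Proportions are never
rounded internally; presentation rounding (half-up, 1 decimal for minutes
and percentages, 3 for κ) happens only when writing tables.

**Per-stage breakdowns** condition on the consensus: metrics for stage s
are computed over exactly the epochs whose majority score is s. Stage-
specific κ is deliberately *not* computed this way — conditioning on the
majority makes the marginals degenerate — so per-stage κ is the binary
one-vs-rest κ, and per-stage tables report agreement proportions. For the
pooled cohort the default is pooled-epoch averaging (concatenate all
subjects' epochs, then compute); per-subject averaging (compute per
subject, then average) is available via `per_subject_average` since both
conventions appear in the literature and they differ when subjects have
unequal lengths.

**Light-sleep variant.** N1 and N2 merge into L, giving the alphabet
(W, L, N3, R) with the tiebreak order induced by the original codes. The
merge happens on the label matrices, and every downstream quantity
(counts, consensus, κ, tables) is recomputed on the merged alphabet.

**Disagreement structure.** A *confusion* for pair {a, b} is an epoch
whose votes span exactly those two stages, regardless of the split (3+7
counts like 5+5); epochs with three or more distinct stages belong to no
pair, so confusions + unanimous + ≥3-stage epochs partition the night.
Transitions are changes of stage between consecutive epochs, reported per
hour of analysed time; they are computed on the consensus hypnogram by
default (the only scorer-independent choice; per-scorer rates are
available by calling `transition_rate` on any scorer's row), and pooled
rates aggregate per-subject counts over per-subject durations rather than
concatenating hypnograms, which would create phantom transitions at
subject boundaries. The scoring-combination distribution keys epochs by
their exact vote composition and attaches agreement bands 100%,
50–90% (covering [50%, 100%)) and <50%; band edges are inclusive at the
lower edge. The agreement time-course bins per-epoch agreement-with-
majority by elapsed time (default bin one epoch) or clock time (default
30 min, wrapping over midnight); bins are configurable since no standard
exists. Covariate correlations default to Pearson with a first-degree
least-squares line; Spearman is offered because agreement/severity
relationships need not be linear.

**Mean disagreement with majority (minutes).** Defined as the mean over
scorers of the time where the scorer's label differs from the consensus,
restricted to consensus-stage-s epochs; the percent column divides by the
consensus minutes of s. This definition makes the printed minutes→percent
identity hold exactly, and it implies the TST row duplicates the wake row
in minutes (TST = total − wake, so their absolute disagreement is equal)
while dividing by consensus TST. The alternative reading — the absolute
difference of per-scorer stage totals — does not admit the consensus
minutes as a natural denominator and is not used.

## The synthetic cohort generator

The generator emulates a ten-scorer, whole-night scoring study with
controllable agreement, for testing and calibration.

*Truth.* Each subject's true hypnogram is a semi-Markov chain: stage runs
with geometric dwell (per-stage mean lengths, default 6/3/25/20/22 epochs
for W/N1/N2/N3/R — N1 visits are short, consolidated N2/N3/REM runs
long), next run drawn from the stationary entry distribution implied by
the target stage marginals (entry weight ∝ marginal/dwell; self-draws
merge, making the epoch-level stage proportions equal the marginals
exactly in expectation, and reducing to i.i.d. epochs when all dwells are
1). Default marginals are 12.3/6.8/43.4/18.3/19.2% — realistic analysed-
night proportions. Nights begin and end with a wake run so the trimming
step is exercised. A fragmentation multiplier divides the dwell means,
raising the transition rate the way disturbed sleep does; per-subject
multipliers are log-normal (sd 0.35 on the log scale) around the
configured level.

*Corruption.* Each scorer independently (1) shifts every true transition
boundary by a rounded Gaussian (default sd 1.3 epochs), clamped inside
the neighbouring runs so the stage sequence is preserved — scorers
disagree on *when* a transition happens, not on the order of stages;
(2) resamples each epoch through a scorer-specific 5 × 5 row-stochastic
confusion matrix, drawn from a Dirichlet around a shared template whose
off-diagonal mass concentrates on N1↔N2, N2↔N3 and W↔N1 (template
diagonals 0.945/0.78/0.91/0.924/0.96) — the stage pairs human scorers
actually mix up, with REM the most reliably detected stage; and
(3) overwrites epochs as unscored at rate 0.002. Under these defaults a
50-subject cohort lands in the regime multicentre studies report: pooled
κ_f ≈ 0.70, mean agreement with majority ≈ 0.87, binary κ lowest for N1
(≈ 0.35) and highest for REM (≈ 0.86), with a moderate negative
correlation between the simulated AHI and per-subject κ_f. Covariates are
simulated, never derived from events: AHI and ArI are affine functions of
the subject's realized true transition rate plus Gaussian noise, so the
fragmentation–agreement link is recoverable by design.

*What the generator does not emulate.* Ultradian REM cycling beyond run-
length structure, systematic per-centre (as opposed to per-scorer)
biases, scorer drift over the night, and the fine split structure that
produces tied epochs: the synthetic tie fraction (~1%) is lower than the
few percent seen with real scorers. Passing tests therefore demonstrate
correctness and calibration of the statistics and the recoverability of
injected effects, not distributional identity with any clinical dataset.

## Numerical and design choices

* Vote counting, κ and agreement formulas are vectorized numpy on int64
  counts; equality of implementations with brute-force pair enumeration
  is asserted to 1e-12 over random matrices.
* The tiebreak argument must be a full permutation of the alphabet;
  degenerate count rows (zero votes, non-constant rater numbers) raise.
* CSV I/O uses the stdlib csv module so ragged rows can be reported with
  their file line numbers; empty cells are read as unscored, supporting
  scorers who start late or stop early. Round-tripping is exact,
  including the start clock to the second, via a JSON sidecar.
* Problem sizes in the test and acceptance runs (cohorts of 3–50
  subjects, 150–25,000 epochs) were chosen so each check has clear
  statistical resolution for its tolerance — e.g. accuracy recovery to
  ±0.02 needs ≥20k epochs, and strict monotonicity of the fragmentation
  sweep needs ~8 subjects per level — while the whole suite stays fast.

## Known limitations

* Fleiss' κ requires the same number of raters at every epoch; cohorts
  where scorers are missing entire subjects are not supported (the
  equal-raters preprocessing guarantees this within a subject).
* Pairwise pooled matrices require identical scorer rosters across
  subjects; otherwise the pooled section is omitted.
* Confidence intervals / standard errors for κ are not implemented; the
  package reports point estimates, as the analyses it supports are
  descriptive.
* No probabilistic consensus (Dawid–Skene-style rater models): the
  consensus is plurality vote by construction.
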