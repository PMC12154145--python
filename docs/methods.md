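# Methods

## Monitoring model

The package monitors a black-box binary classifier (the *primary model*)
through K independently trained *sub-models* performing the identical task.
Per case, the agreement level is the fraction of sub-models whose binary
prediction matches the primary output; it requires no ground truth and no
access to model internals. The working assumption is that agreement tracks
case difficulty: easy cases elicit consensus, hard cases split the
ensemble. Agreement is therefore a confidence proxy, not a calibrated
probability — all downstream quantities (strata, error-detection curves)
are functions of the empirical joint distribution of agreement and
correctness, and inherit that interpretation.

With K = 5 (the default throughout) the attainable levels are
0/20/40/60/80/100%. Level percents are integers obtained by
round-half-away-from-zero of 100·j/K; K values whose levels collide on the
integer grid (K > 100) are rejected.

## Threshold policies and stratification

A `ThresholdPolicy` maps every attainable level, separately per predicted
sign, to *increased*, *similar* or *decreased* confidence. Construction
enforces totality and monotonicity (confidence never drops as agreement
rises). The shipped default for K = 5 is the clinically vetted ICH policy:
positive predictions — 100% → increased, 60–80% → similar, 0–40% →
decreased; negative predictions — 100% → increased, 20–80% → similar, 0% →
decreased. Positive predictions are treated more sceptically because in
the motivating deployment their baseline accuracy is lower.

`select_thresholds` (and `ConfidenceStratifier.fit` with `policy=None`)
learns a policy from a labelled cohort: per sign and level, a paired
bootstrap (shared resample indices, default 1000 draws) compares the
primary model's accuracy among cases at that level with the baseline
accuracy of all cases of that sign; levels significantly above baseline
(two-sided p < α, default 0.05) map to increased, significantly below to
decreased, else similar. Unpopulated levels inherit the nearest populated
level's stratum (ties toward the lower level). Because per-level tests are
independent, the raw assignment can be non-monotone; a deterministic repair
demotes any decreased above the first non-decreased level and any increased
below the last non-increased level to similar, yielding a
decreased*/similar*/increased* shape in two linear passes. The repair is a
design choice of this package: threshold selection in practice mixes
statistics with expert review, and no canonical algorithm exists.

## Error-detection curves

"Primary model erred" is the event; a case is flagged when agreement ≤
cutoff (low agreement = suspected error — the inequality direction is a
documented convention matching decreased-confidence semantics). Sweeping
the cutoff over all K+1 attainable levels gives error-detection
sensitivity, PPV, specificity and NPV per cutoff. The two summaries:

* ED-SPAUC: trapezoidal area of PPV against sensitivity, with an anchor at
  (sensitivity 0, PPV of the smallest non-empty flag set);
* ED-SNAUC: trapezoidal area of NPV against specificity, with an anchor at
  (specificity 0, NPV of the smallest non-empty unflagged set).

Points with undefined PPV/NPV (empty flag or unflag set) are dropped, not
imputed. Degenerate case: if every case sits at agreement 0, no cutoff
leaves anything unflagged and ED-SNAUC is defined as 0. Both AUCs need at
least one error and one correct case; otherwise they are refused rather
than fabricated. Absolute AUC values depend on these endpoint conventions,
which is why they are spelled out; useful reference points are 1.0 for a
perfectly separating monitor and the overall error rate for a monitor whose
agreement is independent of correctness.

## Review tradeoff

Reviewing the decreased stratum assumes the reviewer relabels correctly
(an optional `reviewer_accuracy` < 1 interpolates). Relative improvement is
100·(post − base)/base; the false-alarm rate is 100·(decreased ∧
correct)/n. The denominator n is the whole analysed (sign-restricted)
sub-cohort by default — consistent with sub-percent published false-alarm
rates — with `fa_denominator="reviewed"` as the alternative reading, since
the canonical denominator is not standardised.

## Bootstrap and prevalence control

Percentile bootstrap throughout (empirical 2.5/97.5 percentiles at α =
0.05), resampling whole cases so the pairing across models is preserved.
Prevalence control draws, with replacement, all N_n negatives-worth of
negatives and r·N_n positives: `exact_ratio` mode sets r = p/(1−p) so the
realised prevalence equals the target; `literal_fraction` sets r = p, a
simpler recipe seen in practice which actually realises p/(1+p) (0.3 →
23.1%). Both are provided because published descriptions are often
ambiguous between them; `exact_ratio` is the default since it delivers the
stated prevalence. Positive-draw counts round half away from zero;
training-subset sizing floors (matching the published 18,370 → 4,592/918
series). The paired p-value is the standard two-sided
percentile-of-difference construction, p = min(1, 2·min(#{d≤0},
#{d≥0})/B); ties at zero count on both sides, making the test slightly
conservative at coarse metric granularity. A metric undefined on more than
half the draws raises an error carrying the diagnostic count instead of
returning a number.

## Synthetic cohort generator

The generator emulates the statistical structure of a monitored
hemorrhage-detection cohort, not images: truth ~ Bernoulli(prevalence);
positives are easy or subtle (probability `p_subtle`), negatives normal or
mimicking (`p_mimic`); difficulty d ~ Beta per phenotype; each model errs
independently given d with probability clip(base + slope·d). All
cross-model error correlation flows through the shared difficulty
(conditional independence given d) — the simplest mechanism that produces
the observed phenomenology (consensus on easy cases, joint failure on
extremely hard ones) without copula machinery.

The frozen `clinical_ich` preset (p_subtle = p_mimic = 0.25, easy
Beta(1, 12), hard Beta(4, 1), primary error (0.01, 0.75), sub error
(0.02, 0.75)) was calibrated once so that a K = 5, 45%-prevalence cohort
reproduces a four-cell agreement-by-correctness partition within ±10
percentage points of the published 51/29/16/4 split (it lands near
49/31/18/2). The preset is a fixture for testing the toolkit, not an
estimate of any real model's error process: real data add scanner and
demographic covariate shift, inter-model architecture correlation beyond
shared difficulty, and non-stationary case mix, none of which the
generator represents. Passing tests therefore demonstrate correctness of
the computations and qualitative behaviour of the framework, not clinical
performance.

## Numerical conventions and degenerate inputs

* Binary labels are 1 = positive, 0 = negative everywhere; truth may be
  missing (agreement and stratification never need it; accuracy-type
  outputs exclude unlabelled cases with a logged count).
* Reported integer-percent shares use round-half-away-from-zero; raw
  fractions are always retained alongside.
* "Partial agreement" means agreement < 100%, including 0%.
* Empty strata report accuracy as NaN, never 0, to avoid fake degradation
  signals.
* All stochastic operations are reproducible given their seed; the
  generator's draw order is fixed (truth, phenotype, difficulty by fixed
  phenotype order, then one uniform per model per case).

## Problem sizes

Statistical guarantees are exercised at sizes chosen to make Monte-Carlo
noise small relative to the asserted tolerances while keeping the suite
quick: binomial agreement GOF pools 10 seeds × 10,000 cases; bootstrap
coverage uses 200 replicates of n = 2000 with 1000 draws; the paired-test
type-I rate uses 500 replicates of n = 2000 with 500 draws; ED-curve oracle
equivalence enumerates 200 random cohorts of ≤ 50 cases.

## Known limitations

Only binary primary outputs are supported (no scores, no multi-class), the
monitor must share the primary task exactly, and longitudinal drift
analysis is out of scope — the `timestamp` field on case records is a
placeholder for such extensions. The bootstrap is percentile (not BCa) and
unstratified. Learned policies depend on cohort size through the
significance tests: small cohorts legitimately collapse to all-similar.
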