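# emmon — ensembled monitoring of black-box binary classifiers

Deployed clinical AI classifiers — for example FDA-cleared intracranial
hemorrhage (ICH) detectors reading head CT — are typically black boxes:
only their final binary label is observable, so per-case confidence is
unavailable and every prediction carries the same face value. `emmon`
implements the *ensembled monitoring model* (EMM) approach to real-time,
case-by-case monitoring of such systems: K independently trained sub-models
perform the same task, and the fraction of them that agree with the primary
model's output serves as a label-free confidence proxy.

It is written for ML-monitoring engineers and clinical-AI evaluation teams
who have per-case binary predictions (primary model + K monitor sub-models)
in a table and want confidence stratification and monitor evaluation without
touching images or model internals.

## The statistic

For case *i* with primary prediction ŷᵢ and sub-model predictions
s⁽¹⁾ᵢ…s⁽ᴷ⁾ᵢ, the agreement level is

    aᵢ = (1/K) Σₖ 1[s⁽ᵏ⁾ᵢ = ŷᵢ]   ∈ {0, 1/K, …, 1}

(for K = 5: 0, 20, …, 100%). A *threshold policy* maps each attainable
level — separately for positive and negative ŷᵢ — to **increased**,
**similar** or **decreased** confidence, each suggesting an action (trust /
read as usual / review). On labelled cohorts the package evaluates the
monitor with:

* **ED-SPAUC / ED-SNAUC** — treat "primary prediction is wrong" as the
  event and low agreement (aᵢ ≤ cutoff) as the flag; sweep the cutoff and
  take the trapezoidal area under the error-detection (sensitivity, PPV)
  and (specificity, NPV) points;
* **review tradeoff** — relative accuracy improvement from reviewing the
  decreased-confidence group, 100·(post − base)/base, versus the
  false-alarm rate, 100·(reviewed-but-correct)/n;
* **prevalence-controlled bootstrap** — percentile CIs and paired p-values
  over case-level resamples, with the cohort resampled to a target
  prevalence (r·N_n positives against N_n negatives, r = p/(1−p)).

A synthetic-cohort generator with difficulty-driven, correlated errors
(subtle-positive and mimic-negative phenotypes sharing a latent difficulty)
stands in for image data, so the whole pipeline is testable end to end.

## Worked example

```python
import emmon as em

cfg = em.clinical_ich_preset(n_cases=3000, seed=7)   # 45% prevalence, K=5
preds, latent = em.generate_cohort(cfg)

clf = em.ConfidenceStratifier(policy=em.default_policy()).fit(preds)
strata = clf.predict(preds)                          # per-case strata

print(em.stratum_summary(preds, clf.policy_).round(3))
rep = em.tradeoff(preds, clf.policy_, sign="positive")
print(f"baseline {rep.baseline_accuracy:.3f} -> post-review {rep.post_review_accuracy:.3f}")
print(f"relative improvement {rep.relative_improvement:.1f}% vs false alarms {rep.false_alarm_rate:.2f}%")
curve = em.ed_curve(preds)
print(f"ED-SPAUC {curve.ed_spauc:.3f}  ED-SNAUC {curve.ed_snauc:.3f}")
```

prints

```
                    count  share  accuracy
sign     stratum
positive increased    684  0.228     0.953
         similar      512  0.171     0.648
         decreased    245  0.082     0.343
negative increased    822  0.274     0.962
         similar      688  0.229     0.702
         decreased     49  0.016     0.265
baseline 0.741 -> post-review 0.853
relative improvement 15.1% vs false alarms 5.83%
ED-SPAUC 0.563  ED-SNAUC 0.925
```

Read: full-agreement cases are far more accurate (0.95–0.96) than the
baseline, decreased-confidence cases far less (0.27–0.34), so routing the
8% of positive predictions in the decreased stratum to review raises
accuracy by 15.1% relative while only 5.8% of that sub-cohort are
unnecessary reviews — a net benefit. `ConfidenceStratifier` is a
scikit-learn estimator: with `policy=None` its `fit` *learns* the policy
from a labelled cohort by paired-bootstrap comparison of per-level accuracy
against baseline.

The same operations are available on CSV prediction tables from the shell:

```
emm simulate --n-cases 3000 --seed 7 --output preds.csv
emm stratify --input preds.csv --output strata.csv
emm tradeoff --input preds.csv --sign positive --output report.json
emm bootstrap --input preds.csv --metric sensitivity --prevalence 0.30 \
    --draws 1000 --seed 17 --output ci.json
```

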