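"""Cost/benefit of reviewing decreased-confidence cases.

Sending every decreased-confidence case to expert review buys accuracy
(reviewed cases are assumed to end up correctly labelled) at the cost of
*false alarms* — reviews of cases the primary model had already labelled
correctly. The two headline numbers, both in percent:

* relative accuracy improvement = 100 x (post-review - baseline) / baseline;
* false-alarm rate = 100 x (decreased & primary-correct) / n, with the
  denominator ``n`` being the whole analysed (sign-restricted) sub-cohort
  by default, or the reviewed cases only (``fa_denominator='reviewed'``).

A review policy yields *net benefit* when the relative improvement exceeds
the false-alarm rate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .cohort import validate_cohort
from .exceptions import EmptyInputError, InvalidParameterError, UndefinedMetricError
from .monitor import stratify_cohort
from .policy import ThresholdPolicy


@dataclass(frozen=True)
class TradeoffReport:
    """Review tradeoff for one (sub-cohort, policy) pair."""

    sign: str
    baseline_accuracy: float
    post_review_accuracy: float
    relative_improvement: float  # percent
    false_alarm_rate: float  # percent
    n_reviewed: int
    n_cases: int

    def to_dict(self) -> dict:
        return asdict(self)


def tradeoff(
    cohort: pd.DataFrame,
    policy: ThresholdPolicy,
    sign: str = "all",
    reviewer_accuracy: float = 1.0,
    fa_denominator: str = "all",
) -> TradeoffReport:
    """Review-tradeoff metrics on the sub-cohort with the given predicted sign.

    ``reviewer_accuracy`` < 1 relaxes the perfect-reviewer assumption: a
    reviewed case ends up correct with that probability (in expectation),
    so post-review accuracy interpolates between the unreviewed and fully
    corrected values.
    """
    validate_cohort(cohort, require_truth=True)
    if fa_denominator not in ("all", "reviewed"):
        raise InvalidParameterError("fa_denominator must be 'all' or 'reviewed'")
    if not (0 <= reviewer_accuracy <= 1):
        raise InvalidParameterError("reviewer_accuracy must be in [0, 1]")
    if sign == "all":
        sub = cohort
    elif sign in ("positive", "negative"):
        sub = cohort[cohort["primary"] == (1 if sign == "positive" else 0)]
    else:
        raise InvalidParameterError("sign must be 'positive', 'negative' or 'all'")
    if len(sub) == 0:
        raise EmptyInputError(f"no cases with predicted sign {sign!r}")

    strata = stratify_cohort(sub, policy).to_numpy()
    correct = (sub["primary"].to_numpy(dtype=int) == sub["truth"].to_numpy(dtype=int))
    decreased = strata == "decreased"
    n = len(sub)
    n_reviewed = int(decreased.sum())
    n_correct = int(correct.sum())
    baseline = n_correct / n
    if baseline == 0:
        raise UndefinedMetricError("baseline accuracy is 0; relative improvement undefined")
    # reviewed cases become correct with prob reviewer_accuracy; unreviewed unchanged
    post_correct = (
        n_correct - int((decreased & correct).sum()) + reviewer_accuracy * n_reviewed
    )
    post = post_correct / n
    false_alarms = int((decreased & correct).sum())
    fa_den = n if fa_denominator == "all" else max(n_reviewed, 1)
    return TradeoffReport(
        sign=sign,
        baseline_accuracy=baseline,
        post_review_accuracy=post,
        relative_improvement=100 * (post - baseline) / baseline,
        false_alarm_rate=100 * false_alarms / fa_den,
        n_reviewed=n_reviewed,
        n_cases=n,
    )


def net_benefit_table(
    cohorts_by_prevalence: dict[float, pd.DataFrame],
    policy: ThresholdPolicy,
    signs: tuple[str, ...] = ("positive", "negative"),
    **kwargs,
) -> pd.DataFrame:
    """One tradeoff row per (prevalence, sign), plus a net-benefit flag.

    ``net_benefit`` is True when the relative accuracy improvement exceeds
    the false-alarm rate (both in percent).
    """
    rows = []
    for prev, cohort in cohorts_by_prevalence.items():
        for sign in signs:
            rep = tradeoff(cohort, policy, sign=sign, **kwargs)
            row = {"prevalence": prev, **rep.to_dict()}
            row["net_benefit"] = rep.relative_improvement > rep.false_alarm_rate
            rows.append(row)
    return pd.DataFrame(rows)
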