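"""Agreement computation, confidence stratification and cohort summaries.

The monitoring idea: K independently trained sub-models perform the same
binary task as a black-box *primary* model. Per case, the fraction of
sub-models whose prediction matches the primary prediction (the *agreement
level*; for K = 5 one of 0/20/40/60/80/100%) proxies confidence in the
primary output without any ground truth. A :class:`~emmon.policy.ThresholdPolicy`
then maps agreement levels — separately for positive and negative primary
predictions — to *increased*, *similar* or *decreased* confidence, each
suggesting a different action (trust, read as usual, review).

:class:`ConfidenceStratifier` packages this as a scikit-learn estimator:
``fit`` learns the policy from a labelled cohort by bootstrap comparison of
per-level accuracy against baseline; ``predict`` assigns strata to new,
possibly unlabelled, cases. The module-level functions are thin functional
equivalents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import bootstrap as _bs
from .cohort import (
    has_truth,
    n_submodels,
    round_half_away,
    sub_columns,
    validate_cohort,
)
from .exceptions import InvalidRecordError, UnstableMetricError
from .policy import ThresholdPolicy, attainable_levels

logger = logging.getLogger(__name__)

CROSS_TAB_CELLS = (
    "full_agreement_correct",
    "partial_agreement_correct",
    "partial_agreement_incorrect",
    "full_agreement_incorrect",
)


@dataclass(frozen=True)
class CaseRecord:
    """A single monitored case."""

    case_id: str
    primary_pred: int
    sub_preds: tuple[int, ...]
    truth: int | None = None
    timestamp: int | None = None  # ordinal slot for longitudinal use

    def __post_init__(self):
        if len(self.sub_preds) < 1:
            raise InvalidRecordError(f"case {self.case_id}: no sub-model predictions")
        labels = {self.primary_pred, *self.sub_preds}
        if self.truth is not None:
            labels.add(self.truth)
        if not labels <= {0, 1}:
            raise InvalidRecordError(f"case {self.case_id}: labels must be 0/1")


@dataclass(frozen=True)
class AgreementResult:
    """Count and fraction of sub-models agreeing with the primary output."""

    case_id: str
    n_agree: int
    agreement: float

    @property
    def level_percent(self) -> int:
        return round_half_away(100 * self.agreement)


def compute_agreement(record: CaseRecord) -> AgreementResult:
    """Agreement of the K sub-models with the primary prediction.

    Invariant to sub-model order; never consults ground truth.
    """
    n_agree = sum(1 for s in record.sub_preds if s == record.primary_pred)
    return AgreementResult(
        case_id=record.case_id,
        n_agree=n_agree,
        agreement=n_agree / len(record.sub_preds),
    )


def agreement_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-case agreement: columns case_id, n_agree, agreement."""
    validate_cohort(cohort)
    subs = cohort[sub_columns(cohort)].to_numpy(dtype=int)
    primary = cohort["primary"].to_numpy(dtype=int)
    n_agree = (subs == primary[:, None]).sum(axis=1)
    k = subs.shape[1]
    return pd.DataFrame(
        {
            "case_id": cohort["case_id"].to_numpy(),
            "n_agree": n_agree,
            "agreement": n_agree / k,
        }
    )


def _level_percents(cohort: pd.DataFrame) -> np.ndarray:
    k = n_submodels(cohort)
    levels = np.asarray(attainable_levels(k))
    agg = agreement_table(cohort)
    return levels[agg["n_agree"].to_numpy()]


def stratify(agreement: AgreementResult, primary_pred: int, policy: ThresholdPolicy) -> str:
    """Confidence stratum for one case under a threshold policy."""
    sign = "positive" if primary_pred == 1 else "negative"
    return policy.stratum(agreement.level_percent, sign)


def stratify_cohort(cohort: pd.DataFrame, policy: ThresholdPolicy) -> pd.Series:
    """Per-case strata for a whole cohort (index-aligned Series)."""
    validate_cohort(cohort)
    if n_submodels(cohort) != policy.k:
        raise _policy_mismatch(cohort, policy)
    levels = _level_percents(cohort)
    primary = cohort["primary"].to_numpy(dtype=int)
    out = np.empty(len(cohort), dtype=object)
    for sign, sign_val in (("positive", 1), ("negative", 0)):
        mapping = getattr(policy, sign)
        mask = primary == sign_val
        out[mask] = [mapping[l] for l in levels[mask]]
    return pd.Series(out, index=cohort.index, name="stratum")


def _policy_mismatch(cohort, policy):
    from .exceptions import PolicyMismatchError

    return PolicyMismatchError(
        f"cohort has K={n_submodels(cohort)} sub-models but policy expects K={policy.k}"
    )


# ---------------------------------------------------------------------------
# cohort-level summaries
# ---------------------------------------------------------------------------

def cross_tab(cohort: pd.DataFrame) -> pd.DataFrame:
    """Four-way partition of a labelled cohort: agreement x correctness.

    Cells: full agreement (100%) vs partial (< 100%, including 0%), crossed
    with primary-correct vs primary-incorrect. Per cell: count, raw share of
    the cohort, share rounded to integer percent (half away from zero), and
    within-cell counts by *predicted* sign (the predicted/true-sign choice is
    ambiguous in general; predicted sign is reported because it is available
    without truth and matches how the strata are conditioned).
    """
    validate_cohort(cohort, require_truth=True)
    agg = agreement_table(cohort)
    full = agg["n_agree"].to_numpy() == n_submodels(cohort)
    truth = cohort["truth"].to_numpy(dtype=int)
    primary = cohort["primary"].to_numpy(dtype=int)
    correct = primary == truth
    masks = {
        "full_agreement_correct": full & correct,
        "partial_agreement_correct": ~full & correct,
        "partial_agreement_incorrect": ~full & ~correct,
        "full_agreement_incorrect": full & ~correct,
    }
    n = len(cohort)
    rows = []
    for cell in CROSS_TAB_CELLS:
        m = masks[cell]
        count = int(m.sum())
        rows.append(
            {
                "count": count,
                "share": count / n,
                "share_pct": round_half_away(100 * count / n),
                "n_pred_positive": int((m & (primary == 1)).sum()),
                "n_pred_negative": int((m & (primary == 0)).sum()),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(CROSS_TAB_CELLS, name="cell"))


def stratum_summary(cohort: pd.DataFrame, policy: ThresholdPolicy) -> pd.DataFrame:
    """Counts, cohort shares and primary accuracy per (sign, stratum) cell.

    Shares are fractions of the whole cohort and sum to 1. Accuracy is the
    fraction of primary predictions matching truth within the cell, computed
    over labelled cases only (unlabelled cases are excluded with a logged
    count); empty cells report accuracy as NaN, never 0.
    """
    validate_cohort(cohort)
    strata = stratify_cohort(cohort, policy)
    primary = cohort["primary"].to_numpy(dtype=int)
    if "truth" in cohort.columns:
        labelled = cohort["truth"].notna().to_numpy()
        truth_arr = cohort["truth"].fillna(-1).to_numpy(dtype=int)
    else:
        labelled = np.zeros(len(cohort), dtype=bool)
        truth_arr = np.full(len(cohort), -1)
    n_dropped = int((~labelled).sum())
    if 0 < n_dropped < len(cohort):
        logger.info("stratum_summary: %d unlabelled cases excluded from accuracy", n_dropped)
    n = len(cohort)
    rows = []
    index = []
    for sign, sign_val in (("positive", 1), ("negative", 0)):
        for stratum in ("increased", "similar", "decreased"):
            m = (primary == sign_val) & (strata == stratum).to_numpy()
            count = int(m.sum())
            lab = m & labelled
            acc = float((primary[lab] == truth_arr[lab]).mean()) if lab.any() else np.nan
            rows.append({"count": count, "share": count / n, "accuracy": acc})
            index.append((sign, stratum))
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["sign", "stratum"]))


# ---------------------------------------------------------------------------
# data-driven threshold selection
# ---------------------------------------------------------------------------

def _accuracy_at_level(level: int, levels_col: str = "_level"):
    def metric(df: pd.DataFrame) -> float:
        m = df[levels_col].to_numpy() == level
        if not m.any():
            from .exceptions import UndefinedMetricError

            raise UndefinedMetricError(f"no cases at level {level}")
        return float(
            (df["primary"].to_numpy(dtype=int)[m] == df["truth"].to_numpy(dtype=int)[m]).mean()
        )

    return metric


def _monotone_repair(assignment: dict[int, str], levels: Sequence[int]) -> dict[int, str]:
    """Demote assignments that break monotonicity to 'similar'.

    Two linear passes: any 'decreased' above the first non-decreased level,
    and any 'increased' below the last non-increased level, become 'similar'.
    The result is decreased* similar* increased* over ascending agreement.
    """
    fixed = dict(assignment)
    seen_other = False
    for lvl in levels:
        if fixed[lvl] != "decreased":
            seen_other = True
        elif seen_other:
            fixed[lvl] = "similar"
    seen_other = False
    for lvl in reversed(levels):
        if fixed[lvl] != "increased":
            seen_other = True
        elif seen_other:
            fixed[lvl] = "similar"
    return fixed


def select_thresholds(
    cohort: pd.DataFrame,
    baseline_accuracy_by_sign: dict[str, float] | None = None,
    bootstrap_params: _bs.BootstrapSpec | None = None,
) -> ThresholdPolicy:
    """Learn a threshold policy from a labelled cohort.

    Per sign and agreement level, the primary model's accuracy among cases
    at that level is compared to the baseline accuracy of all cases with
    that predicted sign via a paired bootstrap test; a level significantly
    above baseline maps to increased confidence, significantly below to
    decreased, otherwise similar. Levels with no cases inherit the stratum
    of the nearest populated level (ties toward lower agreement). Any
    non-monotone assignment is then demoted to 'similar'.

    If ``baseline_accuracy_by_sign`` is given, the comparison is against
    those fixed values; otherwise baseline is re-computed on every resample
    (fully paired).
    """
    validate_cohort(cohort, require_truth=True)
    spec = bootstrap_params or _bs.BootstrapSpec()
    k = n_submodels(cohort)
    levels = attainable_levels(k)
    work = cohort.copy()
    work["_level"] = _level_percents(cohort)
    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * len(levels)) % (2**31)

    mappings: dict[str, dict[int, str]] = {}
    for s_i, (sign, sign_val) in enumerate((("positive", 1), ("negative", 0))):
        sub = work[work["primary"] == sign_val]
        assignment: dict[int, str] = {}
        populated = []
        if len(sub):
            if baseline_accuracy_by_sign is not None:
                base_point = float(baseline_accuracy_by_sign[sign])

                def base_metric(df, _b=base_point):
                    return _b
            else:
                def base_metric(df):
                    return float((df["primary"].to_numpy(dtype=int)
                                  == df["truth"].to_numpy(dtype=int)).mean())

                base_point = base_metric(sub)
            for l_i, lvl in enumerate(levels):
                m = sub["_level"].to_numpy() == lvl
                if not m.any():
                    continue
                populated.append(lvl)
                point = float((sub["primary"].to_numpy(dtype=int)[m]
                               == sub["truth"].to_numpy(dtype=int)[m]).mean())
                draw_spec = _bs.BootstrapSpec(
                    n_draws=spec.n_draws,
                    alpha=spec.alpha,
                    seed=int(seeds[s_i * len(levels) + l_i]),
                    prevalence_mode=spec.prevalence_mode,
                )
                try:
                    p = _bs.paired_pvalue(sub, _accuracy_at_level(lvl), base_metric, draw_spec)
                except UnstableMetricError:
                    p = 1.0
                if p < spec.alpha and point > base_point:
                    assignment[lvl] = "increased"
                elif p < spec.alpha and point < base_point:
                    assignment[lvl] = "decreased"
                else:
                    assignment[lvl] = "similar"
        if not populated:
            assignment = {lvl: "similar" for lvl in levels}
        else:
            for lvl in levels:  # empty levels inherit the nearest populated one
                if lvl not in assignment:
                    nearest = min(populated, key=lambda p_l: (abs(p_l - lvl), p_l))
                    assignment[lvl] = assignment[nearest]
        mappings[sign] = _monotone_repair(assignment, levels)

    return ThresholdPolicy(positive=mappings["positive"], negative=mappings["negative"], k=k)


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class ConfidenceStratifier(BaseEstimator):
    """Agreement-based confidence stratifier for a monitored binary classifier.

    Parameters
    ----------
    policy : ThresholdPolicy, path, or None
        Fixed threshold policy. When None, ``fit`` learns one from a
        labelled cohort by bootstrap comparison of per-agreement-level
        accuracy against baseline (see :func:`select_thresholds`).
    alpha : float, default 0.05
        Significance level of the per-level bootstrap test when fitting.
    n_draws : int, default 1000
        Bootstrap draws per test when fitting.
    random_state : int or None
        Seed for the bootstrap draws.
    baseline_accuracy : dict or None
        Optional fixed per-sign baseline accuracies ``{'positive': a_p,
        'negative': a_n}`` to test against instead of resampled baselines.

    Attributes
    ----------
    policy_ : ThresholdPolicy
        The policy used for prediction.
    k_ : int
        Number of sub-models the policy covers.
    baseline_accuracy_ : dict
        Per-sign baseline accuracy of the primary model on the fit cohort
        (only when truth was available).

    Examples
    --------
    >>> from emmon import ConfidenceStratifier, default_policy
    >>> clf = ConfidenceStratifier(policy=default_policy())
    >>> strata = clf.fit(cohort).predict(cohort)  # doctest: +SKIP
    """

    def __init__(self, policy=None, alpha=0.05, n_draws=1000, random_state=None,
                 baseline_accuracy=None):
        self.policy = policy
        self.alpha = alpha
        self.n_draws = n_draws
        self.random_state = random_state
        self.baseline_accuracy = baseline_accuracy

    def fit(self, X: pd.DataFrame, y=None):
        """Fix or learn the threshold policy from a cohort frame."""
        validate_cohort(X)
        if self.policy is not None:
            pol = self.policy
            if not isinstance(pol, ThresholdPolicy):
                pol = ThresholdPolicy.load(pol)
            if pol.k != n_submodels(X):
                raise _policy_mismatch(X, pol)
            self.policy_ = pol
        else:
            spec = _bs.BootstrapSpec(n_draws=self.n_draws, alpha=self.alpha,
                                     seed=self.random_state)
            self.policy_ = select_thresholds(X, self.baseline_accuracy, spec)
        self.k_ = self.policy_.k
        if has_truth(X):
            t = X["truth"].to_numpy(dtype=int)
            p = X["primary"].to_numpy(dtype=int)
            self.baseline_accuracy_ = {
                sign: (float((p[p == v] == t[p == v]).mean()) if (p == v).any() else np.nan)
                for sign, v in (("positive", 1), ("negative", 0))
            }
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Per-case confidence strata ('increased'/'similar'/'decreased')."""
        if not hasattr(self, "policy_"):
            raise InvalidRecordError("ConfidenceStratifier is not fitted")
        return stratify_cohort(X, self.policy_).to_numpy()

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict(X)
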