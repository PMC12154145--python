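"""Prevalence-controlled resampling and bootstrap inference.

Evaluation cohorts in diagnostic monitoring rarely share the disease
prevalence of the deployment setting, so metrics are re-estimated on
resampled cohorts with a controlled prevalence: draw (with replacement) all
``N_n`` negatives-worth of negative cases and ``r x N_n`` positive cases.
Two conventions for ``r`` are supported:

* ``exact_ratio`` (default) — ``r = p / (1 - p)``, so the resampled cohort
  has expected prevalence exactly ``p``;
* ``literal_fraction`` — ``r = p``, a simpler recipe seen in practice which
  actually realises prevalence ``p / (1 + p)`` (0.3 yields ~23.1%).

Confidence intervals are percentile bootstrap (2.5th/97.5th percentiles at
the default alpha = 0.05) over case-level resamples with replacement; paired
p-values use the two-sided percentile-of-difference construction on shared
resample indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import round_half_away, validate_cohort
from .exceptions import (
    ClassMissingError,
    InvalidParameterError,
    UndefinedMetricError,
    UnstableMetricError,
)

PREVALENCE_MODES = ("exact_ratio", "literal_fraction")


@dataclass(frozen=True)
class BootstrapSpec:
    """Parameters of a bootstrap run.

    n_draws: number of resamples (default 1000).
    alpha: two-sided interval level, CI is [alpha/2, 1-alpha/2] percentiles.
    seed: RNG seed; the draw sequence is fully determined by it.
    prevalence_mode: how a target prevalence is converted to a positive-draw
        count, see module docstring.
    """

    n_draws: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    prevalence_mode: str = "exact_ratio"

    def __post_init__(self):
        if self.n_draws < 1:
            raise InvalidParameterError("n_draws must be >= 1")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.prevalence_mode not in PREVALENCE_MODES:
            raise InvalidParameterError(
                f"prevalence_mode must be one of {PREVALENCE_MODES}"
            )


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a percentile-bootstrap interval.

    ``lo <= hi`` always; the point estimate may fall outside [lo, hi] for
    strongly skewed bootstrap distributions (percentile intervals do not
    guarantee containment).
    """

    point: float
    lo: float
    hi: float
    alpha: float


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def positive_draw_count(n_negative: int, target_p: float, mode: str = "exact_ratio") -> int:
    """Number of positive cases to draw per ``n_negative`` negatives."""
    if not (0 < target_p < 1):
        raise InvalidParameterError("target prevalence must be in (0, 1)")
    if mode not in PREVALENCE_MODES:
        raise InvalidParameterError(f"unknown prevalence mode {mode!r}")
    r = target_p / (1 - target_p) if mode == "exact_ratio" else target_p
    return round_half_away(r * n_negative)


def resample_to_prevalence(
    cohort: pd.DataFrame,
    target_p: float,
    mode: str = "exact_ratio",
    rng=None,
) -> pd.DataFrame:
    """Resample (with replacement) to a controlled prevalence.

    Draws all-negatives-worth of negatives and ``r x N_n`` positives, where
    ``r`` depends on ``mode``. Case order in the output is positives first,
    then negatives; downstream metrics are order-invariant.
    """
    validate_cohort(cohort, require_truth=True)
    rng = _as_rng(rng)
    truth = cohort["truth"].to_numpy(dtype=int)
    pos_idx = np.flatnonzero(truth == 1)
    neg_idx = np.flatnonzero(truth == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ClassMissingError("both classes must be present to control prevalence")
    n_pos = positive_draw_count(len(neg_idx), target_p, mode)
    take_pos = pos_idx[rng.integers(0, len(pos_idx), size=n_pos)]
    take_neg = neg_idx[rng.integers(0, len(neg_idx), size=len(neg_idx))]
    return cohort.iloc[np.concatenate([take_pos, take_neg])].reset_index(drop=True)


def _metric_values(
    cohort: pd.DataFrame,
    metric_fns: list[Callable[[pd.DataFrame], float]],
    spec: BootstrapSpec,
    target_prevalence: float | None,
) -> np.ndarray:
    """(n_draws, n_metrics) matrix of metric values over shared resamples."""
    rng = np.random.default_rng(spec.seed)
    n = len(cohort)
    out = np.full((spec.n_draws, len(metric_fns)), np.nan)
    for b in range(spec.n_draws):
        if target_prevalence is None:
            draw = cohort.take(rng.integers(0, n, size=n))
        else:
            draw = resample_to_prevalence(cohort, target_prevalence, spec.prevalence_mode, rng)
        for j, fn in enumerate(metric_fns):
            try:
                out[b, j] = fn(draw)
            except UndefinedMetricError:
                pass  # leave NaN
    return out


def bootstrap_ci(
    cohort: pd.DataFrame,
    metric_fn: Callable[[pd.DataFrame], float],
    spec: BootstrapSpec = BootstrapSpec(),
    target_prevalence: float | None = None,
) -> IntervalEstimate:
    """Percentile-bootstrap confidence interval for a cohort-level metric.

    The point estimate is the metric on the full cohort; the interval is the
    empirical alpha/2 and 1-alpha/2 percentiles over ``n_draws`` case-level
    resamples with replacement, optionally composed with prevalence-
    controlled resampling per draw. Draws on which the metric is undefined
    are dropped; if more than half are undefined an
    :class:`UnstableMetricError` is raised.
    """
    if len(cohort) == 0:
        raise InvalidParameterError("cohort must be non-empty")
    try:
        point = float(metric_fn(cohort))
    except UndefinedMetricError:
        point = float("nan")
    vals = _metric_values(cohort, [metric_fn], spec, target_prevalence)[:, 0]
    defined = vals[~np.isnan(vals)]
    n_undef = spec.n_draws - len(defined)
    if n_undef > spec.n_draws / 2:
        raise UnstableMetricError(
            f"metric undefined on {n_undef}/{spec.n_draws} bootstrap draws",
            n_undef, spec.n_draws,
        )
    lo, hi = np.percentile(defined, [100 * spec.alpha / 2, 100 * (1 - spec.alpha / 2)])
    return IntervalEstimate(point=point, lo=float(lo), hi=float(hi), alpha=spec.alpha)


def paired_pvalue(
    cohort: pd.DataFrame,
    metric_fn_a: Callable[[pd.DataFrame], float],
    metric_fn_b: Callable[[pd.DataFrame], float],
    spec: BootstrapSpec = BootstrapSpec(),
    target_prevalence: float | None = None,
) -> float:
    """Two-sided paired bootstrap p-value for H0: metric A equals metric B.

    Both metrics are evaluated on the *same* resample of cases in every draw
    (paired design), the per-draw differences ``d_b = A_b - B_b`` are formed,
    and ``p = min(1, 2 * min(#{d_b <= 0}, #{d_b >= 0}) / B)`` over the B
    draws on which both metrics are defined.
    """
    vals = _metric_values(cohort, [metric_fn_a, metric_fn_b], spec, target_prevalence)
    ok = ~np.isnan(vals).any(axis=1)
    n_undef = spec.n_draws - int(ok.sum())
    if n_undef > spec.n_draws / 2:
        raise UnstableMetricError(
            f"a metric was undefined on {n_undef}/{spec.n_draws} bootstrap draws",
            n_undef, spec.n_draws,
        )
    d = vals[ok, 0] - vals[ok, 1]
    n_le = int((d <= 0).sum())
    n_ge = int((d >= 0).sum())
    return min(1.0, 2 * min(n_le, n_ge) / len(d))


def subsample_count(total: int, fraction: float) -> int:
    """Size of a training-data subset: ``floor(total * fraction)``."""
    if total < 0:
        raise InvalidParameterError("total must be >= 0")
    if not (0 < fraction <= 1):
        raise InvalidParameterError("fraction must be in (0, 1]")
    return int(math.floor(total * fraction))
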