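"""Cohort container, prediction-table I/O, and basic diagnostic metrics.

A *cohort* is a plain :class:`pandas.DataFrame` with one row per case:

========== ======================================================
column      content
========== ======================================================
case_id     unique case identifier (string)
truth       ground-truth label, 1 = positive, 0 = negative; may be
            missing (``pd.NA``) — agreement and stratification never
            need it, accuracy-type summaries do
primary     binary prediction of the monitored (primary) model
sub_1..K    binary predictions of the K monitor sub-models
========== ======================================================

Labels are encoded 1 = positive (condition present), 0 = negative,
in memory and in the CSV interchange format.
"""

from __future__ import annotations

import math
import re
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, InvalidRecordError, TruthRequiredError, UndefinedMetricError

SUB_COL_RE = re.compile(r"^sub_(\d+)$")

POSITIVE, NEGATIVE = 1, 0


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def sub_columns(cohort: pd.DataFrame) -> list[str]:
    """Ordered sub-model prediction columns ``sub_1 .. sub_K``."""
    cols = [(int(m.group(1)), c) for c in cohort.columns if (m := SUB_COL_RE.match(c))]
    return [c for _, c in sorted(cols)]


def n_submodels(cohort: pd.DataFrame) -> int:
    return len(sub_columns(cohort))


def validate_cohort(cohort: pd.DataFrame, require_truth: bool = False) -> pd.DataFrame:
    """Validate the cohort schema and label encoding.

    Returns the (unmodified) frame so calls can be chained. Raises
    :class:`InvalidRecordError` on schema violations and
    :class:`TruthRequiredError` when ``require_truth`` is set but any
    truth value is missing.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cohort is empty")
    subs = sub_columns(cohort)
    if not subs:
        raise InvalidRecordError("cohort has no sub-model prediction columns (sub_1..sub_K)")
    expected = [f"sub_{i}" for i in range(1, len(subs) + 1)]
    if subs != expected:
        raise InvalidRecordError(f"sub-model columns must be contiguous sub_1..sub_K, got {subs}")
    if "primary" not in cohort.columns:
        raise InvalidRecordError("cohort lacks a 'primary' prediction column")
    for col in ["primary", *subs]:
        vals = cohort[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise InvalidRecordError(f"column {col!r} contains values other than 0/1")
    if "truth" in cohort.columns:
        t = cohort["truth"]
        bad = t.dropna()[~t.dropna().isin((0, 1))]
        if len(bad):
            raise InvalidRecordError("column 'truth' contains values other than 0/1/missing")
    if require_truth and not has_truth(cohort):
        raise TruthRequiredError("this operation requires ground truth for every case")
    return cohort


def has_truth(cohort: pd.DataFrame) -> bool:
    """True when every case carries a ground-truth label."""
    return "truth" in cohort.columns and cohort["truth"].notna().all()


def drop_missing_truth(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Restrict to labelled cases; returns (subset, number dropped)."""
    if "truth" not in cohort.columns:
        return cohort.iloc[0:0], len(cohort)
    keep = cohort["truth"].notna()
    return cohort[keep], int((~keep).sum())


def make_cohort(
    primary: Sequence[int],
    subs: Sequence[Sequence[int]],
    truth: Sequence[int] | None = None,
    case_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble a cohort frame from arrays.

    ``subs`` is per-case: ``subs[i]`` holds the K sub-model predictions for
    case ``i``.
    """
    sub_arr = np.asarray(subs, dtype=int)
    if sub_arr.ndim != 2 or sub_arr.shape[1] < 1:
        raise InvalidRecordError("subs must be an (n_cases, K) array with K >= 1")
    n, k = sub_arr.shape
    data: dict = {"case_id": case_ids if case_ids is not None else [f"case_{i:06d}" for i in range(n)]}
    if truth is not None:
        data["truth"] = pd.array(truth, dtype="Int64")
    data["primary"] = np.asarray(primary, dtype=int)
    for j in range(k):
        data[f"sub_{j + 1}"] = sub_arr[:, j]
    return validate_cohort(pd.DataFrame(data))


def read_predictions(path) -> pd.DataFrame:
    """Read a prediction table (CSV, header row, UTF-8, comma-separated)."""
    df = pd.read_csv(path, dtype={"case_id": str})
    if "truth" in df.columns:
        df["truth"] = pd.array(df["truth"], dtype="Int64")
    return validate_cohort(df)


def write_predictions(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diagnostic-accuracy metrics of the primary model against truth
# ---------------------------------------------------------------------------

def primary_confusion(cohort: pd.DataFrame) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) of the primary prediction against truth."""
    sub, _ = drop_missing_truth(cohort)
    if len(sub) == 0:
        raise TruthRequiredError("no labelled cases")
    t = sub["truth"].to_numpy(dtype=int)
    p = sub["primary"].to_numpy(dtype=int)
    tp = int(((p == 1) & (t == 1)).sum())
    fp = int(((p == 1) & (t == 0)).sum())
    fn = int(((p == 0) & (t == 1)).sum())
    tn = int(((p == 0) & (t == 0)).sum())
    return tp, fp, fn, tn


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined (0/0)")
    return num / den


def accuracy(cohort: pd.DataFrame) -> float:
    tp, fp, fn, tn = primary_confusion(cohort)
    return _ratio(tp + tn, tp + fp + fn + tn, "accuracy")


def sensitivity(cohort: pd.DataFrame) -> float:
    tp, fp, fn, tn = primary_confusion(cohort)
    return _ratio(tp, tp + fn, "sensitivity")


def specificity(cohort: pd.DataFrame) -> float:
    tp, fp, fn, tn = primary_confusion(cohort)
    return _ratio(tn, tn + fp, "specificity")


def ppv(cohort: pd.DataFrame) -> float:
    tp, fp, fn, tn = primary_confusion(cohort)
    return _ratio(tp, tp + fp, "PPV")


def npv(cohort: pd.DataFrame) -> float:
    tp, fp, fn, tn = primary_confusion(cohort)
    return _ratio(tn, tn + fn, "NPV")


def prevalence(cohort: pd.DataFrame) -> float:
    """Fraction of truly positive cases among labelled cases."""
    sub, _ = drop_missing_truth(cohort)
    if len(sub) == 0:
        raise TruthRequiredError("no labelled cases")
    return float((sub["truth"] == 1).mean())


METRICS = {
    "accuracy": accuracy,
    "sensitivity": sensitivity,
    "specificity": specificity,
    "ppv": ppv,
    "npv": npv,
    "prevalence": prevalence,
}
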