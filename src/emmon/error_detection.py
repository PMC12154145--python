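"""Error-detection curves: low agreement as a detector of primary-model errors.

Here the event to detect is "the primary model's prediction is wrong", and
the per-case agreement level serves as the detector score: a case is FLAGGED
when its agreement is at or below a cutoff (low agreement = suspected
error). Sweeping the cutoff over all attainable agreement levels yields a
curve of error-detection sensitivity, PPV, specificity and NPV, from which
two threshold-free summaries are computed:

* ED-SPAUC — trapezoidal area under the (sensitivity, PPV) points,
  augmented with an anchor at sensitivity 0 whose PPV is that of the
  smallest non-empty flag set;
* ED-SNAUC — trapezoidal area under the (specificity, NPV) points,
  augmented with an anchor at specificity 0 whose NPV is that of the
  smallest non-empty unflagged set.

Points with undefined PPV/NPV (empty flagged or unflagged set) are dropped
from the quadrature, not imputed. Both AUCs lie in [0, 1]; higher is
better. The absolute values depend on these endpoint conventions, which is
why they are spelled out here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import n_submodels, validate_cohort
from .exceptions import InvalidParameterError, UndefinedAUCError
from .monitor import agreement_table


@dataclass(frozen=True)
class EDCurve:
    """Error-detection curve and its two areas.

    ``points`` has one row per attainable cutoff (ascending), columns
    cutoff, ed_sensitivity, ed_ppv, ed_specificity, ed_npv (PPV/NPV NaN
    where undefined).
    """

    points: pd.DataFrame
    ed_spauc: float
    ed_snauc: float


def _subset(cohort: pd.DataFrame, sign: str) -> pd.DataFrame:
    if sign == "all":
        return cohort
    if sign not in ("positive", "negative"):
        raise InvalidParameterError("sign must be 'positive', 'negative' or 'all'")
    return cohort[cohort["primary"] == (1 if sign == "positive" else 0)]


def ed_confusion(cohort: pd.DataFrame, cutoff: float) -> tuple[int, int, int, int]:
    """Error-detection confusion counts at one agreement cutoff.

    A case is flagged iff its agreement fraction is <= ``cutoff``. Returns
    ``(flagged_error, flagged_correct, unflagged_error, unflagged_correct)``
    where *error* means the primary prediction differs from truth. The four
    counts sum to the cohort size.
    """
    validate_cohort(cohort, require_truth=True)
    k = n_submodels(cohort)
    j = cutoff * k
    if not (0 <= cutoff <= 1) or abs(j - round(j)) > 1e-9:
        raise InvalidParameterError(
            f"cutoff {cutoff} is not an attainable agreement level for K={k}"
        )
    n_agree = agreement_table(cohort)["n_agree"].to_numpy()
    flagged = n_agree <= round(j)
    error = cohort["primary"].to_numpy(dtype=int) != cohort["truth"].to_numpy(dtype=int)
    return (
        int((flagged & error).sum()),
        int((flagged & ~error).sum()),
        int((~flagged & error).sum()),
        int((~flagged & ~error).sum()),
    )


def ed_curve(cohort: pd.DataFrame, sign: str = "all") -> EDCurve:
    """Full error-detection curve over every attainable cutoff.

    Requires at least one error and one correct case (otherwise sensitivity
    or specificity is 0/0 and the areas are undefined). ``sign`` restricts
    the analysis to cases with that predicted sign.
    """
    sub = _subset(cohort, sign)
    validate_cohort(sub, require_truth=True)
    k = n_submodels(sub)
    n_agree = agreement_table(sub)["n_agree"].to_numpy()
    error = sub["primary"].to_numpy(dtype=int) != sub["truth"].to_numpy(dtype=int)
    n_err = int(error.sum())
    n_cor = int((~error).sum())
    if n_err == 0 or n_cor == 0:
        raise UndefinedAUCError(
            f"ED AUCs need >=1 error and >=1 correct case (got {n_err} errors, {n_cor} correct)"
        )

    rows = []
    for j in range(k + 1):
        flagged = n_agree <= j
        fe = int((flagged & error).sum())
        fc = int((flagged & ~error).sum())
        ue, uc = n_err - fe, n_cor - fc
        n_flag, n_unflag = fe + fc, ue + uc
        rows.append(
            {
                "cutoff": j / k,
                "ed_sensitivity": fe / n_err,
                "ed_ppv": fe / n_flag if n_flag else np.nan,
                "ed_specificity": uc / n_cor,
                "ed_npv": uc / n_unflag if n_unflag else np.nan,
            }
        )
    points = pd.DataFrame(rows)

    # sensitivity-PPV area: anchor at sensitivity 0 with the PPV of the
    # smallest non-empty flag set, then trapezoid over defined points
    sp = points.dropna(subset=["ed_ppv"])
    x = np.concatenate([[0.0], sp["ed_sensitivity"].to_numpy()])
    y = np.concatenate([[sp["ed_ppv"].iloc[0]], sp["ed_ppv"].to_numpy()])
    ed_spauc = float(np.trapezoid(y, x))

    # specificity-NPV area: cutoffs ascending means specificity descending;
    # anchor at specificity 0 with the NPV of the smallest non-empty
    # unflagged set (the largest cutoff that leaves cases unflagged)
    sn = points.dropna(subset=["ed_npv"])
    if len(sn) == 0:
        # every case flagged at every cutoff (all agreements are 0):
        # specificity is identically 0 and the area degenerates to 0
        ed_snauc = 0.0
    else:
        xs = np.concatenate([[0.0], sn["ed_specificity"].to_numpy()[::-1]])
        ys = np.concatenate([[sn["ed_npv"].iloc[-1]], sn["ed_npv"].to_numpy()[::-1]])
        ed_snauc = float(np.trapezoid(ys, xs))

    return EDCurve(points=points, ed_spauc=ed_spauc, ed_snauc=ed_snauc)
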