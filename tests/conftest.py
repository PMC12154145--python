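import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from emmon import make_cohort

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


def cohort_from_levels(primary, truth, n_agree, k=5):
    """Build a cohort where case i has exactly n_agree[i] sub-models matching
    its primary prediction (first n_agree agree, the rest are flipped)."""
    primary = np.asarray(primary, dtype=int)
    n_agree = np.asarray(n_agree, dtype=int)
    subs = np.empty((len(primary), k), dtype=int)
    for i, (p, a) in enumerate(zip(primary, n_agree)):
        subs[i, :a] = p
        subs[i, a:] = 1 - p
    return make_cohort(primary=primary, subs=subs, truth=truth)


@pytest.fixture
def ten_case_cohort():
    """Hand-enumerated 10-case positive-prediction cohort.

    All primary predictions positive; 8 correct, 2 errors. Under the default
    K=5 policy the decreased stratum (agreement <= 40%) holds exactly two
    cases: one correct (agreement 20%) and one error (agreement 0%). Hence
    baseline accuracy 0.8, post-review 0.9, relative improvement 12.5%,
    false-alarm rate 10%, and decreased-stratum accuracy 0.5.
    """
    primary = [1] * 10
    truth = [1, 1, 1, 1, 1, 1, 1, 1, 0, 0]
    #          seven confident correct | 1 decreased-correct | errors at 0% and 60%
    n_agree = [5, 5, 5, 4, 4, 3, 3, 1, 0, 3]
    return cohort_from_levels(primary, truth, n_agree)


def random_cohort(rng, n=None, k=None, with_truth=True):
    n = n or int(rng.integers(2, 51))
    k = k or int(rng.integers(1, 6))
    primary = rng.integers(0, 2, n)
    subs = rng.integers(0, 2, (n, k))
    truth = rng.integers(0, 2, n) if with_truth else None
    return make_cohort(primary=primary, subs=subs, truth=truth)
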