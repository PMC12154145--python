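import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import emmon as em
from emmon.bootstrap import BootstrapSpec
from emmon.exceptions import InvalidRecordError, PolicyMismatchError, TruthRequiredError
from emmon.monitor import CaseRecord, _monotone_repair

from conftest import cohort_from_levels


class TestComputeAgreement:
    @pytest.mark.parametrize(
        "primary,subs,n_agree",
        [
            (1, (1, 1, 1, 0, 0), 3),  # 60% agreement
            (0, (0, 0, 0, 0, 0), 5),  # unanimity
            (1, (0, 0, 0, 0, 0), 0),  # full disagreement
        ],
    )
    def test_counts_matches_by_hand(self, primary, subs, n_agree):
        rec = CaseRecord(case_id="c", primary_pred=primary, sub_preds=subs)
        res = em.compute_agreement(rec)
        assert res.n_agree == n_agree
        assert res.agreement == pytest.approx(n_agree / 5)

    def test_empty_sub_predictions_invalid(self):
        with pytest.raises(InvalidRecordError):
            CaseRecord(case_id="c", primary_pred=1, sub_preds=())

    @given(
        primary=st.integers(0, 1),
        subs=st.lists(st.integers(0, 1), min_size=1, max_size=8),
    )
    def test_permutation_invariance(self, primary, subs):
        base = em.compute_agreement(CaseRecord("c", primary, tuple(subs)))
        perm = em.compute_agreement(CaseRecord("c", primary, tuple(reversed(subs))))
        assert base.n_agree == perm.n_agree

    def test_agreement_table_matches_per_record_loop(self):
        rng = np.random.default_rng(0)
        cohort = em.make_cohort(
            primary=rng.integers(0, 2, 30), subs=rng.integers(0, 2, (30, 5))
        )
        tab = em.agreement_table(cohort)
        for i, row in cohort.iterrows():
            rec = CaseRecord(row["case_id"], row["primary"],
                             tuple(row[f"sub_{j}"] for j in range(1, 6)))
            assert tab.loc[i, "n_agree"] == em.compute_agreement(rec).n_agree


class TestLabelFlipInvariance:
    def test_flipping_all_labels_preserves_crosstab_and_summary(self):
        rng = np.random.default_rng(1)
        primary = rng.integers(0, 2, 200)
        subs = rng.integers(0, 2, (200, 5))
        truth = rng.integers(0, 2, 200)
        a = em.make_cohort(primary=primary, subs=subs, truth=truth)
        b = em.make_cohort(primary=1 - primary, subs=1 - subs, truth=1 - truth)
        ct_a, ct_b = em.cross_tab(a), em.cross_tab(b)
        assert ct_a["count"].tolist() == ct_b["count"].tolist()
        # strata swap signs but counts/accuracies transpose exactly
        sym = em.ThresholdPolicy(positive=em.default_policy().positive,
                                 negative=em.default_policy().positive, k=5)
        sa, sb = em.stratum_summary(a, sym), em.stratum_summary(b, sym)
        for stratum in ("increased", "similar", "decreased"):
            assert sa.loc[("positive", stratum), "count"] == sb.loc[("negative", stratum), "count"]


class TestStratify:
    @pytest.mark.parametrize(
        "level,sign,expected",
        [(100, "positive", "increased"), (40, "positive", "decreased"),
         (20, "negative", "similar")],
    )
    def test_default_policy_assignments(self, level, sign, expected):
        res = em.AgreementResult("c", n_agree=level // 20, agreement=level / 100)
        assert em.stratify(res, 1 if sign == "positive" else 0, em.default_policy()) == expected

    def test_k_mismatch_raises(self):
        cohort = em.make_cohort(primary=[1], subs=[[1, 1, 1]])
        with pytest.raises(PolicyMismatchError):
            em.stratify_cohort(cohort, em.default_policy())

    def test_cohort_stratification_consistent_with_summary_counts(self):
        rng = np.random.default_rng(2)
        cohort = em.make_cohort(
            primary=rng.integers(0, 2, 300), subs=rng.integers(0, 2, (300, 5)),
            truth=rng.integers(0, 2, 300),
        )
        pol = em.default_policy()
        strata = em.stratify_cohort(cohort, pol)
        summ = em.stratum_summary(cohort, pol)
        for sign, v in (("positive", 1), ("negative", 0)):
            for s in ("increased", "similar", "decreased"):
                brute = sum(
                    1 for i in range(len(cohort))
                    if cohort["primary"].iloc[i] == v and strata.iloc[i] == s
                )
                assert summ.loc[(sign, s), "count"] == brute


class TestCrossTab:
    def test_reported_partition_of_published_monitoring_cohort(self):
        # reconstruct a 2,919-case cohort with the published four-cell counts
        counts = {"full_agreement_correct": 1479, "partial_agreement_correct": 848,
                  "partial_agreement_incorrect": 454, "full_agreement_incorrect": 138}
        primary, truth, n_agree = [], [], []
        for cell, n in counts.items():
            full = cell.startswith("full")
            correct = cell.endswith("_correct")
            primary += [1] * n
            truth += [1] * n if correct else [0] * n
            n_agree += [5 if full else 2] * n
        ct = em.cross_tab(cohort_from_levels(primary, truth, n_agree))
        assert ct["count"].sum() == 2919
        assert ct["share_pct"].tolist()[:3] == [51, 29, 16]
        assert ct.loc["full_agreement_correct", "share"] == pytest.approx(1479 / 2919)

    def test_degenerate_unanimous_cohort_single_cell(self):
        cohort = cohort_from_levels([1] * 4, [1] * 4, [5] * 4)
        ct = em.cross_tab(cohort)
        assert ct.loc["full_agreement_correct", "share_pct"] == 100
        assert ct["count"].tolist() == [4, 0, 0, 0]

    def test_one_case_per_cell_uniform_shares(self):
        cohort = cohort_from_levels([1, 1, 1, 1], [1, 1, 0, 0], [5, 3, 3, 5])
        ct = em.cross_tab(cohort)
        assert ct["count"].tolist() == [1, 1, 1, 1]
        assert ct["share_pct"].tolist() == [25, 25, 25, 25]

    def test_zero_agreement_counts_as_partial(self):
        ct = em.cross_tab(cohort_from_levels([1, 1], [1, 1], [0, 5]))
        assert ct.loc["partial_agreement_correct", "count"] == 1

    def test_counts_sum_to_cohort_size_and_split_by_predicted_sign(self):
        rng = np.random.default_rng(3)
        cohort = em.make_cohort(
            primary=rng.integers(0, 2, 123), subs=rng.integers(0, 2, (123, 4)),
            truth=rng.integers(0, 2, 123),
        )
        ct = em.cross_tab(cohort)
        assert ct["count"].sum() == 123
        assert (ct["n_pred_positive"] + ct["n_pred_negative"]).tolist() == ct["count"].tolist()

    def test_truth_required(self):
        with pytest.raises(TruthRequiredError):
            em.cross_tab(em.make_cohort(primary=[1], subs=[[1]]))


class TestStratumSummary:
    def test_all_increased_correct_gives_unit_accuracy(self):
        cohort = cohort_from_levels([1] * 3, [1] * 3, [5] * 3)
        summ = em.stratum_summary(cohort, em.default_policy())
        assert summ.loc[("positive", "increased"), "accuracy"] == 1.0

    def test_hand_enumerated_decreased_stratum(self, ten_case_cohort):
        summ = em.stratum_summary(ten_case_cohort, em.default_policy())
        assert summ.loc[("positive", "decreased"), "count"] == 2
        assert summ.loc[("positive", "decreased"), "accuracy"] == pytest.approx(0.5)

    def test_empty_cells_report_nan_accuracy_and_shares_sum_to_one(self, ten_case_cohort):
        summ = em.stratum_summary(ten_case_cohort, em.default_policy())
        for s in ("increased", "similar", "decreased"):
            assert summ.loc[("negative", s), "count"] == 0
            assert np.isnan(summ.loc[("negative", s), "accuracy"])
        assert summ["share"].sum() == pytest.approx(1.0)

    def test_unlabelled_cases_counted_but_excluded_from_accuracy(self):
        cohort = cohort_from_levels([1, 1], [1, 1], [5, 5])
        cohort["truth"] = pd.array([1, None], dtype="Int64")
        summ = em.stratum_summary(cohort, em.default_policy())
        assert summ.loc[("positive", "increased"), "count"] == 2
        assert summ.loc[("positive", "increased"), "accuracy"] == 1.0


class TestMonotoneRepair:
    def test_stray_decreased_above_similar_demoted(self):
        levels = [0, 50, 100]
        fixed = _monotone_repair({0: "similar", 50: "decreased", 100: "increased"}, levels)
        assert fixed == {0: "similar", 50: "similar", 100: "increased"}

    def test_stray_increased_below_decreased_demoted(self):
        levels = [0, 50, 100]
        fixed = _monotone_repair({0: "increased", 50: "decreased", 100: "increased"}, levels)
        assert fixed == {0: "similar", 50: "similar", 100: "increased"}

    @given(st.lists(st.sampled_from(["decreased", "similar", "increased"]),
                    min_size=1, max_size=8))
    def test_repair_always_yields_monotone_assignment(self, strata):
        levels = list(range(len(strata)))
        fixed = _monotone_repair(dict(enumerate(strata)), levels)
        rank = {"decreased": 0, "similar": 1, "increased": 2}
        seq = [rank[fixed[l]] for l in levels]
        assert seq == sorted(seq)
        # already-monotone assignments are untouched
        orig = [rank[s] for s in strata]
        if orig == sorted(orig):
            assert fixed == dict(enumerate(strata))


class TestSelectThresholds:
    def test_well_separated_levels_recover_expected_shape(self):
        # strong difficulty correlation: level-100 far above baseline accuracy,
        # level-0 far below, middle levels near baseline
        rng = np.random.default_rng(42)
        n = 1200
        level = rng.integers(0, 6, n)
        acc_by_level = {0: 0.30, 1: 0.55, 2: 0.80, 3: 0.80, 4: 0.80, 5: 0.98}
        correct = rng.random(n) < np.vectorize(acc_by_level.get)(level)
        truth = rng.integers(0, 2, n)
        primary = np.where(correct, truth, 1 - truth)
        cohort = cohort_from_levels(primary, truth, level)
        pol = em.select_thresholds(
            cohort, bootstrap_params=BootstrapSpec(n_draws=300, seed=9)
        )
        for sign in ("positive", "negative"):
            mapping = getattr(pol, sign)
            assert mapping[100] == "increased"
            assert mapping[0] == "decreased"

    def test_identical_level_accuracies_all_similar(self):
        cohort = cohort_from_levels([1] * 12, [1] * 12, [0, 1, 2, 3, 4, 5] * 2)
        pol = em.select_thresholds(cohort, bootstrap_params=BootstrapSpec(n_draws=200, seed=1))
        assert set(pol.positive.values()) == {"similar"}

    def test_one_case_per_level_no_significance(self):
        cohort = cohort_from_levels(
            [1] * 6, [1, 1, 1, 0, 1, 1], [0, 1, 2, 3, 4, 5]
        )
        pol = em.select_thresholds(cohort, bootstrap_params=BootstrapSpec(n_draws=200, seed=2))
        assert set(pol.positive.values()) == {"similar"}

    def test_truth_required(self):
        cohort = em.make_cohort(primary=[1, 0], subs=[[1, 1], [0, 0]])
        with pytest.raises(TruthRequiredError):
            em.select_thresholds(cohort)


class TestConfidenceStratifier:
    def test_fixed_policy_predict_matches_functional_path(self, ten_case_cohort):
        clf = em.ConfidenceStratifier(policy=em.default_policy()).fit(ten_case_cohort)
        np.testing.assert_array_equal(
            clf.predict(ten_case_cohort),
            em.stratify_cohort(ten_case_cohort, em.default_policy()).to_numpy(),
        )
        assert clf.baseline_accuracy_["positive"] == pytest.approx(0.8)

    def test_sklearn_param_protocol_and_clone(self):
        clf = em.ConfidenceStratifier(alpha=0.01, n_draws=50, random_state=3)
        assert clf.get_params()["alpha"] == 0.01
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        cloned.set_params(alpha=0.10)
        assert cloned.alpha == 0.10 and clf.alpha == 0.01

    def test_fit_learns_policy_when_none_given(self):
        rng = np.random.default_rng(5)
        n = 600
        level = rng.integers(0, 6, n)
        acc = np.where(level == 5, 0.99, np.where(level == 0, 0.2, 0.8))
        correct = rng.random(n) < acc
        truth = rng.integers(0, 2, n)
        cohort = cohort_from_levels(np.where(correct, truth, 1 - truth), truth, level)
        clf = em.ConfidenceStratifier(n_draws=200, random_state=11).fit(cohort)
        assert clf.policy_.positive[100] == "increased"
        strata = clf.predict(cohort)
        assert set(strata) <= {"increased", "similar", "decreased"}

    def test_predict_before_fit_raises(self, ten_case_cohort):
        with pytest.raises(InvalidRecordError):
            em.ConfidenceStratifier().predict(ten_case_cohort)
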