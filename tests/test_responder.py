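import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabologenome.responder import (
    UndefinedScoreError,
    classify_responders,
    responder_score,
    score_feature_table,
    score_indices,
)

finite = st.floats(-1e6, 1e6)


class TestResponderScore:
    def test_improvement_vignette(self):
        assert responder_score(80, 100, 100, 100) == pytest.approx(-0.2)

    def test_equal_differential_change_scores_zero(self):
        assert responder_score(130, 100, 150, 120) == 0.0

    def test_zero_denominator_is_explicit_error(self):
        with pytest.raises(UndefinedScoreError):
            responder_score(1.0, 100.0, 1.0, -100.0)

    def test_feature_doubling_under_test_food(self):
        assert responder_score(0.04, 0.02, 0.02, 0.02) == pytest.approx(1.0)

    @given(finite, finite, finite, finite)
    @settings(max_examples=100, deadline=None)
    def test_swapping_periods_negates_numerator(self, t_end, t1, c_end, c1):
        if (c1 + t1) == 0:
            return
        s = responder_score(t_end, t1, c_end, c1)
        swapped = responder_score(c_end, c1, t_end, t1)
        assert swapped == pytest.approx(-s, rel=1e-9, abs=1e-9)

    @given(finite, finite, finite, finite, st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, t_end, t1, c_end, c1, k):
        if (c1 + t1) == 0 or (c1 + t1) * k == 0:
            return
        s = responder_score(t_end, t1, c_end, c1)
        sk = responder_score(t_end * k, t1 * k, c_end * k, c1 * k)
        assert sk == pytest.approx(s, rel=1e-6, abs=1e-9)


def _indices_frame(per_subject: dict) -> pd.DataFrame:
    rows = []
    for subject, entries in per_subject.items():
        for (name, timepoint), value in entries.items():
            rows.append(dict(subject=subject, timepoint=timepoint, name=name, value=value))
    return pd.DataFrame(rows)


def _vignette(g_iauc_t=70, g_iauc_c=100, g_auc_t=11000, g_auc_c=11550, i_iauc_t=80, i_iauc_c=100):
    """All six criterion inputs at week 2; week 4 kept neutral (no change)."""
    entries = {}
    for name, tv, cv in (
        ("glucose_iAUC_0_90", g_iauc_t, g_iauc_c),
        ("glucose_AUC_0_90", g_auc_t, g_auc_c),
        ("insulin_iAUC_0_90", i_iauc_t, i_iauc_c),
    ):
        entries[(name, "T2")] = tv
        entries[(name, "C2")] = cv
        entries[(name, "T3")] = cv
        entries[(name, "C3")] = cv
    return entries


class TestClassifyResponders:
    def test_all_three_criteria_met_at_week2(self):
        calls = classify_responders(_indices_frame({"S01": _vignette()}))
        week2 = calls[(calls.subject == "S01") & (calls.week == 2)].iloc[0]
        assert week2.criterion1 and week2.criterion2 and week2.criterion3
        assert week2.responder_at_week
        assert week2.responder_overall

    def test_twenty_percent_iauc_drop_fails_criterion1(self):
        v = _vignette(g_iauc_t=80, g_iauc_c=100)
        calls = classify_responders(_indices_frame({"S01": v}))
        week2 = calls[(calls.subject == "S01") & (calls.week == 2)].iloc[0]
        assert not week2.criterion1
        assert not week2.responder_overall

    def test_glucose_auc_increase_fails_criterion2(self):
        v = _vignette(g_auc_t=11600, g_auc_c=11550)
        calls = classify_responders(_indices_frame({"S01": v}))
        week2 = calls[(calls.subject == "S01") & (calls.week == 2)].iloc[0]
        assert week2.criterion1 and week2.criterion3 and not week2.criterion2
        assert not week2.responder_overall

    def test_boundary_exact_25_percent_drop_is_inclusive(self):
        v = _vignette(g_iauc_t=75.0, g_iauc_c=100.0)
        calls = classify_responders(_indices_frame({"S01": v}))
        assert calls[(calls.subject == "S01") & (calls.week == 2)].iloc[0].criterion1

    def test_missing_index_flags_exclusion_not_silent_drop(self):
        v = _vignette()
        del v[("insulin_iAUC_0_90", "T2")]
        calls = classify_responders(_indices_frame({"S01": v}))
        week2 = calls[(calls.subject == "S01") & (calls.week == 2)].iloc[0]
        assert week2.excluded
        assert not week2.responder_at_week

    def test_constructed_cohort_recovers_exactly_the_planted_responders(self):
        cohort = {}
        planted = {"S01", "S04", "S07"}
        for i in range(1, 9):
            subject = f"S{i:02d}"
            if subject in planted:
                cohort[subject] = _vignette()
            else:
                cohort[subject] = _vignette(g_iauc_t=90)  # criterion 1 fails
        calls = classify_responders(_indices_frame(cohort))
        responders = set(calls[calls.responder_overall].subject.unique())
        assert responders == planted


class TestScoreFeatureTable:
    @staticmethod
    def _table_and_meta(values_by_label, feature="TaxonA", subject="S01"):
        meta = pd.DataFrame(
            [
                dict(sample_id=f"{subject}{lab}", subject=subject, timepoint=lab)
                for lab in ("T1", "T2", "T3", "C1", "C2", "C3")
            ]
        )
        table = pd.DataFrame(
            {feature: [values_by_label.get(lab, 0.0) for lab in ("T1", "T2", "T3", "C1", "C2", "C3")]},
            index=[f"{subject}{lab}" for lab in ("T1", "T2", "T3", "C1", "C2", "C3")],
        )
        return table, meta

    def test_doubled_taxon_scores_one(self):
        table, meta = self._table_and_meta(
            {"T1": 0.02, "T3": 0.04, "C1": 0.02, "C3": 0.02, "T2": 0.02, "C2": 0.02}
        )
        scores, _ = score_feature_table(table, meta)
        week4 = scores[scores.week == 4].iloc[0]
        assert week4.score == pytest.approx(1.0)

    def test_zero_denominator_subject_excluded_and_logged(self):
        table, meta = self._table_and_meta(
            {"T1": 0.0, "C1": 0.0, "T3": 0.01, "C3": 0.01, "T2": 0.01, "C2": 0.01}
        )
        scores, excl = score_feature_table(table, meta)
        assert scores.empty
        assert (excl.reason.str.contains("zero denominator")).any()

    def test_all_zero_feature_warns_and_yields_empty_table(self):
        table, meta = self._table_and_meta({})
        with pytest.warns(UserWarning, match="all subjects excluded"):
            scores, excl = score_feature_table(table, meta)
        assert scores.empty and not excl.empty


def test_score_indices_week2_uses_T2_C2(default_cohort):
    from metabologenome.ogtt import glucose_tolerance_indices

    indices = glucose_tolerance_indices(default_cohort.ogtt_curves)
    scores = score_indices(indices)
    assert set(scores.week.unique()) == {2, 4}
    # spot-check one subject against the formula applied by hand
    name, subject = "glucose_AUC_0_90", "S01"
    wide = indices.pivot_table(index="subject", columns=["name", "timepoint"], values="value")
    t1, c1 = wide.loc[subject, (name, "T1")], wide.loc[subject, (name, "C1")]
    t2, c2 = wide.loc[subject, (name, "T2")], wide.loc[subject, (name, "C2")]
    expected = ((t2 - t1) - (c2 - c1)) / ((c1 + t1) / 2)
    got = scores[(scores.subject == subject) & (scores.quantity == name) & (scores.week == 2)]
    assert got.score.iloc[0] == pytest.approx(expected)
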