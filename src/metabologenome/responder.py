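"""Responder scoring and classification for the crossover trial.

The per-subject *responder score* of any quantity X (a glucose-tolerance
index, a taxon abundance, a metabolite peak area) is the normalized
difference-in-differences between the test (T) and control (C) periods:

    score = ((T_end - T1) - (C_end - C1)) / mean(C1, T1)

where T1/C1 are the period baselines and T_end/C_end the values after 2 or
4 weeks of intervention. For indices where a decrease is an improvement
(glucose/insulin AUC and iAUC), a negative score means improvement.

*Responder classification* uses three criteria, each comparing the test
and control periods at the same week w (T2 vs C2, or T3 vs C3):

1. glucose iAUC (0-90 min) decreased by at least 25%  (Tw <= 0.75 * Cw);
2. glucose AUC (0-90 min) decreased                   (Tw <  Cw);
3. insulin iAUC (0-90 min) decreased by at least 15%  (Tw <= 0.85 * Cw).

A subject is a responder at week w if all three hold at that week, and a
responder overall if they hold at either week.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "UndefinedScoreError",
    "responder_score",
    "classify_responders",
    "score_indices",
    "score_feature_table",
]


class UndefinedScoreError(ValueError):
    """The responder score denominator mean(C1, T1) is zero."""


#: week -> (test timepoint, control timepoint) pairs used throughout
WEEK_TIMEPOINTS = {2: ("T2", "C2"), 4: ("T3", "C3")}


def responder_score(t_end: float, t1: float, c_end: float, c1: float) -> float:
    """((t_end - t1) - (c_end - c1)) / mean(c1, t1).

    Raises :class:`UndefinedScoreError` when the denominator is zero rather
    than propagating NaN/inf.
    """
    denom = 0.5 * (c1 + t1)
    if denom == 0:
        raise UndefinedScoreError("mean(C1, T1) is zero; score undefined")
    return float(((t_end - t1) - (c_end - c1)) / denom)


def classify_responders(indices: pd.DataFrame) -> pd.DataFrame:
    """Apply the three responder criteria to every subject.

    Parameters
    ----------
    indices : tidy frame with columns subject, timepoint, name, value
        (as produced by :func:`metabologenome.ogtt.glucose_tolerance_indices`).

    Returns
    -------
    One row per subject x week with boolean columns criterion1..criterion3,
    responder_at_week, responder_overall, and an ``excluded`` flag set when
    any required index value is missing for that subject (criteria columns
    are then NA, and the subject never counts as a responder).
    """
    wide = indices.pivot_table(
        index="subject", columns=["name", "timepoint"], values="value", aggfunc="first"
    )
    rows = []
    for subject in wide.index:
        week_calls = {}
        excluded = False
        for week, (tw, cw) in WEEK_TIMEPOINTS.items():
            try:
                g_iauc_t = wide.loc[subject, ("glucose_iAUC_0_90", tw)]
                g_iauc_c = wide.loc[subject, ("glucose_iAUC_0_90", cw)]
                g_auc_t = wide.loc[subject, ("glucose_AUC_0_90", tw)]
                g_auc_c = wide.loc[subject, ("glucose_AUC_0_90", cw)]
                i_iauc_t = wide.loc[subject, ("insulin_iAUC_0_90", tw)]
                i_iauc_c = wide.loc[subject, ("insulin_iAUC_0_90", cw)]
            except KeyError:
                week_calls[week] = None
                excluded = True
                continue
            vals = (g_iauc_t, g_iauc_c, g_auc_t, g_auc_c, i_iauc_t, i_iauc_c)
            if any(pd.isna(v) for v in vals):
                week_calls[week] = None
                excluded = True
                continue
            c1 = bool(g_iauc_t <= 0.75 * g_iauc_c)
            c2 = bool(g_auc_t < g_auc_c)
            c3 = bool(i_iauc_t <= 0.85 * i_iauc_c)
            week_calls[week] = (c1, c2, c3)
        overall = any(calls is not None and all(calls) for calls in week_calls.values())
        for week, calls in week_calls.items():
            if calls is None:
                rows.append(
                    dict(
                        subject=subject,
                        week=week,
                        criterion1=pd.NA,
                        criterion2=pd.NA,
                        criterion3=pd.NA,
                        responder_at_week=False,
                        responder_overall=overall,
                        excluded=True,
                    )
                )
            else:
                rows.append(
                    dict(
                        subject=subject,
                        week=week,
                        criterion1=calls[0],
                        criterion2=calls[1],
                        criterion3=calls[2],
                        responder_at_week=all(calls),
                        responder_overall=overall,
                        excluded=excluded,
                    )
                )
    return pd.DataFrame(rows)


def score_indices(indices: pd.DataFrame, weeks=(2, 4)) -> pd.DataFrame:
    """Responder scores for every glucose-tolerance index.

    Week-2 scores use T2/C2 in place of T3/C3 in the score formula. Returns
    columns subject, quantity, week, score.
    """
    wide = indices.pivot_table(
        index="subject", columns=["name", "timepoint"], values="value", aggfunc="first"
    )
    rows = []
    for name in indices["name"].unique():
        for week in weeks:
            tw, cw = WEEK_TIMEPOINTS[week]
            for subject in wide.index:
                try:
                    t1 = wide.loc[subject, (name, "T1")]
                    c1 = wide.loc[subject, (name, "C1")]
                    t_end = wide.loc[subject, (name, tw)]
                    c_end = wide.loc[subject, (name, cw)]
                except KeyError:
                    continue
                if any(pd.isna(v) for v in (t1, c1, t_end, c_end)) or (c1 + t1) == 0:
                    continue
                rows.append(
                    dict(
                        subject=subject,
                        quantity=name,
                        week=week,
                        score=responder_score(t_end, t1, c_end, c1),
                    )
                )
    return pd.DataFrame(rows, columns=["subject", "quantity", "week", "score"])


def score_feature_table(
    table: pd.DataFrame, metadata: pd.DataFrame, weeks=(2, 4)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Responder scores for every feature (taxon/metabolite) column.

    Parameters
    ----------
    table : samples x features frame (nonnegative; NaN = missing), indexed
        by sample id.
    metadata : per-sample frame with columns sample_id, subject, timepoint.

    Returns
    -------
    (scores, exclusions): scores has columns subject, quantity, week,
    score; exclusions logs every (subject, feature, week) dropped for a
    zero denominator or missing value, with a reason. Features for which
    every subject is excluded yield no score rows and trigger a warning.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    sample_of = {
        (row["subject"], row["timepoint"]): sid
        for sid, row in meta.iterrows()
        if sid in table.index
    }
    subjects = sorted(meta["subject"].unique())
    score_rows, excl_rows = [], []
    for feature in table.columns:
        col = table[feature]
        feature_has_rows = False
        for week in weeks:
            tw, cw = WEEK_TIMEPOINTS[week]
            for subject in subjects:
                vals = {}
                ok = True
                for label in ("T1", "C1", tw, cw):
                    sid = sample_of.get((subject, label))
                    v = col.get(sid) if sid is not None else None
                    if v is None or pd.isna(v):
                        excl_rows.append(
                            dict(subject=subject, quantity=feature, week=week,
                                 reason=f"missing value at {label}")
                        )
                        ok = False
                        break
                    vals[label] = float(v)
                if not ok:
                    continue
                if 0.5 * (vals["C1"] + vals["T1"]) == 0:
                    excl_rows.append(
                        dict(subject=subject, quantity=feature, week=week,
                             reason="zero denominator (absent at both baselines)")
                    )
                    continue
                score_rows.append(
                    dict(
                        subject=subject,
                        quantity=feature,
                        week=week,
                        score=responder_score(vals[tw], vals["T1"], vals[cw], vals["C1"]),
                    )
                )
                feature_has_rows = True
        if not feature_has_rows:
            warnings.warn(f"feature {feature!r}: all subjects excluded from responder scoring")
    scores = pd.DataFrame(score_rows, columns=["subject", "quantity", "week", "score"])
    exclusions = pd.DataFrame(excl_rows, columns=["subject", "quantity", "week", "reason"])
    return scores, exclusions
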