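"""Responder-association analysis and the end-to-end pipeline.

This is the stage that asks which baseline characteristics and which
intestinal-environment *changes* track the per-subject glucose-tolerance
improvement:

* ``baseline_correlation`` — Spearman (and Pearson) correlation between a
  subject's baseline glucose-tolerance index and their responder score for
  that index. A negative correlation for glucose AUC means subjects with
  worse baseline tolerance improved more.
* ``feature_change_correlation`` — per feature x index x week, Spearman
  correlation between the feature's responder score (the same normalized
  difference-in-differences formula applied to a taxon or metabolite) and
  the index responder score.
* ``consistency_filter`` — the two-time-point screen: a feature-index
  association is *consistent* when it is significant at alpha at BOTH
  weeks (2 and 4) with the same correlation sign. The screen uses raw
  p-values — cross-week sign-consistent replication is the multiplicity
  control — but BH-adjusted values are carried alongside so the screen can
  be tightened.
* ``run_pipeline`` — orchestrates the full analysis from a cohort dataset
  or written manifest directory: outcome effect sizes, differential
  features, beta diversity / ordination / PERMANOVA, responder calls,
  baseline and feature-change correlations, and consistency calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecology, features, ogtt, responder
from .simulate import CohortDataset
from .stats import DegenerateDataError, bh_fdr, hedges_g_paired, paired_t, spearman_test

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "baseline_correlation",
    "feature_change_correlation",
    "consistency_filter",
    "run_pipeline",
    "write_report",
]

#: glucose-tolerance indices used as responder-score targets
TARGET_INDICES = (
    "glucose_AUC_0_90",
    "glucose_iAUC_0_90",
    "insulin_AUC_0_90",
    "insulin_iAUC_0_90",
)

#: the seven primary/secondary trial outcomes summarized per week
OUTCOMES = (
    "glucose_AUC_0_120",
    "insulin_AUC_0_120",
    "glucose_iAUC_0_120",
    "insulin_iAUC_0_120",
    "fasting_glucose",
    "fasting_insulin",
    "stool_frequency",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis conventions; every choice the pipeline makes is a field here."""

    iauc_convention: str = "positive_only"
    alpha: float = 0.05
    min_mean_abundance: float = 0.001
    detect_frac: float = 0.75
    lfc_base: int = 2
    baseline_definition: str = "mean_C1_T1"  # or "T1"
    mds_dims: int = 2
    n_permutations: int = 999
    min_subjects: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    """Bundle of every pipeline output table plus the run log."""

    outcome_effects: pd.DataFrame
    differential: dict
    distances: dict
    ordinations: dict
    permanova: dict
    responder_calls: pd.DataFrame
    index_scores: pd.DataFrame
    baseline_assoc: pd.DataFrame
    feature_assoc: pd.DataFrame
    consistency: pd.DataFrame
    exclusions: pd.DataFrame
    run_log: dict = field(default_factory=dict)


def _baseline_values(indices: pd.DataFrame, definition: str) -> pd.DataFrame:
    """Per subject x index baseline value: mean of C1 and T1 (default) or T1."""
    base = indices[indices["timepoint"].isin(("T1", "C1"))]
    if definition == "T1":
        base = base[base["timepoint"] == "T1"]
    elif definition != "mean_C1_T1":
        raise ValueError(f"unknown baseline definition: {definition!r}")
    return base.groupby(["subject", "name"])["value"].mean().reset_index()


def baseline_correlation(
    index_scores: pd.DataFrame,
    indices: pd.DataFrame,
    targets=TARGET_INDICES,
    baseline_definition: str = "mean_C1_T1",
    min_subjects: int = 5,
) -> pd.DataFrame:
    """Correlate each index's baseline value with its own responder score.

    Returns one row per (index, week): Spearman rho/p, Pearson r/p, and n.
    """
    baselines = _baseline_values(indices, baseline_definition)
    rows = []
    for name in targets:
        base = baselines[baselines["name"] == name].set_index("subject")["value"]
        for week, grp in index_scores[index_scores["quantity"] == name].groupby("week"):
            merged = grp.set_index("subject")["score"].to_frame("score").join(
                base.to_frame("baseline"), how="inner"
            ).dropna()
            if len(merged) < min_subjects:
                raise ValueError(
                    f"{name} week {week}: only {len(merged)} subjects with "
                    f"baseline and score; need {min_subjects}"
                )
            rho, p, n = spearman_test(merged["baseline"], merged["score"])
            from scipy import stats as sps

            r, rp = sps.pearsonr(merged["baseline"], merged["score"])
            rows.append(
                dict(
                    feature=name, layer="index", target=name, week=week,
                    rho=rho, p=p, pearson_r=float(r), pearson_p=float(rp), n=n,
                )
            )
    return pd.DataFrame(rows)


def feature_change_correlation(
    feature_scores: pd.DataFrame,
    index_scores: pd.DataFrame,
    layer: str,
    targets=TARGET_INDICES,
    min_subjects: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every feature's responder score with every index score.

    Both score tables are tidy (subject, quantity, week, score). Features
    with fewer than ``min_subjects`` usable subjects at a week, or constant
    scores, are skipped with a reason. Returns (associations, skipped).
    """
    rows, skipped = [], []
    idx_by = {
        (name, week): grp.set_index("subject")["score"]
        for (name, week), grp in index_scores.groupby(["quantity", "week"])
    }
    for (feature, week), grp in feature_scores.groupby(["quantity", "week"]):
        f_scores = grp.set_index("subject")["score"]
        for target in targets:
            t_scores = idx_by.get((target, week))
            if t_scores is None:
                skipped.append(dict(feature=feature, target=target, week=week,
                                    reason="no index scores at this week"))
                continue
            shared = f_scores.index.intersection(t_scores.index)
            if len(shared) < min_subjects:
                skipped.append(dict(feature=feature, target=target, week=week,
                                    reason=f"only {len(shared)} usable subjects"))
                continue
            try:
                rho, p, n = spearman_test(f_scores.loc[shared], t_scores.loc[shared])
            except DegenerateDataError as exc:
                skipped.append(dict(feature=feature, target=target, week=week,
                                    reason=str(exc)))
                continue
            rows.append(dict(feature=feature, layer=layer, target=target,
                             week=week, rho=rho, p=p, n=n))
    assoc = pd.DataFrame(rows, columns=["feature", "layer", "target", "week", "rho", "p", "n"])
    skipped_df = pd.DataFrame(skipped, columns=["feature", "target", "week", "reason"])
    if not assoc.empty:
        assoc["q"] = np.nan
        for (_, week), grp in assoc.groupby(["target", "week"]):
            assoc.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    return assoc, skipped_df


def consistency_filter(assoc: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Two-time-point consistency screen over an association table.

    A feature x target pair is *consistent* when p < alpha at both weeks 2
    and 4 with the same rho sign (raw p; adjusted q carried through when
    present). Pairs missing a week are marked unevaluable. Output is
    sorted by the worse (max) of the two p-values.
    """
    rows = []
    for (feature, target), grp in assoc.groupby(["feature", "target"]):
        by_week = {int(w): r for w, r in grp.set_index("week").iterrows()}
        if 2 not in by_week or 4 not in by_week:
            rows.append(dict(feature=feature, target=target, rho_week2=np.nan,
                             rho_week4=np.nan, p_week2=np.nan, p_week4=np.nan,
                             q_week2=np.nan, q_week4=np.nan,
                             consistent=False, evaluable=False))
            continue
        w2, w4 = by_week[2], by_week[4]
        consistent = bool(
            w2["p"] < alpha
            and w4["p"] < alpha
            and np.sign(w2["rho"]) == np.sign(w4["rho"])
            and w2["rho"] != 0
        )
        rows.append(
            dict(
                feature=feature, target=target,
                rho_week2=float(w2["rho"]), rho_week4=float(w4["rho"]),
                p_week2=float(w2["p"]), p_week4=float(w4["p"]),
                q_week2=float(w2.get("q", np.nan)), q_week4=float(w4.get("q", np.nan)),
                consistent=consistent, evaluable=True,
            )
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["max_p"] = out[["p_week2", "p_week4"]].max(axis=1)
        out = out.sort_values("max_p", kind="mergesort").reset_index(drop=True)
    return out


def run_pipeline(
    dataset: "CohortDataset | str | Path",
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> PipelineResult:
    """Run the complete analysis on a cohort dataset or manifest directory.

    The result is a pure function of (dataset, config, seed); ``seed``
    only drives the PERMANOVA permutations.
    """
    if not isinstance(dataset, CohortDataset):
        from .io import read_cohort

        dataset = read_cohort(dataset)

    curves = dataset.ogtt_curves
    indices = ogtt.glucose_tolerance_indices(curves, iauc_convention=config.iauc_convention)

    # (i) outcome panel: paired t + Hedge's g at C2-vs-T2 and C3-vs-T3
    meta = dataset.metadata
    stool = meta.rename(columns={"stool_frequency": "value"})[
        ["subject", "timepoint", "value"]
    ].assign(name="stool_frequency")
    panel = pd.concat([indices, stool[["subject", "timepoint", "name", "value"]]])
    wide = panel.pivot_table(index="subject", columns=["name", "timepoint"],
                             values="value", aggfunc="first")
    effect_rows = []
    for week, (tw, cw) in responder.WEEK_TIMEPOINTS.items():
        for name in OUTCOMES:
            if (name, cw) not in wide.columns or (name, tw) not in wide.columns:
                continue
            pair = wide[[(name, cw), (name, tw)]].dropna()
            c_vals = pair[(name, cw)].to_numpy()
            t_vals = pair[(name, tw)].to_numpy()
            try:
                eff = hedges_g_paired(c_vals, t_vals)
                t_stat, p, _ = paired_t(c_vals, t_vals)
            except DegenerateDataError:
                continue
            effect_rows.append(
                dict(outcome=name, comparison=f"{cw} vs {tw}", week=week, n=eff.n,
                     g=eff.g, g_ci_low=eff.g_ci_low, g_ci_high=eff.g_ci_high,
                     t=t_stat, p=p)
            )
    outcome_effects = pd.DataFrame(effect_rows)

    # feature tables: filter, then test
    abundance = features.filter_taxa(dataset.abundance, config.min_mean_abundance)
    metabolome = features.filter_metabolites(dataset.metabolome, config.detect_frac)
    differential = {}
    for layer, table in (("microbe", abundance), ("metabolite", metabolome)):
        for tp_a, tp_b in (("T1", "T3"), ("C3", "T3")):
            differential[f"{layer}_{tp_a}_{tp_b}"] = features.paired_feature_test(
                table, meta, tp_a, tp_b, min_pairs=config.min_subjects
            )

    # (iii) beta diversity, ordination, PERMANOVA (intra- vs inter-subject)
    d_micro = ecology.unifrac_matrix(abundance, dataset.tree, weighted=False)
    d_metab = ecology.correlation_distance_matrix(metabolome)
    subject_of = meta.set_index("sample_id")["subject"]
    distances = {"microbiome_unweighted_unifrac": d_micro,
                 "metabolome_spearman": d_metab}
    ordinations, permanova_results = {}, {}
    rng = np.random.default_rng(seed)
    for key, dmat in distances.items():
        coords, eigvals = ecology.classical_mds(dmat, k=config.mds_dims)
        total = np.abs(eigvals).sum()
        share = eigvals / total if total > 0 else eigvals
        ordinations[key] = (coords, share)
        permanova_results[key] = ecology.permanova(
            dmat,
            subject_of.loc[dmat.index],
            n_permutations=config.n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    # (iv) responder calls and index scores
    responder_calls = responder.classify_responders(indices)
    index_scores = responder.score_indices(indices)

    # (v) baseline correlations
    baseline_assoc = baseline_correlation(
        index_scores, indices,
        baseline_definition=config.baseline_definition,
        min_subjects=config.min_subjects,
    )

    # (vi) feature-change correlations + consistency screen
    assoc_frames, excl_frames = [], []
    for layer, table in (("microbe", abundance), ("metabolite", metabolome)):
        scores, excl = responder.score_feature_table(table, meta)
        assoc, skipped = feature_change_correlation(
            scores, index_scores, layer=layer, min_subjects=config.min_subjects
        )
        assoc_frames.append(assoc)
        excl_frames.append(excl.assign(layer=layer))
        excl_frames.append(
            skipped.rename(columns={"target": "quantity"}).assign(layer=layer)
            if not skipped.empty
            else pd.DataFrame()
        )
    feature_assoc = pd.concat(assoc_frames, ignore_index=True)
    exclusions = pd.concat([f for f in excl_frames if not f.empty], ignore_index=True) \
        if any(not f.empty for f in excl_frames) else pd.DataFrame()
    consistency = consistency_filter(feature_assoc, alpha=config.alpha)

    run_log = {
        "config": asdict(config),
        "seed": int(seed),
        "n_subjects": int(meta["subject"].nunique()),
        "n_samples": int(len(meta)),
        "n_taxa_tested": int(abundance.shape[1]),
        "n_metabolites_tested": int(metabolome.shape[1]),
        "lfc_base": config.lfc_base,
        "iauc_convention": config.iauc_convention,
        "permanova_seeds": {k: r.seed for k, r in permanova_results.items()},
    }
    return PipelineResult(
        outcome_effects=outcome_effects,
        differential=differential,
        distances=distances,
        ordinations=ordinations,
        permanova=permanova_results,
        responder_calls=responder_calls,
        index_scores=index_scores,
        baseline_assoc=baseline_assoc,
        feature_assoc=feature_assoc,
        consistency=consistency,
        exclusions=exclusions,
        run_log=run_log,
    )


def write_report(result: PipelineResult, directory) -> None:
    """Serialize every pipeline output table to TSV plus run_log.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fmt = "%.17g"

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(directory / name, sep="\t", index=index, na_rep="NA", float_format=fmt)

    _write(result.outcome_effects, "outcome_effects.tsv")
    for key, df in result.differential.items():
        _write(df, f"differential_{key}.tsv")
    for key, dmat in result.distances.items():
        _write(dmat, f"distance_{key}.tsv", index=True)
    for key, (coords, share) in result.ordinations.items():
        out = coords.copy()
        _write(out, f"mds_{key}.tsv", index=True)
        np.savetxt(directory / f"mds_{key}_eigenvalue_share.tsv", share, fmt=fmt)
    perm_rows = [
        dict(matrix=k, pseudo_F=r.pseudo_F, p=r.p,
             n_permutations=r.n_permutations, seed=r.seed)
        for k, r in result.permanova.items()
    ]
    _write(pd.DataFrame(perm_rows), "permanova.tsv")
    _write(result.responder_calls, "responder_calls.tsv")
    _write(result.index_scores, "index_responder_scores.tsv")
    _write(result.baseline_assoc, "baseline_correlations.tsv")
    _write(result.feature_assoc, "feature_change_correlations.tsv")
    _write(result.consistency, "consistency_calls.tsv")
    if not result.exclusions.empty:
        _write(result.exclusions, "exclusion_log.tsv")
    (directory / "run_log.json").write_text(
        json.dumps(result.run_log, indent=1, sort_keys=True)
    )
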