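"""Microbiome and metabolome feature-table preparation and paired testing.

Tables are pandas DataFrames with samples in rows (indexed by sample id)
and features in columns: relative abundances on the simplex for taxa,
nonnegative relative peak areas (NaN = not detected) for metabolites.

Filtering follows the trial's rules: taxa with mean relative abundance
below 0.001 over all samples are dropped (values are NOT renormalized
afterwards — downstream tests run on the observed relative abundances);
metabolites detected in fewer than 75% of samples are dropped. Paired
differential testing between two time points uses the Wilcoxon signed-rank
test per feature with Benjamini-Hochberg FDR across features within one
comparison and omics layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, wilcoxon_signed_rank

__all__ = [
    "aggregate_to_genus",
    "filter_taxa",
    "filter_metabolites",
    "prevotella_bacteroides_ratio",
    "paired_feature_test",
]

_RANK_PREFIX = re.compile(r"^[a-z]__")


def _genus_of(name: str) -> str:
    """Genus label from a semicolon-delimited lineage or a bare genus name.

    Lineages use rank prefixes (``d__;p__;...;g__Blautia``); a lineage whose
    genus slot is empty or absent maps to ``unclassified_<last known rank>``.
    """
    if ";" not in name:
        return name.strip()
    parts = [p.strip() for p in name.split(";")]
    last_known = ""
    for part in parts:
        value = _RANK_PREFIX.sub("", part)
        if part.startswith("g__"):
            if value:
                return value
        elif value:
            last_known = value
    return f"unclassified_{last_known}" if last_known else "unclassified"


def aggregate_to_genus(table: pd.DataFrame) -> pd.DataFrame:
    """Sum columns sharing a genus; conserves row mass exactly."""
    if table.empty:
        raise ValueError("empty abundance table")
    genus = [_genus_of(str(c)) for c in table.columns]
    out = table.T.groupby(pd.Index(genus, name=table.columns.name)).sum(min_count=1).T
    return out


def filter_taxa(table: pd.DataFrame, min_mean: float = 0.001) -> pd.DataFrame:
    """Drop taxa whose mean relative abundance over all samples is below
    ``min_mean`` (strictly; a mean exactly at the threshold is retained).
    Remaining values are not renormalized."""
    if table.empty:
        raise ValueError("empty abundance table")
    keep = table.mean(axis=0) >= min_mean
    if not keep.any():
        raise ValueError("all taxa fall below the mean-abundance threshold")
    return table.loc[:, keep]


def filter_metabolites(table: pd.DataFrame, detect_frac: float = 0.75) -> pd.DataFrame:
    """Drop metabolites detected (non-missing) in fewer than ``detect_frac``
    of samples; detection in exactly that fraction retains the feature."""
    if table.empty:
        raise ValueError("empty metabolome table")
    keep = table.notna().mean(axis=0) >= detect_frac
    if not keep.any():
        raise ValueError("all metabolites fall below the detection threshold")
    return table.loc[:, keep]


def prevotella_bacteroides_ratio(table: pd.DataFrame) -> pd.Series:
    """Per-sample Prevotella/Bacteroides ratio on a genus-level table.

    All genera whose name starts with "Prevotella" are summed (SILVA-style
    split genera such as Prevotella_2, Prevotella_7). Samples with zero
    Bacteroides get NaN (undefined, flagged by missingness).
    """
    prev_cols = [c for c in table.columns if str(c).startswith("Prevotella")]
    if "Bacteroides" not in table.columns or not prev_cols:
        raise ValueError("table lacks Prevotella and/or Bacteroides genera")
    prev = table[prev_cols].sum(axis=1)
    bact = table["Bacteroides"]
    ratio = prev / bact.where(bact > 0)
    ratio.name = "prevotella_bacteroides_ratio"
    return ratio


@dataclass(frozen=True)
class _Pairing:
    subjects: list
    rows_a: list
    rows_b: list


def _pair_samples(metadata: pd.DataFrame, tp_a: str, tp_b: str) -> _Pairing:
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    by_tp = {
        tp: meta.loc[meta["timepoint"] == tp, "subject"] for tp in (tp_a, tp_b)
    }
    sample_of = {
        tp: {subj: sid for sid, subj in series.items()} for tp, series in by_tp.items()
    }
    shared = sorted(set(sample_of[tp_a]) & set(sample_of[tp_b]))
    return _Pairing(
        subjects=shared,
        rows_a=[sample_of[tp_a][s] for s in shared],
        rows_b=[sample_of[tp_b][s] for s in shared],
    )


def paired_feature_test(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    timepoint_a: str,
    timepoint_b: str,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Per-feature Wilcoxon signed-rank test between two time points.

    Pairs samples by subject; subjects missing either sample (or with a
    missing value for a given feature) are dropped pairwise. p-values are
    BH-adjusted across the features of this comparison. The fold change is
    ``log2(mean_b / mean_a)``; when a mean is zero, an epsilon of half the
    smallest positive mean in the comparison is added to both means.

    Returns columns feature, comparison, lfc, p, q, n_pairs, degenerate
    (True when all paired differences are zero; p is then reported as 1).
    """
    pairing = _pair_samples(metadata, timepoint_a, timepoint_b)
    if len(pairing.subjects) < min_pairs:
        raise ValueError(
            f"only {len(pairing.subjects)} subjects with both {timepoint_a} "
            f"and {timepoint_b}; need at least {min_pairs}"
        )
    a = table.loc[pairing.rows_a].to_numpy(dtype=float)
    b = table.loc[pairing.rows_b].to_numpy(dtype=float)

    all_means = np.concatenate(
        [np.nanmean(a, axis=0), np.nanmean(b, axis=0)]
    )
    positive = all_means[np.isfinite(all_means) & (all_means > 0)]
    eps = 0.5 * positive.min() if positive.size else 1.0

    rows = []
    comparison = f"{timepoint_a}-{timepoint_b}"
    for j, feature in enumerate(table.columns):
        xa, xb = a[:, j], b[:, j]
        ok = np.isfinite(xa) & np.isfinite(xb)
        n = int(ok.sum())
        if n < min_pairs:
            continue
        xa, xb = xa[ok], xb[ok]
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        if mean_a == 0 or mean_b == 0:  # epsilon on both sides keeps lfc finite
            num, den = mean_b + eps, mean_a + eps
        else:
            num, den = mean_b, mean_a
        lfc = float(np.log2(num / den))
        diffs = xb - xa
        if np.all(diffs == 0):
            rows.append((feature, comparison, lfc, 1.0, n, True))
        else:
            _, p = wilcoxon_signed_rank(diffs)
            rows.append((feature, comparison, lfc, p, n, False))
    out = pd.DataFrame(
        rows, columns=["feature", "comparison", "lfc", "p", "n_pairs", "degenerate"]
    )
    if out.empty:
        raise ValueError("no feature had enough complete pairs")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out[["feature", "comparison", "lfc", "p", "q", "n_pairs", "degenerate"]]
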