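"""Readers for cohort manifests written by :func:`metabologenome.simulate.write_cohort`.

All tables are plain TSV with a header row and a ``sample_id`` column;
missing metabolome cells are the literal string "NA"; the tree is newick
with branch lengths; truth.json is optional (real datasets have none).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import CohortConfig, CohortDataset

__all__ = ["read_cohort", "read_feature_table", "SchemaError"]


class SchemaError(ValueError):
    """A manifest file is missing or malformed; message names the file and column."""


def _require_columns(df: pd.DataFrame, columns, path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_feature_table(path) -> pd.DataFrame:
    """Samples x features TSV indexed by sample_id; "NA" -> missing."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    _require_columns(df, ["sample_id"], path)
    return df.set_index("sample_id")


def read_cohort(directory) -> CohortDataset:
    """Load a written cohort directory back into a :class:`CohortDataset`.

    Fails fast with :class:`SchemaError` naming the offending file/column.
    ``truth.json`` is optional; without it the dataset carries an empty
    truth block and the default configuration.
    """
    directory = Path(directory)
    for name in ("ogtt.tsv", "abundance.tsv", "metabolome.tsv", "tree.nwk", "metadata.tsv"):
        if not (directory / name).exists():
            raise SchemaError(f"{directory / name}: file missing")

    ogtt = pd.read_csv(directory / "ogtt.tsv", sep="\t")
    _require_columns(
        ogtt, ["sample_id", "subject", "timepoint", "analyte", "minute", "value"],
        directory / "ogtt.tsv",
    )
    abundance = read_feature_table(directory / "abundance.tsv")
    metabolome = read_feature_table(directory / "metabolome.tsv")
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t")
    _require_columns(
        metadata, ["sample_id", "subject", "period", "week", "timepoint"],
        directory / "metadata.tsv",
    )
    tree = (directory / "tree.nwk").read_text().strip()
    if not tree.endswith(";"):
        raise SchemaError(f"{directory / 'tree.nwk'}: not a newick string")

    truth: dict = {}
    config = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        cfg = truth.pop("config", None)
        if cfg is not None:
            cfg["times"] = tuple(cfg["times"])
            config = CohortConfig(**cfg)
    return CohortDataset(
        config=config if config is not None else CohortConfig(),
        ogtt=ogtt,
        abundance=abundance,
        metabolome=metabolome,
        tree=tree,
        metadata=metadata,
        truth=truth,
    )
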