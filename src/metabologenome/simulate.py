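"""Synthetic crossover-trial cohort generator.

Emulates a two-period randomized crossover dietary trial: every subject
contributes six sampling points (T1, T2, T3 in the test-food period; C1,
C2, C3 in the control period, at weeks 0/2/4 of each period), each with an
OGTT glucose and insulin curve, a gut genus-level relative-abundance
profile, a stool metabolome profile, and a stool-frequency reading.

The planted structure mirrors what the downstream analysis assumes:

* **OGTT curves** — fasting level plus a peaked excursion
  ``A * (t/tp) * exp(1 - t/tp)`` sampled at 0/30/60/90/120 min, with
  subject-level and visit-level amplitude variation and measurement noise.
  Under test food at weeks 2 and 4, the excursion amplitude shifts by
  ``baseline_dependence * (subject baseline AUC - cohort mean)`` plus
  noise, so a negative slope makes high-baseline subjects improve more.
  Insulin receives an analogous, independently drawn effect.
* **Microbiome** — per-subject Dirichlet mean compositions; each sample is
  a Dirichlet draw with parameter ``subject_concentration * subject_mean +
  time_concentration * timepoint_drift``. With subject >> time the
  composition is subject-dominant, as observed in repeated-sampling
  studies. A designated taxon's log-abundance under test food at weeks
  2/4 is shifted by ``planted_taxon_effect`` times the subject's
  standardized true glucose responder score (negative effect = the taxon
  rises in subjects whose glucose tolerance improves).
* **Metabolome** — log-normal peak areas with metabolite- and
  subject-level effects; values below ``detection_limit`` are recorded as
  missing (left-censoring, emulating undetected peaks). One designated
  metabolite gains a fixed log increase under test food.

The ``truth`` block stores every planted quantity so recovery can be
verified without re-deriving it from the noisy tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ogtt import OGTTCurve

__all__ = ["CohortConfig", "CohortDataset", "generate_cohort", "generate_tree", "write_cohort"]

GENUS_POOL = (
    "Bacteroides",
    "Blautia",
    "Faecalibacterium",
    "Bifidobacterium",
    "Prevotella_2",
    "Agathobacter",
    "Fusicatenibacter",
    "Anaerostipes",
    "Roseburia",
    "Prevotella_7",
    "Ruminococcus",
    "Subdoligranulum",
    "Dorea",
    "Coprococcus",
    "Parabacteroides",
    "Alistipes",
    "Lachnoclostridium",
    "Streptococcus",
    "Dialister",
    "Akkermansia",
)

METABOLITE_POOL = (
    "azelate",
    "butyrate",
    "acetate",
    "propionate",
    "imidazole_propionate",
    "paraxanthine",
    "6-hydroxynicotinate",
    "lactate",
    "succinate",
    "tryptophan",
)

TIMEPOINT_LABELS = ("T1", "T2", "T3", "C1", "C2", "C3")
_WEEK_OF = {"1": 0, "2": 2, "3": 4}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the trial's scale: 19 subjects, 6 sampling points
    each, genus-level community of 50 taxa, 100 metabolites. Effect
    parameters default to the qualitative structure the study reports
    (baseline-dependent glucose improvement; a taxon whose increase tracks
    improvement). Setting both effects to 0 yields a null cohort.
    """

    n_subjects: int = 19
    n_taxa: int = 50
    n_metabolites: int = 100
    times: tuple = (0.0, 30.0, 60.0, 90.0, 120.0)
    subject_sd: float = 15.0       # mg/dL, between-subject excursion amplitude sd
    noise_sd: float = 5.0          # mg/dL, visit amplitude + measurement noise sd
    baseline_dependence: float = -0.01  # amplitude shift per AUC unit above cohort mean
    planted_taxon_effect: float = -0.8  # log-abundance shift per sd of responder score
    planted_taxon: str = "Anaerostipes"
    planted_metabolite: str = "azelate"
    planted_metabolite_lfc: float = 0.5  # natural-log increase under test food
    subject_concentration: float = 150.0
    time_concentration: float = 10.0
    detection_limit: float = 0.1  # relative-peak-area floor; below = missing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be at least 4 (tree degenerate below that)")
        if self.n_metabolites < 1:
            raise ValueError("n_metabolites must be positive")
        t = np.asarray(self.times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        for name in ("subject_sd", "noise_sd", "subject_concentration", "time_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be nonnegative")

    @property
    def is_null(self) -> bool:
        return self.baseline_dependence == 0 and self.planted_taxon_effect == 0


@dataclass
class CohortDataset:
    """One generated trial dataset.

    ``abundance``/``metabolome`` are samples x features frames indexed by
    sample id; ``metadata`` has one row per sample (subject, period, week,
    timepoint, sequence, stool_frequency); ``tree`` is a rooted newick
    string over exactly the abundance taxa; ``truth`` records the planted
    parameters and per-subject true responder scores.
    """

    config: CohortConfig
    ogtt: pd.DataFrame
    abundance: pd.DataFrame
    metabolome: pd.DataFrame
    tree: str
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def ogtt_curves(self) -> list[OGTTCurve]:
        from .ogtt import curves_from_frame

        return curves_from_frame(self.ogtt)


def _excursion(times: np.ndarray, amplitude: float, tp: float) -> np.ndarray:
    return amplitude * (times / tp) * np.exp(1.0 - times / tp)


def _curve_auc(times, fasting, amplitude, tp) -> float:
    """Trapezoid AUC of the noise-free curve at the sampled times."""
    values = fasting + _excursion(times, amplitude, tp)
    return float(np.trapezoid(values, times))


def generate_tree(n_taxa: int, seed: int, names: "list[str] | None" = None) -> str:
    """Random bifurcating rooted tree over ``n_taxa`` leaves, as newick.

    Branch lengths are uniform on [0.05, 1.0]. Leaf names default to the
    genus names :func:`generate_cohort` uses, so the tree and abundance
    table agree.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if names is None:
        names = taxon_names(n_taxa)
    if len(names) != n_taxa:
        raise ValueError("names must match n_taxa")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n_taxa))

    def build(leaves: list[int]) -> str:
        if len(leaves) == 1:
            return names[leaves[0]]
        split = int(rng.integers(1, len(leaves)))
        left, right = leaves[:split], leaves[split:]
        bl = rng.uniform(0.05, 1.0)
        br = rng.uniform(0.05, 1.0)
        return f"({build(left)}:{bl:.6f},{build(right)}:{br:.6f})"

    return build(order) + ";"


def taxon_names(n_taxa: int) -> list[str]:
    names = list(GENUS_POOL[:n_taxa])
    names += [f"Genus_{i:02d}" for i in range(len(names), n_taxa)]
    return names


def metabolite_names(n_metabolites: int) -> list[str]:
    names = list(METABOLITE_POOL[:n_metabolites])
    names += [f"metabolite_{i:03d}" for i in range(len(names), n_metabolites)]
    return names


def generate_cohort(config: CohortConfig = CohortConfig()) -> CohortDataset:
    """Generate a complete synthetic trial dataset from one root seed."""
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    n = config.n_subjects
    subjects = [f"S{i + 1:02d}" for i in range(n)]
    sequences = np.array(["AB", "BA"])[rng.permutation(n) % 2]

    # --- subject-level OGTT parameters -------------------------------------
    fasting_glu = np.clip(rng.normal(95.0, 6.0, n), 70.0, None)
    amp_glu = np.clip(rng.normal(60.0, config.subject_sd, n), 10.0, None)
    tp_glu = rng.uniform(35.0, 55.0, n)
    fasting_ins = np.clip(rng.normal(8.0, 2.0, n), 2.0, None)
    amp_ins = np.clip(rng.normal(55.0, 12.0, n), 10.0, None)
    tp_ins = rng.uniform(40.0, 60.0, n)

    base_auc_glu = np.array(
        [_curve_auc(times, fasting_glu[i], amp_glu[i], tp_glu[i]) for i in range(n)]
    )
    base_auc_ins = np.array(
        [_curve_auc(times, fasting_ins[i], amp_ins[i], tp_ins[i]) for i in range(n)]
    )

    # realized test-food amplitude shifts; the dietary effect is fully
    # established by week 2 (fiber responses stabilise within 1-2 weeks)
    shift_glu = config.baseline_dependence * (base_auc_glu - base_auc_glu.mean()) + rng.normal(
        0.0, config.noise_sd, n
    )
    shift_ins = config.baseline_dependence * (base_auc_ins - base_auc_ins.mean()) + rng.normal(
        0.0, config.noise_sd, n
    )
    week_weight = {0: 0.0, 2: 1.0, 4: 1.0}

    # true glucose responder score: noise-free difference-in-differences of
    # glucose AUC, normalized by the baseline AUC
    true_score = np.array(
        [
            (
                _curve_auc(times, fasting_glu[i], amp_glu[i] + shift_glu[i], tp_glu[i])
                - base_auc_glu[i]
            )
            / base_auc_glu[i]
            for i in range(n)
        ]
    )
    score_sd = true_score.std()
    z_score = (true_score - true_score.mean()) / (score_sd if score_sd > 0 else 1.0)

    # --- OGTT records ------------------------------------------------------
    ogtt_rows = []
    meta_rows = []
    stool_base = np.clip(rng.normal(1.2, 0.4, n), 0.3, None)
    for i, subject in enumerate(subjects):
        for label in TIMEPOINT_LABELS:
            period = "test" if label[0] == "T" else "control"
            week = _WEEK_OF[label[1]]
            sample_id = f"{subject}{label}"
            w = week_weight[week] if period == "test" else 0.0
            for analyte, fasting, amp, tp, shift in (
                ("glucose", fasting_glu[i], amp_glu[i], tp_glu[i], shift_glu[i]),
                ("insulin", fasting_ins[i], amp_ins[i], tp_ins[i], shift_ins[i]),
            ):
                visit_amp = amp + w * shift + rng.normal(0.0, config.noise_sd)
                values = fasting + _excursion(times, max(visit_amp, 0.0), tp)
                values = np.clip(values + rng.normal(0.0, config.noise_sd, times.size), 0.0, None)
                values[0] = max(fasting + rng.normal(0.0, config.noise_sd / 2), 0.0)
                for t, v in zip(times, values):
                    ogtt_rows.append((sample_id, subject, label, analyte, t, v))
            meta_rows.append(
                dict(
                    sample_id=sample_id,
                    subject=subject,
                    period=period,
                    week=week,
                    timepoint=label,
                    sequence=sequences[i],
                    stool_frequency=float(
                        np.clip(stool_base[i] + rng.normal(0.0, 0.2), 0.1, None)
                    ),
                )
            )
    ogtt = pd.DataFrame(
        ogtt_rows, columns=["sample_id", "subject", "timepoint", "analyte", "minute", "value"]
    )
    metadata = pd.DataFrame(meta_rows)

    # --- microbiome --------------------------------------------------------
    taxa = taxon_names(config.n_taxa)
    planted_idx = taxa.index(config.planted_taxon) if config.planted_taxon in taxa else 0
    base_weights = 1.0 / np.arange(1, config.n_taxa + 1) ** 0.9
    base_weights /= base_weights.sum()
    subject_means = rng.dirichlet(base_weights * config.n_taxa * 0.4, size=n)
    drift = {label: rng.dirichlet(base_weights * 8.0) for label in TIMEPOINT_LABELS}
    abund_rows = []
    for i in range(n):
        for label in TIMEPOINT_LABELS:
            mean = subject_means[i].copy()
            period = "test" if label[0] == "T" else "control"
            week = _WEEK_OF[label[1]]
            if period == "test" and week > 0:
                mult = np.exp(
                    config.planted_taxon_effect * z_score[i] * week_weight[week]
                )
                mean[planted_idx] *= mult
                mean /= mean.sum()
            alpha = (
                config.subject_concentration * mean
                + config.time_concentration * drift[label]
            )
            draw = rng.dirichlet(alpha)
            draw[draw < 1e-12] = 0.0  # tiny/denormal draws are below any real detection
            abund_rows.append(draw / draw.sum())
    abundance = pd.DataFrame(
        np.vstack(abund_rows), index=metadata["sample_id"].to_numpy(), columns=taxa
    )
    abundance.index.name = "sample_id"

    tree = generate_tree(config.n_taxa, seed=int(rng.integers(0, 2**31 - 1)), names=taxa)

    # --- metabolome --------------------------------------------------------
    mets = metabolite_names(config.n_metabolites)
    planted_met_idx = mets.index(config.planted_metabolite) if config.planted_metabolite in mets else 0
    mu = rng.normal(-1.0, 1.0, config.n_metabolites)
    subj_eff = rng.normal(0.0, 0.5, size=(n, config.n_metabolites))
    met_rows = []
    for i in range(n):
        for label in TIMEPOINT_LABELS:
            period = "test" if label[0] == "T" else "control"
            week = _WEEK_OF[label[1]]
            log_vals = mu + subj_eff[i] + rng.normal(0.0, 0.3, config.n_metabolites)
            if period == "test" and week > 0:
                log_vals[planted_met_idx] += config.planted_metabolite_lfc * week_weight[week]
            vals = np.exp(log_vals)
            vals[vals < config.detection_limit] = np.nan
            met_rows.append(vals)
    metabolome = pd.DataFrame(
        np.vstack(met_rows), index=metadata["sample_id"].to_numpy(), columns=mets
    )
    metabolome.index.name = "sample_id"

    truth = {
        "null_cohort": config.is_null,
        "planted_taxon": taxa[planted_idx],
        "planted_metabolite": mets[planted_met_idx],
        "planted_taxon_effect": config.planted_taxon_effect,
        "planted_metabolite_lfc": config.planted_metabolite_lfc,
        "baseline_dependence": config.baseline_dependence,
        "subjects": subjects,
        "true_glucose_responder_score": true_score.tolist(),
        "true_baseline_glucose_auc": base_auc_glu.tolist(),
        "true_baseline_insulin_auc": base_auc_ins.tolist(),
        "true_planted_taxon_log_change": (
            config.planted_taxon_effect * z_score
        ).tolist(),
    }
    return CohortDataset(
        config=config,
        ogtt=ogtt,
        abundance=abundance,
        metabolome=metabolome,
        tree=tree,
        metadata=metadata,
        truth=truth,
    )


MANIFEST_FILES = (
    "ogtt.tsv",
    "abundance.tsv",
    "metabolome.tsv",
    "tree.nwk",
    "metadata.tsv",
    "truth.json",
)


def write_cohort(dataset: CohortDataset, directory, overwrite: bool = False) -> dict:
    """Write a cohort to ``directory`` and return the file manifest.

    Emits ogtt.tsv, abundance.tsv, metabolome.tsv, tree.nwk, metadata.tsv
    and truth.json plus manifest.json (file names and sha256 checksums).
    Missing metabolome cells are serialized as "NA". Refuses to clobber an
    existing manifest unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    fmt = "%.17g"  # lossless float64 round trip
    dataset.ogtt.to_csv(directory / "ogtt.tsv", sep="\t", index=False, float_format=fmt)
    dataset.abundance.to_csv(directory / "abundance.tsv", sep="\t", float_format=fmt)
    dataset.metabolome.to_csv(
        directory / "metabolome.tsv", sep="\t", na_rep="NA", float_format=fmt
    )
    (directory / "tree.nwk").write_text(dataset.tree + "\n")
    dataset.metadata.to_csv(directory / "metadata.tsv", sep="\t", index=False, float_format=fmt)
    truth = dict(dataset.truth)
    truth["config"] = asdict(dataset.config)
    truth["config"]["times"] = list(truth["config"]["times"])
    (directory / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    manifest = {
        "files": {
            name: hashlib.sha256((directory / name).read_bytes()).hexdigest()
            for name in MANIFEST_FILES
        }
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
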