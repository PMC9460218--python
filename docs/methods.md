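# Methods

## Study design the package models

A two-period randomized crossover dietary trial. Each subject consumes a
test food and a control food for 4 weeks each, in randomized order (AB/BA),
separated by a washout. Sampling occurs at the start (week 0) and after 2
and 4 weeks of each period, giving six points per subject: T1, T2, T3
(test) and C1, C2, C3 (control). At every point: an oral glucose tolerance
test (OGTT; blood glucose in mg/dL and insulin in μU/mL at 0/30/60/90/120
min after a 75 g load), a genus-level gut microbiome profile (relative
abundances on the simplex), a stool metabolome profile (relative peak
areas, missing when undetected), and stool frequency. The crossover
sequence is recorded in the metadata but not modelled downstream; the
analysis treats periods symmetrically, as is standard when no carryover
model is fitted.

## Glucose-tolerance indices

AUC and iAUC use the trapezoid rule on the sampled curve. Windows are
closed minute intervals whose start must coincide with a sampled time; an
end between samples is linearly interpolated. Two iAUC conventions are
implemented because responder criteria built from iAUC ratios are
convention-sensitive:

* `positive_only` (default) — only excursions above the fasting (t = 0)
  value count, with exact linear interpolation at baseline crossings
  (the Wolever convention of the glycemic-index literature);
* `net` — total AUC minus fasting × window length; may be negative.

The convention is a pipeline config field and is recorded in the run log.

## Responder machinery

The responder score of any quantity X is
`((T_end − T1) − (C_end − C1)) / mean(C1, T1)`, computed at week 2
(T2/C2) and week 4 (T3/C3). For indices where lower is better (glucose and
insulin AUC/iAUC), negative scores mean improvement. A zero denominator is
an explicit error at the scalar level; at the table level the affected
subject is excluded *for that feature* and logged, rather than patched
with a pseudocount — a score manufactured for a taxon absent at both
baselines would be meaningless.

Responder classification requires, at the same week, (1) glucose
iAUC(0–90) at Tw ≤ 0.75 × Cw, (2) glucose AUC(0–90) at Tw < Cw, and
(3) insulin iAUC(0–90) at Tw ≤ 0.85 × Cw. "Decreased by at least 25 %" is
read boundary-inclusive; the bare "decreased" of criterion 2 is strict.
All three criteria must hold in the same week; a subject is an overall
responder if either week qualifies. Mixing criteria across weeks is not
allowed — the per-week reading is the natural one for a criteria set that
compares "T2 and C2 or T3 and C3" and it keeps calls auditable.

## Feature tables and differential testing

Lineage-named columns are aggregated to genus (rank-prefixed SILVA-style
strings; lineages ending above genus become `unclassified_<last rank>`),
conserving row mass exactly. Taxa with mean relative abundance below 0.001
over all samples are dropped, **without renormalizing** the survivors —
tests run on observed relative abundances, and renormalizing would change
the tested values. Metabolites detected in fewer than 75 % of samples are
dropped; "detected" means non-missing, and censored values are not imputed
before the filter.

Paired differential testing between two time points uses the Wilcoxon
signed-rank test per feature on per-subject pairs (subjects missing either
sample dropped pairwise; fewer than 5 complete pairs refuses the
comparison), with BH adjustment across features *within one comparison and
one omics layer* — microbes and metabolites form separate FDR families.
Fold changes are log2 of the ratio of means; when a mean is zero, half the
smallest positive mean in the comparison is added to both means. All-zero
difference vectors are degenerate: reported with p = 1 and flagged rather
than dropped. Test p-values are two-sided.

## Beta diversity, ordination, PERMANOVA

UniFrac is computed from a branch-incidence matrix built once per tree
(branch lengths × a boolean branches-by-taxa matrix), which makes whole
distance matrices a few dense products. Unweighted UniFrac is unique
observed branch length over total observed branch length (presence =
abundance > 0, branches observed in either sample); weighted UniFrac is
the length-weighted L1 difference of the per-branch abundance flows, with
an optional normalizer bounding it by 1. Metabolome dissimilarity is
1 − Spearman rho over the features non-missing in both samples (≥ 3
required; constant profiles give a flagged undefined entry).

Ordination is classical (Torgerson) MDS — double-center −½ J D² J, top-k
eigenpairs, coordinates scaled by √eigenvalue — chosen over iterative
stress minimization because it is deterministic and has a closed-form
correctness check (a Euclidean distance matrix is reconstructed exactly).
Negative eigenvalues are reported, never used for coordinates.

PERMANOVA is one-way with subject as the grouping factor, implementing the
intra- versus inter-subject comparison: pseudo-F from between/within
squared-distance sums, p = (1 + #{F_perm ≥ F_obs}) / (1 + n_permutations)
under full label permutation. The permutation seed is a required, logged
parameter; 999 permutations is the default, making 0.001 the attainable
floor.

## Inferential primitives

* Paired t: two-sided, df = n − 1; zero-variance differences are an error,
  not an infinite statistic.
* Paired Hedge's g: d = mean(diff)/sd(diff) with the small-sample
  correction J = 1 − 3/(4 df − 1); the CI inverts the noncentral-t
  distribution of the paired t statistic for the noncentrality parameter
  and rescales by J/√n. This matches the approach of standard effect-size
  packages; their exact CI algorithms vary by version, so agreement is an
  approximation target, not an identity.
* Wilcoxon signed-rank: zeros dropped; exact null distribution for n ≤ 25
  without ties in |differences|, otherwise normal approximation with tie
  and continuity corrections. Pratt's zero handling is deliberately not
  offered.
* BH FDR: step-up adjusted values via statsmodels, clipped at 1, order
  restored; verified against a brute-force step-up in tests.
* Spearman: mid-rank rho, p from t = rho·√((n−2)/(1−rho²)); |rho| = 1 is
  reported at the exact permutation bound 2/n!. Pairs with missing values
  are deleted pairwise; at the trial's n = 19 the t approximation holds
  its nominal 5 % level to within simulation error.

## Responder association and the consistency screen

Baseline association: Spearman (and Pearson, for reference) correlation
between a subject's baseline index value and their responder score for
that index. Baseline defaults to the mean of the C1 and T1 measurements —
the symmetric choice when both periods have a baseline — and is
configurable to T1 only.

Feature association: per feature × index × week, Spearman correlation
between the feature's responder score and the index's responder score.
Features with fewer than 5 usable subjects (after per-feature
zero-denominator exclusions) or constant scores are skipped with a logged
reason.

The consistency screen calls a feature–index pair consistent when the
correlation is significant at α (default 0.05, raw p) at **both** weeks
with the same sign. Raw p is deliberate: the two weeks share baselines, so
the two tests are positively dependent, and requiring sign-consistent
replication across time points is the multiplicity control; BH-adjusted
q-values are carried in the output so users can tighten the screen.

## The synthetic cohort generator

Defaults reproduce the trial's scale: 19 subjects × 6 points, 50 genera,
100 metabolites, OGTT at 0/30/60/90/120 min.

* **OGTT curves**: fasting value plus a peaked excursion
  A·(t/tp)·exp(1 − t/tp) with tp ∈ [35, 55] min (glucose) — smooth,
  peaked, returning toward baseline. Between-subject amplitude sd defaults
  to 15 mg/dL, visit-level amplitude and measurement noise to 5 mg/dL;
  chosen for physiologically plausible curves (fasting ≈ 95 mg/dL, peaks
  ≈ 150–160 mg/dL), since within-subject OGTT variance is rarely
  reported. Under test food the excursion amplitude shifts by
  `baseline_dependence × (subject baseline AUC − cohort mean)` plus noise
  (default −0.01: high-baseline subjects improve more); insulin gets an
  analogous, independently drawn shift. The dietary effect is fully
  established by week 2 — fiber responses stabilize within 1–2 weeks —
  so weeks 2 and 4 carry the same planted shift plus independent noise.
* **True responder scores** are computed from the noise-free curves and
  stored in the truth block, so recovery checks never re-derive the
  ground truth from noisy data.
* **Microbiome**: subject mean compositions drawn from a Dirichlet over a
  power-law rank-abundance profile; each sample is a Dirichlet draw with
  parameter `subject_concentration · subject_mean + time_concentration ·
  timepoint_drift` (defaults 150 and 10). Subject weight ≫ time weight
  yields the subject-dominant beta diversity repeatedly observed in human
  gut time series. The planted taxon's log-abundance under test food is
  shifted by `planted_taxon_effect` × the subject's standardized true
  glucose responder score (default −0.8: the taxon rises in improvers).
  The planted taxon sits mid-rank (~1.5 % mean abundance): abundant
  enough to survive the 0.001 filter, rare enough that its planted shifts
  do not materially distort the rest of the composition.
* **Metabolome**: log-normal peak areas with metabolite-level means,
  subject random effects (sd 0.5 in log space) and sampling noise
  (sd 0.3); values below the detection limit (default 0.1, ≈ 11 %
  missingness) are recorded missing. One designated metabolite gains a
  fixed log increase (default 0.5) under test food.
* A single root generator seeded from `seed` drives all randomness;
  identical config + seed reproduces byte-identical written cohorts.

### What the generator does not emulate

Sequencing error and OTU inference, compositional count noise (abundances
are continuous Dirichlet draws, not rarefied counts), metabolite
cross-correlations, dietary non-compliance, carryover effects, and any
real taxon–metabolite biochemistry. Passing recovery tests therefore shows
the *statistical machinery* recovers planted structure at realistic noise
levels — not that the biological findings themselves generalize.

### Compositional closure

Because relative abundances sum to one, a planted increase in one taxon
necessarily depresses all others. With a strong planted effect this
mirror-image signal can itself become detectable in the most abundant
competitor taxa — a real property of compositional data, not an artifact
of the generator. The recovery tests therefore bound how often any given
unplanted taxon is flagged rather than demanding zero.

## Problem sizes and numerical choices

Simulation-based tests use: 20 replicate cohorts of 100 subjects for
planted-effect recovery; 200 single-feature null cohorts for error-rate
control; 500 label-shuffled 20-sample matrices (199 permutations each) for
PERMANOVA calibration; 100 random trees of ≤ 8 leaves against the
brute-force UniFrac oracle. These sizes give stable rates while keeping
the default test run fast. Distance matrices are symmetrized against
floating-point asymmetry and MDS eigenvalues below 1e-12 of the leading
eigenvalue are treated as zero. Abundance draws below 1e-12 are floored to
zero (no real assay resolves them, and subnormal values break ratio
denominators).

## Known limitations

* The Hedge's g CI matches the noncentral-t construction, not any one R
  package version bit-for-bit.
* Spearman p-values use the t approximation at all n (exact only in the
  |rho| = 1 corner); fine at n ≥ ~15, approximate below.
* PERMANOVA assumes exchangeability under the null; with repeated
  measures per subject that is exactly the hypothesis being tested
  (subject structure), so the test is used for its descriptive p-value,
  as is conventional.
* The generator's metabolome has no planted metabolite–score coupling, so
  metabolite consistency calls on synthetic data are null by design.
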