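# metabologenome

Analysis toolkit for **metabologenomic crossover dietary trials**: studies
in which each subject eats a test food and a control food in randomized
order (separated by a washout), and glucose tolerance, the gut microbiome
and the stool metabolome are profiled at baseline and after 2 and 4 weeks
of each period (time points T1–T3 and C1–C3).

The package answers the questions such a trial poses:

1. **Did the test food shift glucose tolerance overall?** OGTT areas under
   the curve by the trapezoid rule — total AUC and incremental iAUC (area
   above the fasting value) over configurable windows — compared between
   periods with paired *t*-tests and paired Hedge's *g* with noncentral-*t*
   confidence intervals.
2. **Who responded?** Per-subject *responder scores*, a normalized
   difference-in-differences for any quantity X:

   ```
   score(X) = ((T_end − T1) − (C_end − C1)) / mean(C1, T1)
   ```

   plus a categorical responder call: at the same week, glucose iAUC(0–90)
   down ≥ 25 %, glucose AUC(0–90) down, insulin iAUC(0–90) down ≥ 15 %.
3. **Did the intestinal environment change?** Genus aggregation,
   abundance/detection filters, per-feature Wilcoxon signed-rank tests
   with Benjamini–Hochberg FDR, unweighted/weighted UniFrac and Spearman
   correlation distances, classical MDS, and one-way PERMANOVA of
   intra- versus inter-subject dissimilarity.
4. **Which changes track the improvement?** Spearman correlations between
   feature responder scores and glucose-tolerance-index responder scores,
   screened for *consistency*: significant with the same sign at both
   week 2 and week 4.

A synthetic cohort generator (`metabologenome.simulate`) produces complete
trial datasets — OGTT curves, subject-dominant compositional microbiomes
with a phylogeny, left-censored log-normal metabolomes — with planted,
recoverable effects, so the whole pipeline is testable end to end without
any clinical data.

## Worked example

```python
from metabologenome import CohortConfig, PipelineConfig, generate_cohort, run_pipeline

dataset = generate_cohort(CohortConfig(seed=1))   # 19 subjects x 6 time points
result = run_pipeline(dataset, PipelineConfig(), seed=1)

print(result.permanova["microbiome_unweighted_unifrac"].p)
print(result.responder_calls.groupby("subject").responder_overall.first().sum())
print(result.baseline_assoc.query("feature == 'glucose_AUC_0_90' and week == 4").rho)
```

prints

```
0.001
2
1   -0.385965
Name: rho, dtype: float64
```

meaning: no random subject relabelling produced inter/intra-subject
separation as strong as the observed one (PERMANOVA at the permutation
floor with 999 permutations — the microbiome is subject-dominant); 2 of the
19 synthetic subjects meet all three responder criteria; and subjects with
higher baseline glucose AUC tended to improve more (negative rank
correlation between baseline and responder score).

The `examples/` directory holds one short script per capability
(simulation, OGTT metrics, responder screening, beta diversity, the
consistency screen); each prints the numbers it computes and a line on
what they mean. A thin CLI mirrors the two entry points:

```sh
metabologenome simulate --out cohort/ --seed 1
metabologenome run --manifest cohort/ --out report/ --seed 1
```

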