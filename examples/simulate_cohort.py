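"""Generate a synthetic crossover-trial cohort and write it to disk.

The cohort mimics a two-period dietary trial: 19 subjects, six sampling
points each (T1-T3 test food, C1-C3 control), with OGTT curves, a gut
genus-abundance table, a stool metabolome table and a phylogeny.
"""

from metabologenome import CohortConfig, generate_cohort, write_cohort

dataset = generate_cohort(CohortConfig(seed=1))
manifest = write_cohort(dataset, "scratch/example_cohort", overwrite=True)

print(f"samples:            {dataset.abundance.shape[0]}")
print(f"taxa:               {dataset.abundance.shape[1]}")
print(f"metabolites:        {dataset.metabolome.shape[1]}")
print(f"metabolome missing: {dataset.metabolome.isna().mean().mean():.1%}")
print(f"planted taxon:      {dataset.truth['planted_taxon']}")
print(f"files written:      {sorted(manifest['files'])}")
# 114 samples = 19 subjects x 6 time points; the planted taxon is the one
# whose change under test food is coupled to glucose-tolerance improvement.
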