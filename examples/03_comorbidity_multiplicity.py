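"""Deduplicated aggregation, multiplicity and disease co-occurrence.

Patients often qualify for several autoimmune diseases, so summing
per-disease counts overstates the class-level burden.  This example counts
each patient once, tabulates how many distinct diseases each carries, and
prints the pairwise co-occurrence counts for the most co-occurring pair.
"""

import autoprev as ap

cfg = ap.default_sim_config(seed=11, n_persons=10_000)
sim = ap.generate(cfg)
cohorts = ap.build_all_cohorts(sim.events, cfg.phenotypes(), sim.persons)

sizes = sum(len(c) for c in cohorts.values())
union = ap.aggregate_cohort(cohorts)
print(f"sum of per-disease cohort sizes: {sizes:,}")
print(f"distinct patients (deduplicated): {len(union):,} "
      f"— naive summing would overcount by {sizes - len(union):,}")

dist = ap.multiplicity_distribution(cohorts)
print("\npatients by number of distinct autoimmune diseases:")
for k in sorted(dist.counts):
    print(f"  {dist.label(k):>2}: {dist.counts[k]:5d}  ({dist.percentages[k]}%)")

matrix = ap.cooccurrence_matrix(cohorts)
off = matrix.where(~(matrix.index.values[:, None] >= matrix.columns.values))
i, j = off.stack().idxmax()
print(f"\nmost co-occurring pair: {i} & {j} share {matrix.loc[i, j]} patients "
      f"(cohort sizes {matrix.loc[i, i]} and {matrix.loc[j, j]})")
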