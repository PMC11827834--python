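"""Simulate a small multi-site EHR extract and estimate prevalence.

Generates 10,000 synthetic patients under the default study conditions
(10 autoimmune diseases, prevalences 0.5%-8%, female:male ratios 0.5-4,
plus an NOS category), runs the two-code/30-day phenotyping pipeline, and
projects the stratified rates onto the bundled example census.
"""

import autoprev as ap

cfg = ap.default_sim_config(seed=42, n_persons=10_000)
sim = ap.generate(cfg)
print(f"simulated {len(sim.persons):,} persons, {len(sim.events):,} diagnosis events")

study = cfg.study
census = ap.load_census(ap.default_census_path(), study)

# denominator: >=2 diagnoses of any kind >=30 days apart
den = ap.build_denominator(sim.events, sim.persons, study.denominator_params)
# numerators: >=2 disease codes >=30 days apart (or NOS-then-specific)
cohorts = ap.build_all_cohorts(sim.events, cfg.phenotypes(), sim.persons,
                               study.numerator_params)
union = ap.aggregate_cohort(cohorts)
print(f"denominator {len(den):,}; any-autoimmune cohort {len(union):,} "
      f"(crude {100 * len(union) / len(den):.1f}%)")

table = ap.stratum_counts(union, den, sim.persons, study)
est = ap.project_to_census(table, census)
print(
    f"projected to the reference census: {est.projected_count:,.0f} people "
    f"({est.prevalence_pct:.2f}% of {est.census_total:,.0f}), "
    f"95% CI {est.ci_low:,.0f}-{est.ci_high:,.0f}"
)
# the projection applies each (sex, age-group) stratum's observed rate to
# that stratum's census population and sums the eight contributions

print("\nper-disease crude prevalence vs configured truth:")
for spec in cfg.specific_diseases():
    crude = 100 * len(cohorts[spec.disease_id]) / len(den)
    print(f"  {spec.disease_id}: estimated {crude:.2f}%  "
          f"(true {100 * spec.true_prevalence:.2f}%)")
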