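# Methods

This note records the statistical model, the conventions the implementation
fixes where the underlying methodology leaves room, and what the synthetic
data generator does and does not emulate.

## Phenotyping rules

A person qualifies for a disease when at least `min_codes` dated diagnosis
events from the disease's code set exist and the span between the earliest
event and some later event is at least `window_days` (defaults 2 and 30).
Conventions the implementation fixes:

* **Inclusive window.** A span of exactly `window_days` qualifies ("at
  least 30 days apart" / "30 or more days later" read inclusively).
* **Counts vs span.** Two events on the same date count as two codes toward
  `min_codes` but contribute zero span: `min_codes` is about event
  multiplicity, the window about elapsed time. Consequently
  `(min_codes=1, window=30)` still requires two events 30 days apart, while
  `(1, 0)` is the true single-code rule.
* **Qualification date.** The earliest date at which the criterion first
  becomes satisfiable under a chronological scan; with `min_codes=2`, the
  earliest event date at least `window_days` after the person's first
  disease code.
* **NOS direction.** The NOS-then-specific route requires the NOS code
  first and the specific code `window_days` or more later; the reverse
  order never qualifies. The NOS *category* itself retains only persons who
  qualify for no specific disease, so the catch-all is reported as its own
  entity without double-counting patients whose NOS code merely fed the
  side rule, and a person's multiplicity count is not inflated by it.
* **Death records.** Any person with a recorded death date is removed from
  both numerator and denominator (default on). Sites that do not capture
  death simply contribute no death dates. Removing from both sides is the
  only choice that preserves numerator ⊆ denominator.
* **Code identity.** Codes are compared as exact strings after vocabulary
  standardization; no hierarchical (descendant) expansion is applied. This
  is an extension point, not a hidden behavior.
* **No cross-site linkage.** Persons are unique within site; the same human
  appearing at two sites is counted twice, a stated limitation of siloed
  EHR denominators.

## Stratification and projection

Age is computed at year resolution (`year(reference) − birth_year`), the
only resolution reliably available in OMOP person records, with the study
end (2022-06-01) as the default reference date (configurable to each
person's qualification date). The default age groups are [0,18), [18,45),
[45,65), [65,∞) — a conventional pediatric / younger-adult / middle-age /
senior split — and bins are half-open, so an 18-year-old falls in 18–44.

Persons whose recorded sex is outside {female, male} are excluded from the
eight projection strata (the projection is defined over two sex categories)
but are counted and reported under the suppression rules (masked below 20).

Direct standardization: `projected = Σ_s (n_s/d_s)·N_s` over the eight
(sex, age-group) cells, after pooling stratum counts across sites (default
`pool_counts`; `average_projections`, the mean of per-site projections, is
provided because multi-site combination is ambiguous when sites differ in
case mix — the two agree exactly when sites share identical stratum
denominators). Cells with an empty denominator and no cases contribute
zero and are flagged; cases without denominator are an integrity error.

**Confidence interval.** A stratified binomial normal approximation:
`Var = Σ_s N_s²·p̂_s(1−p̂_s)/d_s`, CI `projected ± z·√Var`. This is an
artifact-defined contract chosen for transparency; degenerate cells
(p̂ ∈ {0,1}) contribute zero variance and are flagged. It ignores
between-site heterogeneity and any uncertainty in the census totals.

**Bundled census.** The packaged reference table
(`data/us_census_2022_synthetic_strata.csv`) carries *constructed*,
plausible sex × age-group strata summing to exactly 333,300,000 (the 2022
US total used for national projection). Stratum-level values for a real
analysis are user-supplied.

**Suppression.** Disease-level patient counts in (0, 10) are masked as
`<10` with every estimate column withheld; other/unknown-sex counts in
(0, 20) are masked as `<20`; co-occurrence cells in (0, 10) likewise.
Masking happens before serialization, so masked values are irrecoverable
from outputs.

## Synthetic data generator

The generator emulates exactly the structure the estimator relies on:

* **Population.** Default 50,000 persons over six sites with weights
  (0.25, 0.20, 0.20, 0.15, 0.12, 0.08); sex distribution 52.0% female /
  47.5% male / 0.5% other (EHR populations skew female because females use
  the health system more); age shares (0.18, 0.38, 0.26, 0.18) over the
  four default bins, reflecting the adult-heavy case mix of academic
  medical centers; death-record rate 1% (death is poorly captured in EHRs).
* **Disease panel.** Ten diseases with prevalences 8, 6, 5, 4, 3, 2, 1.5,
  1, 0.8, 0.5% and female:male ratios 4.0, 2.0, 3.0, 0.5, 1.7, 1.3, 1.0,
  2.0, 0.8, 1.5, plus an NOS category at 0.3%. The extreme ratios (4.0,
  0.5) are paired with the higher-prevalence diseases deliberately: a
  sex ratio is a ratio of two case counts, and with fewer than ~1600
  expected cases the sampling error of that ratio exceeds 5% even with a
  perfect estimator, so placing the extremes on rare diseases would leave
  them unverifiable at any sample size this panel represents.
* **Comorbidity.** A single shared latent factor u ~ N(0,1) per person;
  disease j assigned with probability `expit(α_j + β_j·x_sex + λ·u)`
  (x_sex = ±1/2), the simplest mechanism producing the positive
  co-occurrence seen in autoimmune multimorbidity. For each disease,
  (α_j, β_j) are calibrated by nested Brent root-finding (Gauss–Hermite
  quadrature over u) so that the marginal prevalence and the female:male
  *prevalence* ratio exactly equal their configured values at the
  configured load λ (default 1.0). Prevalence ratio, not odds ratio, is
  calibrated because that is the quantity the pipeline estimates and the
  field reports (e.g. a 1.7:1 female-to-male case ratio).
* **Coding.** Each case receives `2 + Poisson(1)` codes per assigned
  disease, first and last codes spanning Uniform[30, 1095] days (support at
  or above the numerator window, so true cases qualify by construction),
  placed uniformly inside the study window. With probability 5% a person
  receives a single *provisional* code for one uniformly drawn disease they
  do not have (a draw landing on a disease they do have is discarded) —
  per person, not per disease, matching the billing-driven "rule-out"
  coding the two-code rule exists to filter. All persons additionally
  receive Poisson(8) background diagnoses with uniform dates, which makes
  ~99.7% of persons denominator-qualified.
* **Dates** are uniform within the study window (no seasonality, no care
  trajectories); death dates are clamped to follow birth.

What the generator does **not** emulate: realistic clinical trajectories
and visit clustering, site-specific coding idiosyncrasies, code-hierarchy
noise, migration between sites, or secular trends. Passing recovery tests
therefore shows the estimator is correct *under its own assumptions*
(cases truly carry ≥2 spaced codes; noise is single-code), not that those
assumptions hold in any particular health system.

## Verification design

* Every qualification, stratification, union, multiplicity and
  co-occurrence operation is checked against independent brute-force
  implementations (per-person loops, exhaustive pair checks) on 200
  randomized small datasets.
* Parameter recovery runs the full pipeline at the default study
  conditions (n = 50,000): each disease's crude prevalence must fall
  within 3 binomial SE of its configured value. Sex-ratio recovery within
  10% is asserted for each disease with at least 1600 expected cases — the
  a-priori power point where a 10% band is ≈2 sampling SD at ratio 1 —
  and for the aggregate cohort, whose model-implied female:male ratio is
  computed independently by quadrature from the calibrated assignment
  model.
* Determinism is asserted byte-for-byte across repeated simulate →
  estimate → serialize runs at a fixed seed.

Problem sizes used by the test suite (50,000 persons for recovery, 4,000
for directional properties, ≤50 persons for oracle equivalence) were chosen
to make each check statistically meaningful at interactive runtimes.

## Known limitations

* The CI contract is a normal approximation; it undercovers in strata with
  very few denominator members.
* Crude and projected prevalence are period prevalence over the whole study
  window; no point-prevalence or incidence machinery is provided.
* The concept map is flat and exact-match; SNOMED hierarchy expansion and
  many-to-many mappings are out of scope.
* `average_projections` pooling averages CI bounds as well, which is a
  descriptive convenience, not a valid interval for the mean of site
  projections.
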