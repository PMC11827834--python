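"""Stratification, census projection, CIs, pooling and suppression."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

import autoprev as ap
from autoprev.prevalence import StratumTable

import oracles
from conftest import make_events, make_persons, random_small_dataset

BINS = (0, 18, 45, 65)
REF = date(2022, 6, 1)


class TestAssignStratum:
    @pytest.mark.parametrize(
        "birth_year,expected",
        [
            (2000, ("female", "18-44")),   # age 22
            (2004, ("female", "18-44")),   # age 18: half-open boundary
            (2005, ("female", "0-17")),    # age 17
            (1957, ("female", "65-plus")),
        ],
    )
    def test_half_open_bins(self, birth_year, expected):
        sex, group = ap.assign_stratum("female", birth_year, BINS, REF)
        assert sex == expected[0]
        assert group == expected[1].replace("65-plus", "65+")

    def test_other_sex_is_excluded_from_projection(self):
        assert ap.assign_stratum("other", 1980, BINS, REF) is None
        assert ap.assign_stratum("unknown", 1980, BINS, REF) is None

    def test_future_birth_year_is_an_error(self):
        with pytest.raises(ap.IntegrityError):
            ap.assign_stratum("male", 2030, BINS, REF)


def _table(cells, bins=BINS, labels=("0-17", "18-44", "45-64", "65+")):
    """StratumTable from {(site, sex, age_group): (n, d)}."""
    idx = pd.MultiIndex.from_tuples(cells, names=["site_id", "sex", "age_group"])
    df = pd.DataFrame(
        {"n": [v[0] for v in cells.values()], "d": [v[1] for v in cells.values()]},
        index=idx,
    )
    return StratumTable(df, bins)


def _census(pops):
    rows = [{"sex": s, "age_group": g, "population": p} for (s, g), p in pops.items()]
    return ap.CensusTable(pd.DataFrame(rows))


class TestStratumCounts:
    def test_single_cell_counts(self, default_config):
        persons = make_persons(
            [("a", "female", 1992, None, "s1"), ("b", "male", 1992, None, "s1")]
        )
        cohort = pd.DataFrame(
            {"disease_id": "dz", "person_id": ["a"], "site_id": ["s1"],
             "qualification_date": [pd.Timestamp("2015-01-01")]}
        )
        denom = pd.DataFrame(
            {"person_id": ["a", "b"], "site_id": ["s1", "s1"],
             "qualification_date": pd.to_datetime(["2015-01-01", "2015-01-01"])}
        )
        t = ap.stratum_counts(cohort, denom, persons, default_config)
        assert t.counts.loc[("s1", "female", "18-44")].tolist() == [1, 1]
        assert t.counts.loc[("s1", "male", "18-44")].tolist() == [0, 1]
        assert t.counts["n"].sum() == 1

    def test_empty_cohort_leaves_denominator_unchanged(self, default_config):
        persons = make_persons([("a", "female", 1992, None, "s1")])
        cohort = pd.DataFrame(
            columns=["disease_id", "person_id", "site_id", "qualification_date"]
        )
        denom = pd.DataFrame(
            {"person_id": ["a"], "site_id": ["s1"],
             "qualification_date": pd.to_datetime(["2015-01-01"])}
        )
        t = ap.stratum_counts(cohort, denom, persons, default_config)
        assert t.counts["n"].sum() == 0
        assert t.counts["d"].sum() == 1

    def test_cohort_member_missing_from_denominator_raises(self, default_config):
        persons = make_persons([("a", "female", 1992, None, "s1")])
        cohort = pd.DataFrame(
            {"disease_id": "dz", "person_id": ["a"], "site_id": ["s1"],
             "qualification_date": [pd.Timestamp("2015-01-01")]}
        )
        denom = pd.DataFrame(
            columns=["person_id", "site_id", "qualification_date"]
        )
        with pytest.raises(ap.IntegrityError):
            ap.stratum_counts(cohort, denom, persons, default_config)

    @pytest.mark.parametrize("seed", range(25))
    def test_cell_sums_match_brute_force_recount(self, seed, default_config):
        persons, events = random_small_dataset(seed)
        den = ap.build_denominator(events, persons, ap.QualificationParams(2, 10))
        pheno = ap.PhenotypeDefinition("dz", "dz", frozenset({"C0", "C1"}))
        cohort = ap.build_disease_cohort(events, pheno, persons,
                                         ap.QualificationParams(2, 10))
        t = ap.stratum_counts(cohort, den, persons, default_config)
        labels = default_config.age_group_labels()
        exp_n, other_n = oracles.oracle_stratum_counts(
            cohort["person_id"], persons, BINS, labels, REF.year
        )
        exp_d, other_d = oracles.oracle_stratum_counts(
            den["person_id"], persons, BINS, labels, REF.year
        )
        got_n = {k: v for k, v in t.counts["n"].items() if v}
        got_d = {k: v for k, v in t.counts["d"].items() if v}
        assert got_n == exp_n
        assert got_d == exp_d
        assert (t.n_other, t.d_other) == (other_n, other_d)


class TestProjection:
    def test_single_ratio_scaling(self):
        t = _table({("s1", "female", "18-44"): (5, 100)})
        est = ap.project_to_census(t, _census({("female", "18-44"): 1000}))
        assert est.projected_count == pytest.approx(50)
        assert est.prevalence_pct == pytest.approx(5.0)

    def test_additivity_across_strata(self):
        t = _table(
            {("s1", "female", "18-44"): (1, 10), ("s1", "male", "18-44"): (2, 10)}
        )
        census = _census({("female", "18-44"): 100, ("male", "18-44"): 100})
        est = ap.project_to_census(t, census)
        assert est.projected_count == pytest.approx(30)
        # conservation: per-stratum contributions sum to the total
        assert est.breakdown["projected"].sum() == pytest.approx(est.projected_count)

    def test_unadjusted_single_stratum_projection(self):
        # one site's crude counts scaled to a national total; expected value
        # frozen from exact rational evaluation of (n/d)*N
        t = _table({("s1", "female", "18-44"): (2552, 375253)})
        est = ap.project_to_census(t, _census({("female", "18-44"): 333_300_000}))
        assert round(est.projected_count) == 2_266_688

    def test_zero_denominator_with_cases_is_integrity_error(self):
        t = _table({("s1", "female", "18-44"): (1, 0)})
        with pytest.raises(ap.IntegrityError):
            ap.project_to_census(t, _census({("female", "18-44"): 100}))

    def test_zero_denominator_without_cases_contributes_zero_and_flags(self):
        t = _table(
            {("s1", "female", "18-44"): (0, 0), ("s1", "male", "18-44"): (1, 10)}
        )
        census = _census({("female", "18-44"): 100, ("male", "18-44"): 100})
        est = ap.project_to_census(t, census)
        assert est.projected_count == pytest.approx(10)
        assert est.zero_denominator_strata == [("female", "18-44")]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = ["0-17", "18-44", "45-64", "65+"]
        cells, pops, triples = {}, {}, []
        for sex in ("female", "male"):
            for g in labels:
                d = int(rng.integers(1, 500))
                n = int(rng.integers(0, d + 1))
                N = int(rng.integers(1000, 100000))
                cells[("s1", sex, g)] = (n, d)
                pops[(sex, g)] = N
                triples.append((n, d, N))
        est = ap.project_to_census(_table(cells), _census(pops))
        assert est.projected_count == pytest.approx(
            oracles.oracle_projection(triples)
        )


class TestConfidenceInterval:
    def test_closed_form_single_stratum(self):
        # p=0.5, d=100, N=100 -> SE = 5, 95% CI = 50 +/- 1.96*5
        t = _table({("s1", "female", "18-44"): (50, 100)})
        lo, hi = ap.confidence_interval(t, _census({("female", "18-44"): 100}))
        assert lo == pytest.approx(40.2, abs=0.01)
        assert hi == pytest.approx(59.8, abs=0.01)

    def test_all_zero_rates_give_zero_width_with_flag(self):
        t = _table({("s1", "female", "18-44"): (0, 100)})
        est = ap.project_to_census(t, _census({("female", "18-44"): 100}))
        assert est.ci_low == est.ci_high == est.projected_count == 0
        assert est.degenerate_strata == [("female", "18-44")]

    def test_width_shrinks_with_sqrt_of_denominator(self):
        c = _census({("female", "18-44"): 1000})
        t1 = _table({("s1", "female", "18-44"): (30, 100)})
        t10 = _table({("s1", "female", "18-44"): (300, 1000)})
        w1 = np.diff(ap.confidence_interval(t1, c))[0]
        w10 = np.diff(ap.confidence_interval(t10, c))[0]
        assert w1 / w10 == pytest.approx(np.sqrt(10), rel=1e-6)

    def test_level_out_of_range(self):
        t = _table({("s1", "female", "18-44"): (5, 10)})
        with pytest.raises(ap.ParameterError):
            ap.project_to_census(t, _census({("female", "18-44"): 100}), level=1.5)


class TestPooling:
    census = _census({("female", "18-44"): 100})

    def test_identical_sites_leave_projection_unchanged(self):
        t = _table({("s1", "female", "18-44"): (1, 10)})
        pooled = ap.pool_sites([t, t], "pool_counts")
        assert pooled.counts["n"].sum() == 2
        assert pooled.counts["d"].sum() == 20
        est = ap.project_to_census(pooled, self.census)
        assert est.projected_count == pytest.approx(10)

    def test_pool_counts_vs_average_projections(self):
        a = _table({("sA", "female", "18-44"): (1, 10)})
        b = _table({("sB", "female", "18-44"): (3, 10)})
        pooled = ap.pool_sites([a, b], "pool_counts")
        est_pool = ap.project_to_census(pooled, self.census)
        est_avg = ap.pool_sites([a, b], "average_projections", census=self.census)
        # equal denominators: the two modes agree exactly
        assert est_pool.projected_count == pytest.approx(20)
        assert est_avg.projected_count == pytest.approx(20)

    def test_mismatched_bins_is_a_config_error(self):
        a = _table({("sA", "female", "18-44"): (1, 10)})
        b = _table({("sB", "female", "18-44"): (1, 10)}, bins=(0, 20, 45, 65))
        with pytest.raises(ap.ConfigError):
            ap.pool_sites([a, b], "pool_counts")


class TestSuppression:
    report = pd.DataFrame(
        {
            "disease_id": ["a", "b", "c"],
            "raw_n": [9, 10, 0],
            "raw_d": [100, 100, 100],
            "projected_count": [90.0, 100.0, 0.0],
            "prevalence_pct": [0.9, 1.0, 0.0],
            "n_other": [19, 25, 0],
        }
    )

    def test_counts_below_threshold_are_masked(self):
        out = ap.suppress(self.report)
        assert out.loc[0, "raw_n"] == "<10"
        assert out.loc[0, "projected_count"] == ""  # projection withheld
        assert out.loc[1, "raw_n"] == 10  # at the threshold: reported
        assert out.loc[2, "raw_n"] == 0  # zero is reportable

    def test_other_sex_masking(self):
        out = ap.suppress(self.report)
        assert out.loc[0, "n_other"] == "<20"
        assert out.loc[1, "n_other"] == 25

    def test_masked_values_are_irrecoverable_after_serialization(self, tmp_path):
        out = ap.suppress(self.report)
        path = tmp_path / "r.csv"
        out.to_csv(path, index=False)
        text = path.read_text()
        assert "9," not in text.splitlines()[1]
        assert "<10" in text
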