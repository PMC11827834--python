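"""Qualification rules and cohort construction."""

from datetime import date

import pandas as pd
import pytest

import autoprev as ap
from autoprev.cohort import build_disease_cohort

import oracles
from conftest import make_events, make_persons, random_small_dataset

P = ap.QualificationParams


class TestQualifies:
    @pytest.mark.parametrize(
        "dates,params,expected",
        [
            (["2020-01-01"], P(2, 30), None),  # below min_codes
            (["2020-01-01", "2020-01-31"], P(2, 30), date(2020, 1, 31)),  # span == window, inclusive
            (["2020-01-01", "2020-01-15", "2020-01-28"], P(2, 30), None),  # span 27
            (["2020-01-01", "2020-02-01", "2020-06-01"], P(2, 30), date(2020, 2, 1)),
            (["2020-01-01", "2020-01-01"], P(2, 0), date(2020, 1, 1)),  # same-day pair, zero window
            (["2020-01-01", "2020-01-01"], P(2, 1), None),  # two codes, zero span
            ([], P(2, 30), None),
            (["2020-05-05"], P(1, 0), date(2020, 5, 5)),  # single-code rule
        ],
    )
    def test_rule_boundaries(self, dates, params, expected):
        assert ap.qualifies(pd.to_datetime(dates), params) == expected

    def test_negative_window_is_a_parameter_error(self):
        with pytest.raises(ap.ParameterError):
            P(2, -1)
        with pytest.raises(ap.ParameterError):
            P(0, 30)

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_exhaustive_pair_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 9))
        dates = pd.Timestamp("2020-01-01") + pd.to_timedelta(
            rng.integers(0, 100, n), unit="D"
        )
        params = P(int(rng.integers(1, 4)), int(rng.integers(0, 60)))
        assert ap.qualifies(dates, params) == oracles.oracle_qualifies(
            dates, params.min_codes, params.window_days
        )


class TestNosRule:
    def test_nos_then_specific_qualifies(self):
        assert ap.nos_qualifies(
            [pd.Timestamp("2020-01-01")], [pd.Timestamp("2020-02-15")], 30
        ) == date(2020, 2, 15)

    def test_direction_matters(self):
        # specific first, NOS later: does not qualify
        assert ap.nos_qualifies(
            [pd.Timestamp("2020-02-15")], [pd.Timestamp("2020-01-01")], 30
        ) is None

    def test_window_is_inclusive_and_short_gaps_fail(self):
        assert ap.nos_qualifies(
            [pd.Timestamp("2020-01-01")], [pd.Timestamp("2020-01-20")], 30
        ) is None
        assert ap.nos_qualifies(
            [pd.Timestamp("2020-01-01")], [pd.Timestamp("2020-01-31")], 30
        ) == date(2020, 1, 31)


RA = ap.PhenotypeDefinition("ra", "RA", frozenset({"C1"}), uses_nos_rule=True)
NOS = ap.PhenotypeDefinition(ap.NOS_DISEASE_ID, "NOS", frozenset({"NOS-A"}))


class TestDiseaseCohort:
    persons = make_persons(
        [
            ("a", "female", 1980, None, "s1"),
            ("b", "male", 1970, None, "s1"),
            ("c", "female", 1990, "2020-06-01", "s1"),
        ]
    )

    def test_two_codes_45_days_apart_qualify(self):
        events = make_events(
            [("a", "C1", "2015-01-01"), ("a", "C1", "2015-02-15")]
        )
        cohort = build_disease_cohort(events, RA, self.persons)
        assert list(cohort["person_id"]) == ["a"]
        assert cohort.loc[0, "qualification_date"] == pd.Timestamp("2015-02-15")

    def test_nos_code_before_specific_code_qualifies(self):
        events = make_events(
            [("a", "NOS-A", "2015-01-01"), ("a", "C1", "2015-02-10")]
        )
        cohort = build_disease_cohort(events, RA, self.persons, nos_phenotype=NOS)
        assert list(cohort["person_id"]) == ["a"]

    def test_both_routes_keep_earlier_qualification_date(self):
        events = make_events(
            [
                ("a", "NOS-A", "2015-01-01"),
                ("a", "C1", "2015-02-10"),  # NOS route qualifies here
                ("a", "C1", "2015-06-01"),  # own-code route qualifies here
            ]
        )
        cohort = build_disease_cohort(events, RA, self.persons, nos_phenotype=NOS)
        assert len(cohort) == 1
        assert cohort.loc[0, "qualification_date"] == pd.Timestamp("2015-02-10")

    def test_deceased_persons_are_removed_when_flag_on(self):
        events = make_events(
            [("c", "C1", "2015-01-01"), ("c", "C1", "2015-03-01")]
        )
        assert build_disease_cohort(events, RA, self.persons).empty
        kept = build_disease_cohort(events, RA, self.persons, remove_deceased=False)
        assert list(kept["person_id"]) == ["c"]


class TestDenominator:
    def test_any_two_codes_far_apart_qualify(self):
        persons = make_persons([("a", "female", 1980, None, "s1")])
        events = make_events(
            [("a", "X", "2015-01-01"), ("a", "Y", "2015-07-20")]
        )
        assert list(ap.build_denominator(events, persons)["person_id"]) == ["a"]

    def test_same_day_codes_have_zero_span(self):
        persons = make_persons([("a", "female", 1980, None, "s1")])
        events = make_events([("a", f"C{i}", "2015-01-01") for i in range(5)])
        assert ap.build_denominator(events, persons).empty


@pytest.mark.parametrize("seed", range(40))
def test_cohorts_match_brute_force_on_random_data(seed):
    """Vectorized engine equals the per-person loop oracle."""
    persons, events = random_small_dataset(seed)
    params = P(2, 30)
    pheno = ap.PhenotypeDefinition("dz", "dz", frozenset({"C0", "C1"}),
                                   uses_nos_rule=True)
    cohort = build_disease_cohort(events, pheno, persons, params,
                                  nos_phenotype=NOS)
    expected = oracles.oracle_cohort(
        events, pheno.code_set, persons, 2, 30,
        nos_codes={"NOS-A"}, uses_nos_rule=True,
    )
    got = {
        r.person_id: r.qualification_date.date()
        for r in cohort.itertuples()
    }
    assert got == expected

    den = ap.build_denominator(events, persons, params)
    den_expected = oracles.oracle_denominator(events, persons, 2, 30)
    assert set(den["person_id"]) == set(den_expected)


@pytest.mark.parametrize("seed", range(15))
def test_monotonicity_and_subset_properties(seed):
    """Wider windows never enlarge cohorts; numerator ⊆ denominator."""
    persons, events = random_small_dataset(seed, n_persons_max=40)
    pheno = ap.PhenotypeDefinition("dz", "dz", frozenset({"C0", "C1", "C2"}))
    sizes = []
    for window in (0, 15, 30, 60):
        c = build_disease_cohort(events, pheno, persons, P(2, window))
        sizes.append(len(c))
    assert sizes == sorted(sizes, reverse=True)

    low = build_disease_cohort(events, pheno, persons, P(1, 30))
    high = build_disease_cohort(events, pheno, persons, P(3, 30))
    base = build_disease_cohort(events, pheno, persons, P(2, 30))
    assert set(high["person_id"]) <= set(base["person_id"]) <= set(low["person_id"])

    den = ap.build_denominator(events, persons, P(2, 30))
    assert set(base["person_id"]) <= set(den["person_id"])


def test_cohort_is_invariant_to_event_order():
    persons, events = random_small_dataset(99)
    pheno = ap.PhenotypeDefinition("dz", "dz", frozenset({"C0", "C1"}))
    shuffled = events.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = build_disease_cohort(events, pheno, persons)
    b = build_disease_cohort(shuffled, pheno, persons)
    pd.testing.assert_frame_equal(a, b)


def test_nos_category_retains_only_nos_only_patients():
    persons = make_persons(
        [("a", "female", 1980, None, "s1"), ("b", "male", 1970, None, "s1")]
    )
    events = make_events(
        [
            # 'a': NOS codes twice AND qualifies for ra -> excluded from NOS category
            ("a", "NOS-A", "2015-01-01"), ("a", "NOS-A", "2015-03-01"),
            ("a", "C1", "2016-01-01"), ("a", "C1", "2016-03-01"),
            # 'b': NOS alone
            ("b", "NOS-A", "2015-01-01"), ("b", "NOS-A", "2015-03-01"),
        ]
    )
    cohorts = ap.build_all_cohorts(events, [RA, NOS], persons)
    assert list(cohorts["ra"]["person_id"]) == ["a"]
    assert list(cohorts[ap.NOS_DISEASE_ID]["person_id"]) == ["b"]
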