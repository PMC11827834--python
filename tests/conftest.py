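"""Shared fixtures: tiny hand-built tables and seeded synthetic datasets."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

import autoprev as ap


def make_persons(rows):
    """Build a person table from (person_id, sex, birth_year, death, site)."""
    df = pd.DataFrame(
        rows, columns=["person_id", "sex", "birth_year", "death_date", "site_id"]
    )
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


def make_events(rows):
    """Build an event table from (person_id, code, date[, site]) tuples."""
    full = []
    for r in rows:
        pid, code, d = r[0], r[1], r[2]
        site = r[3] if len(r) > 3 else "s1"
        full.append((pid, ap.STANDARD_VOCABULARY, code, pd.Timestamp(d), site))
    return pd.DataFrame(
        full, columns=["person_id", "vocabulary", "code", "event_date", "site_id"]
    )


def random_small_dataset(seed, n_persons_max=50, n_events_max=10, n_codes=6,
                         sites=("s1", "s2")):
    """A randomized small OMOP-lite dataset for oracle-equivalence tests.

    Dates fall in a 100-day range so window boundaries are exercised often.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, n_persons_max + 1))
    persons = make_persons(
        [
            (
                f"p{i}",
                rng.choice(["female", "male", "other"], p=[0.45, 0.45, 0.1]),
                int(rng.integers(1940, 2011)),
                pd.Timestamp("2015-06-01") if rng.random() < 0.05 else None,
                str(rng.choice(list(sites))),
            )
            for i in range(n)
        ]
    )
    codes = [f"C{k}" for k in range(n_codes)] + ["NOS-A"]
    rows = []
    base = pd.Timestamp("2020-01-01")
    site_of = dict(zip(persons["person_id"], persons["site_id"]))
    for i in range(n):
        for _ in range(int(rng.integers(0, n_events_max + 1))):
            rows.append(
                (
                    f"p{i}",
                    str(rng.choice(codes)),
                    base + pd.Timedelta(days=int(rng.integers(0, 100))),
                    site_of[f"p{i}"],
                )
            )
    events = make_events(rows) if rows else make_events([])
    return persons, events


@pytest.fixture(scope="session")
def default_config():
    return ap.StudyConfig()


@pytest.fixture(scope="session")
def census(default_config):
    return ap.load_census(ap.default_census_path(), default_config)


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic dataset for structural/directional tests."""
    cfg = ap.default_sim_config(seed=7, n_persons=4000)
    return ap.generate(cfg)


@pytest.fixture(scope="session")
def large_sim():
    """The default study conditions (n=50,000) for parameter recovery."""
    cfg = ap.default_sim_config(seed=20110101 % (2**31), n_persons=50_000)
    return ap.generate(cfg)
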