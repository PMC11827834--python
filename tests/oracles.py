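"""Independent brute-force reference implementations.

These deliberately use naive per-person loops and exhaustive pair checks so
they share no code path with the package's vectorized implementations; the
test suite asserts equality between the two on randomized small datasets.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import pandas as pd


def oracle_qualifies(dates, min_codes, window_days):
    """Exhaustive-pair qualification check on one person's date multiset."""
    ds = sorted(pd.Timestamp(d) for d in dates)
    if len(ds) < min_codes:
        return None
    for k in range(len(ds)):
        upto = ds[: k + 1]
        if len(upto) < min_codes:
            continue
        has_pair = any(
            (b - a).days >= window_days
            for a, b in itertools.combinations(upto, 2)
        ) or window_days == 0
        if has_pair:
            return ds[k].date()
    return None


def oracle_nos_qualifies(nos_dates, specific_dates, window_days):
    """Earliest specific date >= some NOS date + window, by double loop."""
    best = None
    for s in specific_dates:
        s = pd.Timestamp(s)
        for n in nos_dates:
            if (s - pd.Timestamp(n)).days >= window_days:
                if best is None or s < best:
                    best = s
    return best.date() if best is not None else None


def oracle_cohort(events, code_set, persons, min_codes, window_days,
                  nos_codes=None, uses_nos_rule=False, remove_deceased=True):
    """Per-person loop version of disease-cohort membership.

    Returns {person_id: qualification_date}.
    """
    deceased = set(persons.loc[persons["death_date"].notna(), "person_id"])
    members = {}
    for pid, grp in events.groupby("person_id"):
        if remove_deceased and pid in deceased:
            continue
        own = [d for d, c in zip(grp["event_date"], grp["code"]) if c in code_set]
        q = oracle_qualifies(own, min_codes, window_days)
        if uses_nos_rule and nos_codes:
            nos = [d for d, c in zip(grp["event_date"], grp["code"])
                   if c in nos_codes]
            q2 = oracle_nos_qualifies(nos, own, window_days)
            if q2 is not None and (q is None or q2 < q):
                q = q2
        if q is not None:
            members[pid] = q
    return members


def oracle_denominator(events, persons, min_codes, window_days,
                       remove_deceased=True):
    deceased = set(persons.loc[persons["death_date"].notna(), "person_id"])
    members = {}
    for pid, grp in events.groupby("person_id"):
        if remove_deceased and pid in deceased:
            continue
        q = oracle_qualifies(list(grp["event_date"]), min_codes, window_days)
        if q is not None:
            members[pid] = q
    return members


def oracle_stratum_counts(member_ids, persons, age_bins, labels, ref_year):
    """Per-person recount of (sex, age_group) cell occupancy."""
    counts = defaultdict(int)
    other = 0
    info = persons.set_index("person_id")
    for pid in member_ids:
        sex = info.at[pid, "sex"]
        if sex not in ("female", "male"):
            other += 1
            continue
        age = ref_year - int(info.at[pid, "birth_year"])
        label = None
        for lo, lab in zip(age_bins, labels):
            if age >= lo:
                label = lab
        counts[(info.at[pid, "site_id"], sex, label)] += 1
    return dict(counts), other


def oracle_union(cohorts):
    """Set union over {disease: {person}} membership maps."""
    out = set()
    for members in cohorts.values():
        out |= set(members)
    return out


def oracle_multiplicity(cohorts, top_code=4):
    per_person = defaultdict(set)
    for did, members in cohorts.items():
        for pid in members:
            per_person[pid].add(did)
    counts = defaultdict(int)
    for pid, dzs in per_person.items():
        counts[min(len(dzs), top_code)] += 1
    return dict(counts)


def oracle_cooccurrence(cohorts):
    ids = sorted(cohorts)
    out = {}
    for i in ids:
        for j in ids:
            out[(i, j)] = len(set(cohorts[i]) & set(cohorts[j]))
    return out


def oracle_projection(cells):
    """Direct evaluation of sum_s (n_s/d_s) * N_s over (n, d, N) triples."""
    total = 0.0
    for n, d, N in cells:
        if d:
            total += (n / d) * N
    return total
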