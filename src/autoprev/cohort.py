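"""Temporal code-pair phenotyping: numerator and denominator cohorts.

The qualification rule is the study's core phenotype: a person counts as
diagnosed with a disease when at least ``min_codes`` diagnosis codes for the
disease exist at least ``window_days`` apart (default 2 codes, 30 days; the
span comparison is inclusive).  The same rule over *any* diagnosis code
defines the at-risk denominator population.  A catch-all "not otherwise
classified" (NOS) autoimmune code followed ``window_days`` or more later by a
specific disease code also qualifies the person for that specific disease.

Persons with a recorded death date are removed from both numerator and
denominator when ``remove_deceased`` is on (sites that do not capture death
simply have no death dates, so nothing is removed there); removing from both
sides preserves numerator ⊆ denominator.

The qualification date is the earliest date at which the criterion first
becomes satisfiable under a chronological scan — with ``min_codes=2`` this is
the earliest event date at least ``window_days`` after the first event.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ConfigError,
    NOS_DISEASE_ID,
    PhenotypeDefinition,
    QualificationParams,
)

COHORT_COLUMNS = ["disease_id", "person_id", "site_id", "qualification_date"]


def qualifies(event_dates: Iterable[date], params: QualificationParams) -> date | None:
    """Apply the code-count/date-window rule to one person's event dates.

    ``event_dates`` is a multiset (duplicates count toward ``min_codes`` but
    contribute zero span).  Returns the qualification date, or ``None``.
    """
    ds = sorted(pd.Timestamp(d) for d in event_dates)
    if len(ds) < params.min_codes:
        return None
    first = ds[0]
    for i, d in enumerate(ds):
        if i + 1 >= params.min_codes and (d - first).days >= params.window_days:
            return d.date()
    return None


def nos_qualifies(
    nos_dates: Iterable[date],
    specific_dates: Iterable[date],
    window_days: int,
) -> date | None:
    """NOS-then-specific rule for one person.

    Qualifies on the earliest specific-code date that falls ``window_days``
    or more *after* some NOS-code date; the direction matters (an NOS code
    recorded after the specific code does not qualify).
    """
    if window_days < 0:
        raise ConfigError(f"window_days must be >= 0, got {window_days}")
    nos = [pd.Timestamp(d) for d in nos_dates]
    if not nos:
        return None
    cutoff = min(nos) + pd.Timedelta(days=window_days)
    later = [pd.Timestamp(d) for d in specific_dates if pd.Timestamp(d) >= cutoff]
    return min(later).date() if later else None


def _qualification_table(events: pd.DataFrame, params: QualificationParams) -> pd.DataFrame:
    """Vectorized qualification over all persons in an event table.

    Returns one row per qualifying person: person_id, site_id,
    qualification_date.
    """
    if events.empty:
        return pd.DataFrame(columns=["person_id", "site_id", "qualification_date"])
    ev = events[["person_id", "site_id", "event_date"]].sort_values(
        ["person_id", "event_date"], kind="mergesort"
    )
    g = ev.groupby("person_id", sort=True)
    rank = g.cumcount() + 1
    first = g["event_date"].transform("min")
    span_ok = (ev["event_date"] - first).dt.days >= params.window_days
    ok = (rank >= params.min_codes) & span_ok
    hits = ev[ok]
    if hits.empty:
        return pd.DataFrame(columns=["person_id", "site_id", "qualification_date"])
    out = (
        hits.groupby("person_id", sort=True)
        .agg(site_id=("site_id", "first"), qualification_date=("event_date", "min"))
        .reset_index()
    )
    return out[["person_id", "site_id", "qualification_date"]]


def _nos_qualification_table(
    nos_events: pd.DataFrame, specific_events: pd.DataFrame, window_days: int
) -> pd.DataFrame:
    """Vectorized NOS-then-specific qualification across persons."""
    if nos_events.empty or specific_events.empty:
        return pd.DataFrame(columns=["person_id", "site_id", "qualification_date"])
    first_nos = nos_events.groupby("person_id")["event_date"].min().rename("first_nos")
    spec = specific_events[["person_id", "site_id", "event_date"]].merge(
        first_nos, on="person_id", how="inner"
    )
    eligible = spec[
        (spec["event_date"] - spec["first_nos"]).dt.days >= window_days
    ]
    if eligible.empty:
        return pd.DataFrame(columns=["person_id", "site_id", "qualification_date"])
    out = (
        eligible.sort_values(["person_id", "event_date"], kind="mergesort")
        .groupby("person_id", sort=True)
        .agg(site_id=("site_id", "first"), qualification_date=("event_date", "min"))
        .reset_index()
    )
    return out[["person_id", "site_id", "qualification_date"]]


def _drop_deceased(table: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    deceased = persons.loc[persons["death_date"].notna(), "person_id"]
    return table[~table["person_id"].isin(deceased)]


def build_disease_cohort(
    events: pd.DataFrame,
    phenotype: PhenotypeDefinition,
    persons: pd.DataFrame,
    params: QualificationParams = QualificationParams(),
    nos_phenotype: PhenotypeDefinition | None = None,
    remove_deceased: bool = True,
) -> pd.DataFrame:
    """Build the cohort of persons qualifying for one disease.

    Membership comes from the code-pair rule on the phenotype's own code set,
    or — when the phenotype participates in the NOS rule and an NOS phenotype
    is supplied — from an NOS code followed ``window_days`` or more later by
    a specific code.  A person qualifying by both routes appears once, with
    the earlier qualification date.

    Returns a frame with columns ``disease_id, person_id, site_id,
    qualification_date``, sorted by (site_id, person_id).
    """
    own = _qualification_table(
        events[events["code"].isin(phenotype.code_set)], params
    )
    routes = [own]
    if (
        phenotype.uses_nos_rule
        and nos_phenotype is not None
        and phenotype.disease_id != nos_phenotype.disease_id
    ):
        routes.append(
            _nos_qualification_table(
                events[events["code"].isin(nos_phenotype.code_set)],
                events[events["code"].isin(phenotype.code_set)],
                params.window_days,
            )
        )
    nonempty = [r for r in routes if len(r)]
    merged = (
        pd.concat(nonempty, ignore_index=True) if nonempty else routes[0]
    )
    if merged.empty:
        cohort = merged
    else:
        cohort = (
            merged.sort_values(["person_id", "qualification_date"], kind="mergesort")
            .drop_duplicates("person_id", keep="first")
        )
    if remove_deceased:
        cohort = _drop_deceased(cohort, persons)
    cohort = cohort.copy()
    cohort.insert(0, "disease_id", phenotype.disease_id)
    return (
        cohort[COHORT_COLUMNS]
        .sort_values(["site_id", "person_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def build_denominator(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    params: QualificationParams = QualificationParams(),
    remove_deceased: bool = True,
) -> pd.DataFrame:
    """Build the at-risk denominator population (any-diagnosis rule).

    Code identity is irrelevant: any ``min_codes`` diagnosis events spanning
    at least ``window_days`` qualify the person.  Returns ``person_id,
    site_id, qualification_date`` sorted by (site_id, person_id).
    """
    denom = _qualification_table(events, params)
    if remove_deceased:
        denom = _drop_deceased(denom, persons)
    return (
        denom.sort_values(["site_id", "person_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def build_all_cohorts(
    events: pd.DataFrame,
    phenotypes: Sequence[PhenotypeDefinition],
    persons: pd.DataFrame,
    params: QualificationParams = QualificationParams(),
    remove_deceased: bool = True,
) -> dict[str, pd.DataFrame]:
    """Build cohorts for every phenotype, applying the NOS conventions.

    The NOS phenotype (reserved id) feeds the NOS-then-specific route of the
    diseases flagged ``uses_nos_rule``; the NOS category itself retains only
    persons who qualify for NOS *alone*, i.e. for no specific disease.
    """
    by_id = {p.disease_id: p for p in phenotypes}
    if len(by_id) != len(phenotypes):
        raise ConfigError("duplicate disease_id among phenotypes")
    nos = by_id.get(NOS_DISEASE_ID)
    cohorts: dict[str, pd.DataFrame] = {}
    for p in phenotypes:
        if p.disease_id == NOS_DISEASE_ID:
            continue
        cohorts[p.disease_id] = build_disease_cohort(
            events, p, persons, params, nos_phenotype=nos,
            remove_deceased=remove_deceased,
        )
    if nos is not None:
        nos_cohort = build_disease_cohort(
            events, nos, persons, params, remove_deceased=remove_deceased
        )
        nonempty = [c for c in cohorts.values() if len(c)]
        if nonempty:
            specific_members = pd.concat(nonempty)["person_id"].unique()
            nos_cohort = nos_cohort[
                ~nos_cohort["person_id"].isin(specific_members)
            ].reset_index(drop=True)
        cohorts[NOS_DISEASE_ID] = nos_cohort
    return cohorts
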