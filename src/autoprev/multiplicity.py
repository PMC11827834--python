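"""Deduplicated aggregation and disease-multiplicity statistics.

Summing per-disease cohort sizes overstates the burden of autoimmune disease
as a class because patients frequently carry several autoimmune diagnoses.
The aggregate cohort is therefore the *set union* of the per-disease cohorts
keyed by (site, person), counting each patient once, and the multiplicity
distribution reports how many distinct qualifying diseases each aggregate
member has (top-coded at "4 or more" for display, raw counts retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .cohort import COHORT_COLUMNS

AGGREGATE_ID = "any_autoimmune_disease"


def aggregate_cohort(per_disease_cohorts: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union the per-disease cohorts into one deduplicated cohort.

    Each person appears once regardless of how many diseases they qualify
    for; the qualification date is the earliest across diseases.
    """
    frames = [c for c in per_disease_cohorts.values() if len(c)]
    if not frames:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    allc = pd.concat(frames, ignore_index=True)
    union = (
        allc.sort_values(["person_id", "qualification_date"], kind="mergesort")
        .drop_duplicates(["site_id", "person_id"], keep="first")
        .copy()
    )
    union["disease_id"] = AGGREGATE_ID
    return (
        union[COHORT_COLUMNS]
        .sort_values(["site_id", "person_id"], kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass
class MultiplicityDistribution:
    """Distribution of the number of distinct qualifying diseases per patient.

    ``counts[k]`` is the number of aggregate-cohort members with exactly
    ``k`` distinct diseases for ``k < top_code`` and with ``k >= top_code``
    at the top bin.  ``fractions`` are exact; ``percentages`` are rounded to
    integers for display.
    """

    counts: dict[int, int]
    n_total: int
    top_code: int
    per_person: pd.DataFrame  # person_id, site_id, k (raw, not top-coded)

    @property
    def fractions(self) -> dict[int, float]:
        if self.n_total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.n_total for k, v in self.counts.items()}

    @property
    def percentages(self) -> dict[int, int]:
        return {k: round(100.0 * f) for k, f in self.fractions.items()}

    def label(self, k: int) -> str:
        return f"{self.top_code}+" if k == self.top_code else str(k)


def multiplicity_distribution(
    per_disease_cohorts: Mapping[str, pd.DataFrame], top_code: int = 4
) -> MultiplicityDistribution:
    """Count distinct qualifying diseases per patient across cohorts.

    The NOS category counts as one disease for the persons it retains
    (those qualifying for NOS alone), so pass cohorts built with the NOS
    conventions already applied.
    """
    frames = [
        c[["person_id", "site_id", "disease_id"]]
        for c in per_disease_cohorts.values()
        if len(c)
    ]
    if not frames:
        return MultiplicityDistribution(
            {k: 0 for k in range(1, top_code + 1)}, 0, top_code,
            pd.DataFrame(columns=["person_id", "site_id", "k"]),
        )
    allc = pd.concat(frames, ignore_index=True).drop_duplicates()
    per_person = (
        allc.groupby(["site_id", "person_id"], sort=True)["disease_id"]
        .nunique()
        .rename("k")
        .reset_index()[["person_id", "site_id", "k"]]
    )
    capped = per_person["k"].clip(upper=top_code)
    vc = capped.value_counts()
    counts = {k: int(vc.get(k, 0)) for k in range(1, top_code + 1)}
    return MultiplicityDistribution(counts, len(per_person), top_code, per_person)


def cooccurrence_matrix(
    per_disease_cohorts: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Symmetric disease-by-disease co-membership count matrix.

    Off-diagonal entry (i, j) is the number of patients in both cohorts;
    the diagonal holds cohort sizes.
    """
    ids = sorted(per_disease_cohorts)
    frames = []
    for did in ids:
        c = per_disease_cohorts[did]
        if len(c):
            f = c[["site_id", "person_id"]].copy()
            f["disease_id"] = did
            frames.append(f)
    if not frames:
        return pd.DataFrame(0, index=ids, columns=ids)
    allc = pd.concat(frames, ignore_index=True)
    allc["member"] = 1
    x = (
        allc.pivot_table(
            index=["site_id", "person_id"],
            columns="disease_id",
            values="member",
            fill_value=0,
            aggfunc="max",
        )
        .reindex(columns=ids, fill_value=0)
    )
    m = x.T.values @ x.values
    return pd.DataFrame(m, index=ids, columns=ids)


def suppress_cooccurrence(matrix: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Mask positive cells below the suppression threshold as ``"<t"``."""
    out = matrix.copy().astype(object)
    mask = (matrix > 0) & (matrix < threshold)
    out = out.where(~mask, f"<{threshold}")
    return out
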