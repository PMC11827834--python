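"""Stratified prevalence estimation and census projection.

Direct standardization: numerator/denominator counts are stratified into
4 age groups x 2 sexes per site, each stratum's rate n_s/d_s is applied to
the corresponding reference-census population N_s, and the per-stratum
projections are summed:

    projected = sum_s (n_s / d_s) * N_s

Persons whose recorded sex is other/unknown are excluded from the eight
projection strata (the projection is defined over two sex categories) but
counted and reported under the privacy-suppression rules.

The confidence interval is a stratified binomial normal approximation,

    Var = sum_s N_s^2 * p_s (1 - p_s) / d_s,   p_s = n_s / d_s,

an artifact-defined contract: degenerate strata (p_s in {0, 1}) contribute
zero variance and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CensusTable,
    ConfigError,
    IntegrityError,
    ParameterError,
    PROJECTED_SEXES,
    StudyConfig,
)


def assign_stratum(
    sex: str,
    birth_year: int,
    age_bins: Sequence[int],
    reference_date: date,
) -> tuple[str, str] | None:
    """Assign one person to a (sex, age_group) projection stratum.

    Age is computed at year resolution (``year(reference) - birth_year``,
    the only reliably available resolution in OMOP person records) and bins
    are half-open ``[lo, hi)``.  Returns ``None`` for persons with sex
    other/unknown, who are excluded from projection.
    """
    age = reference_date.year - int(birth_year)
    if age < 0:
        raise IntegrityError(f"birth_year {birth_year} is after {reference_date}")
    if sex not in PROJECTED_SEXES:
        return None
    labels = StudyConfig(age_bins=tuple(age_bins)).age_group_labels()
    idx = int(np.searchsorted(np.asarray(age_bins), age, side="right")) - 1
    return sex, labels[idx]


def _strata_frame(
    persons: pd.DataFrame, config: StudyConfig, reference: pd.Series | None
) -> pd.DataFrame:
    """Vectorized stratum assignment: person_id, sex, age_group, projectable."""
    ref_year = (
        reference.dt.year
        if reference is not None
        else pd.Series(config.study_end.year, index=persons.index)
    )
    age = ref_year.values - persons["birth_year"].values
    if (age < 0).any():
        raise IntegrityError("birth_year after the stratification reference date")
    labels = config.age_group_labels()
    idx = np.searchsorted(np.asarray(config.age_bins), age, side="right") - 1
    out = persons[["person_id", "sex"]].copy()
    out["age_group"] = np.asarray(labels, dtype=object)[idx]
    out["projectable"] = out["sex"].isin(PROJECTED_SEXES)
    return out


@dataclass
class StratumTable:
    """Numerator/denominator counts per (site, sex, age-group) cell.

    ``counts`` has a (site_id, sex, age_group) MultiIndex and integer columns
    ``n`` (cohort members) and ``d`` (denominator members); ``n_other`` /
    ``d_other`` hold the persons excluded from projection because their sex
    is outside the two projected categories.
    """

    counts: pd.DataFrame
    age_bins: tuple[int, ...]
    n_other: int = 0
    d_other: int = 0

    @property
    def sites(self) -> list[str]:
        return sorted(self.counts.index.get_level_values("site_id").unique())

    def pooled(self) -> "StratumTable":
        """Sum cells across sites into a single-site table ('pooled')."""
        pooled = self.counts.groupby(level=["sex", "age_group"], sort=True).sum()
        pooled.index = pd.MultiIndex.from_arrays(
            [
                ["pooled"] * len(pooled),
                pooled.index.get_level_values("sex"),
                pooled.index.get_level_values("age_group"),
            ],
            names=["site_id", "sex", "age_group"],
        )
        return StratumTable(pooled, self.age_bins, self.n_other, self.d_other)

    def by_site(self) -> dict[str, "StratumTable"]:
        return {
            s: StratumTable(self.counts.loc[[s]], self.age_bins)
            for s in self.sites
        }

    def restrict(self, sex: str) -> "StratumTable":
        mask = self.counts.index.get_level_values("sex") == sex
        return StratumTable(self.counts[mask], self.age_bins)

    def marginal(self) -> pd.Series:
        """Collapsed (n, d) totals over all projectable cells."""
        return self.counts[["n", "d"]].sum()


def stratum_counts(
    cohort: pd.DataFrame,
    denominator: pd.DataFrame,
    persons: pd.DataFrame,
    config: StudyConfig,
    strict: bool = True,
) -> StratumTable:
    """Stratify cohort and denominator membership into counts per cell.

    With ``strict`` (the default) a cohort member absent from the denominator
    violates the algorithm contract and raises :class:`IntegrityError`;
    sensitivity sweeps that deliberately relax the numerator below the
    denominator rule pass ``strict=False``.
    """
    if strict and not cohort.empty:
        missing = ~cohort["person_id"].isin(denominator["person_id"])
        if missing.any():
            raise IntegrityError(
                "cohort member(s) missing from denominator: "
                f"{sorted(cohort['person_id'][missing])[:5]}"
            )
    demo = persons.set_index("person_id")

    def _counts(members: pd.DataFrame, col: str) -> tuple[pd.DataFrame, int]:
        m = members.merge(
            persons[["person_id", "sex", "birth_year"]], on="person_id", how="left"
        )
        if config.age_reference == "first_qualifying_date" and len(m):
            ref = pd.to_datetime(m["qualification_date"])
        else:
            ref = None
        strata = _strata_frame(m, config, ref)
        strata["site_id"] = m["site_id"].values
        n_other = int((~strata["projectable"]).sum())
        proj = strata[strata["projectable"]]
        c = (
            proj.groupby(["site_id", "sex", "age_group"], observed=True)
            .size()
            .rename(col)
            .to_frame()
        )
        return c, n_other

    n_cells, n_other = _counts(cohort, "n")
    d_cells, d_other = _counts(denominator, "d")
    sites = sorted(
        set(cohort["site_id"]).union(denominator["site_id"])
        if len(cohort) or len(denominator)
        else set()
    )
    full = pd.MultiIndex.from_product(
        [sites, list(PROJECTED_SEXES), config.age_group_labels()],
        names=["site_id", "sex", "age_group"],
    )
    counts = (
        pd.concat([n_cells, d_cells], axis=1)
        .reindex(full)
        .fillna(0)
        .astype(int)
    )
    if strict and (counts["n"] > counts["d"]).any():
        raise IntegrityError("stratum with more cohort members than denominator")
    return StratumTable(counts, config.age_bins, n_other, d_other)


@dataclass
class ProjectedEstimate:
    """A census-projected prevalence estimate.

    ``projected_count`` is in persons of the reference population;
    ``prevalence_pct`` is the percentage of the reference total;
    ``ci_low``/``ci_high`` bound the projected count.  ``breakdown`` carries
    the per-stratum n, d, census N, rate and projected contribution;
    conservation holds: the contributions sum to ``projected_count``.
    """

    projected_count: float
    prevalence_pct: float
    ci_low: float
    ci_high: float
    raw_n: int
    raw_d: int
    census_total: float
    breakdown: pd.DataFrame | None = None
    zero_denominator_strata: list = field(default_factory=list)
    degenerate_strata: list = field(default_factory=list)


def _aligned(table: StratumTable, census: CensusTable) -> pd.DataFrame:
    cells = table.counts.groupby(level=["sex", "age_group"], sort=True).sum()
    pop = census.series()
    merged = cells.join(pop.rename("N"), how="left")
    if merged["N"].isna().any():
        missing = merged.index[merged["N"].isna()].tolist()
        raise ConfigError(f"census lacks population for strata: {missing}")
    return merged


def project_to_census(
    table: StratumTable,
    census: CensusTable,
    level: float = 0.95,
) -> ProjectedEstimate:
    """Project stratified counts onto a reference census.

    Cells with ``d_s = 0`` (and necessarily ``n_s = 0``) contribute nothing
    and are flagged; ``n_s > 0`` with ``d_s = 0`` is an integrity error.
    The table is pooled over sites before projecting.
    """
    merged = _aligned(table, census)
    bad = (merged["n"] > 0) & (merged["d"] == 0)
    if bad.any():
        raise IntegrityError(
            f"stratum with cases but empty denominator: {merged.index[bad].tolist()}"
        )
    d_safe = merged["d"].replace(0, 1)
    merged["rate"] = merged["n"] / d_safe
    merged["projected"] = merged["rate"] * merged["N"]
    zero_d = merged.index[merged["d"] == 0].tolist()
    projected = float(merged["projected"].sum())
    total = float(merged["N"].sum())
    lo, hi, degenerate = _ci_from_cells(merged, projected, level)
    return ProjectedEstimate(
        projected_count=projected,
        prevalence_pct=100.0 * projected / total if total else float("nan"),
        ci_low=lo,
        ci_high=hi,
        raw_n=int(merged["n"].sum()),
        raw_d=int(merged["d"].sum()),
        census_total=total,
        breakdown=merged,
        zero_denominator_strata=zero_d,
        degenerate_strata=degenerate,
    )


def _ci_from_cells(
    merged: pd.DataFrame, projected: float, level: float
) -> tuple[float, float, list]:
    if not (0.0 < level < 1.0):
        raise ParameterError(f"confidence level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = merged["rate"]
    with np.errstate(invalid="ignore"):
        var_cells = merged["N"] ** 2 * p * (1.0 - p) / merged["d"].replace(0, 1)
    degenerate = merged.index[
        ((p == 0) | (p == 1)) & (merged["d"] > 0)
    ].tolist()
    var = float(var_cells.fillna(0.0).sum())
    half = z * np.sqrt(var)
    return projected - half, projected + half, degenerate


def confidence_interval(
    table: StratumTable, census: CensusTable, level: float = 0.95
) -> tuple[float, float]:
    """Stratified binomial normal-approximation CI on the projected count."""
    est = project_to_census(table, census, level=level)
    return est.ci_low, est.ci_high


def pool_sites(
    tables: Sequence[StratumTable],
    mode: str = "pool_counts",
    census: CensusTable | None = None,
    level: float = 0.95,
):
    """Combine per-site stratum tables.

    ``pool_counts`` (default) sums cells across sites and returns one
    :class:`StratumTable`; ``average_projections`` projects each site
    separately and returns a :class:`ProjectedEstimate` whose count (and CI
    bounds) are the mean over sites.  The modes agree exactly when all sites
    share identical stratum denominators.
    """
    if not tables:
        raise ParameterError("no stratum tables to pool")
    bins = {t.age_bins for t in tables}
    if len(bins) != 1:
        raise ConfigError(f"mismatched age bins across sites: {sorted(bins)}")
    if mode == "pool_counts":
        counts = pd.concat([t.counts for t in tables])
        return StratumTable(
            counts,
            tables[0].age_bins,
            sum(t.n_other for t in tables),
            sum(t.d_other for t in tables),
        ).pooled()
    if mode == "average_projections":
        if census is None:
            raise ParameterError("average_projections pooling requires a census")
        ests = [project_to_census(t, census, level=level) for t in tables]
        k = len(ests)
        mean_count = sum(e.projected_count for e in ests) / k
        total = ests[0].census_total
        return ProjectedEstimate(
            projected_count=mean_count,
            prevalence_pct=100.0 * mean_count / total if total else float("nan"),
            ci_low=sum(e.ci_low for e in ests) / k,
            ci_high=sum(e.ci_high for e in ests) / k,
            raw_n=sum(e.raw_n for e in ests),
            raw_d=sum(e.raw_d for e in ests),
            census_total=total,
        )
    raise ParameterError(f"unknown pooling mode: {mode!r}")


def suppress(
    report: pd.DataFrame,
    count_threshold: int = 10,
    other_threshold: int = 20,
) -> pd.DataFrame:
    """Apply small-cell suppression to a per-disease report table.

    Any row whose raw patient count (``raw_n``) is positive but below
    ``count_threshold`` has its count masked as ``"<t"`` and every estimate
    column withheld; counts of other/unknown-sex persons (``n_other``)
    below ``other_threshold`` are masked likewise.  Masking happens before
    serialization and the masked values are irrecoverable from the output.
    """
    out = report.copy().astype(object)
    value_cols = [
        c
        for c in ("raw_n", "raw_d", "projected_count", "prevalence_pct",
                  "ci_low", "ci_high")
        if c in out.columns
    ]
    mask = (report["raw_n"] > 0) & (report["raw_n"] < count_threshold)
    out.loc[mask, "raw_n"] = f"<{count_threshold}"
    for col in value_cols:
        if col != "raw_n":
            out.loc[mask, col] = ""
    if "n_other" in out.columns:
        m = (report["n_other"] > 0) & (report["n_other"] < other_threshold)
        out.loc[m, "n_other"] = f"<{other_threshold}"
    out.attrs["n_suppressed"] = int(mask.sum())
    return out
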