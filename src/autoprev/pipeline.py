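"""End-to-end prevalence run: load → map → cohorts → projection → report.

``run_prevalence`` executes the whole analysis from an input specification
and returns a :class:`RunReport`; ``write_outputs`` serializes the report
(with small-cell suppression applied) to CSV/JSON.  Reruns with identical
inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import multiplicity as mp
from .cohort import build_all_cohorts, build_denominator
from .data_model import (
    CensusTable,
    ConfigError,
    NOS_DISEASE_ID,
    ParameterError,
    PhenotypeDefinition,
    PROJECTED_SEXES,
    StudyConfig,
    load_census,
    load_concept_map,
    load_phenotypes,
    map_concepts,
    read_omop_lite,
)
from .prevalence import (
    ProjectedEstimate,
    StratumTable,
    pool_sites,
    project_to_census,
    stratum_counts,
    suppress,
)

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "disease_id", "sex", "raw_n", "raw_d",
    "projected_count", "prevalence_pct", "ci_low", "ci_high",
]


@dataclass
class RunReport:
    """Everything a prevalence run produced, ready for serialization."""

    config: StudyConfig
    counters: dict
    prevalence_table: pd.DataFrame  # REPORT_COLUMNS (+ n_other on totals)
    aggregate: ProjectedEstimate
    multiplicity: mp.MultiplicityDistribution
    cooccurrence: pd.DataFrame
    rankings: dict[str, pd.DataFrame]
    warnings: list[str] = field(default_factory=list)


def _estimate_rows(
    disease_id: str,
    table: StratumTable,
    census: CensusTable,
) -> list[dict]:
    """Total plus per-sex report rows for one disease's pooled table."""
    rows = []
    overall = project_to_census(table, census)
    rows.append(_row(disease_id, "total", overall, n_other=table.n_other))
    for sex in PROJECTED_SEXES:
        est = project_to_census(table.restrict(sex), census.restrict(sex))
        rows.append(_row(disease_id, sex, est))
    return rows


def _row(disease_id: str, sex: str, est: ProjectedEstimate, n_other: int | None = None) -> dict:
    r = {
        "disease_id": disease_id,
        "sex": sex,
        "raw_n": est.raw_n,
        "raw_d": est.raw_d,
        "projected_count": round(est.projected_count, 1),
        "prevalence_pct": round(est.prevalence_pct, 4),
        "ci_low": round(est.ci_low, 1),
        "ci_high": round(est.ci_high, 1),
    }
    if n_other is not None:
        r["n_other"] = n_other
    return r


def rank_diseases(
    prevalence_table: pd.DataFrame, by: str = "projected_count", k: int = 20
) -> pd.DataFrame:
    """Rank diseases by projected count or by sex share of raw cases.

    ``by`` is one of ``projected_count``, ``female_share``, ``male_share``;
    shares are computed from raw female/male case counts.  Ties break by
    lexicographic ``disease_id`` so rankings are deterministic.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if by not in ("projected_count", "female_share", "male_share"):
        raise ParameterError(f"unknown ranking key: {by!r}")
    t = prevalence_table
    totals = t[t["sex"] == "total"][["disease_id", "raw_n", "projected_count"]]
    bysex = t[t["sex"].isin(PROJECTED_SEXES)].pivot(
        index="disease_id", columns="sex", values="raw_n"
    ).fillna(0)
    merged = totals.merge(bysex, on="disease_id", how="left").fillna(0)
    fm = merged["female"] + merged["male"]
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["female_share"] = np.where(fm > 0, merged["female"] / fm, np.nan)
    merged["male_share"] = 1.0 - merged["female_share"]
    merged = merged.dropna(subset=[by]) if by != "projected_count" else merged
    ranked = merged.sort_values(
        [by, "disease_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    return ranked.reset_index(drop=True)


@dataclass
class RunInputs:
    """Resolved inputs of a prevalence run (paths or in-memory objects)."""

    persons: pd.DataFrame
    events: pd.DataFrame
    phenotypes: Sequence[PhenotypeDefinition]
    census: CensusTable
    counters: dict = field(default_factory=dict)


def load_inputs(
    person_path: str | Path,
    condition_path: str | Path,
    phenotype_path: str | Path,
    census_path: str | Path,
    config: StudyConfig,
    concept_map_path: str | Path | None = None,
    lenient: bool = False,
) -> RunInputs:
    """Load and validate all inputs, applying concept mapping if configured."""
    loaded = read_omop_lite(person_path, condition_path, config, lenient=lenient)
    counters = {
        "persons_read": len(loaded.persons),
        "events_read": len(loaded.events) + loaded.n_events_outside_window,
        "events_outside_window": loaded.n_events_outside_window,
        "rows_dropped_lenient": loaded.n_rows_dropped_lenient,
        "events_unmapped": 0,
    }
    events = loaded.events
    if concept_map_path is not None:
        cmap = load_concept_map(concept_map_path)
        mapped = map_concepts(events, cmap)
        counters["events_unmapped"] = len(mapped.unmapped)
        events = mapped.mapped
    phenotypes = load_phenotypes(phenotype_path)
    census = load_census(census_path, config)
    return RunInputs(loaded.persons, events, phenotypes, census, counters)


def run_prevalence(inputs: RunInputs, config: StudyConfig) -> RunReport:
    """Execute the full prevalence analysis on loaded inputs."""
    persons, events = inputs.persons, inputs.events
    warnings: list[str] = []
    counters = dict(inputs.counters)
    counters["deceased_removed"] = (
        int(persons["death_date"].notna().sum()) if config.remove_deceased else 0
    )

    denominator = build_denominator(
        events, persons, config.denominator_params,
        remove_deceased=config.remove_deceased,
    )
    counters["denominator_size"] = len(denominator)
    cohorts = build_all_cohorts(
        events, inputs.phenotypes, persons, config.numerator_params,
        remove_deceased=config.remove_deceased,
    )
    counters["per_disease_members"] = {
        did: len(c) for did, c in sorted(cohorts.items())
    }

    rows: list[dict] = []
    for did in sorted(cohorts):
        table = _pooled_table(cohorts[did], denominator, persons, config,
                              inputs.census)
        rows.extend(_estimate_rows(did, table, inputs.census))

    union = mp.aggregate_cohort(cohorts)
    counters["aggregate_members"] = len(union)
    agg_table = _pooled_table(union, denominator, persons, config, inputs.census)
    aggregate = project_to_census(agg_table, inputs.census)
    rows.extend(_estimate_rows(mp.AGGREGATE_ID, agg_table, inputs.census))
    if aggregate.zero_denominator_strata:
        warnings.append(
            f"strata with empty denominator: {aggregate.zero_denominator_strata}"
        )

    prevalence_table = pd.DataFrame(rows)
    dist = mp.multiplicity_distribution(cohorts)
    cooc = mp.cooccurrence_matrix(cohorts)
    rankings = {
        by: rank_diseases(
            prevalence_table[prevalence_table["disease_id"] != mp.AGGREGATE_ID],
            by=by, k=20,
        )
        for by in ("projected_count", "female_share", "male_share")
    }
    return RunReport(
        config=config,
        counters=counters,
        prevalence_table=prevalence_table,
        aggregate=aggregate,
        multiplicity=dist,
        cooccurrence=cooc,
        rankings=rankings,
        warnings=warnings,
    )


def _pooled_table(
    cohort: pd.DataFrame,
    denominator: pd.DataFrame,
    persons: pd.DataFrame,
    config: StudyConfig,
    census: CensusTable,
) -> StratumTable:
    table = stratum_counts(cohort, denominator, persons, config)
    pooled = pool_sites(list(table.by_site().values()), "pool_counts")
    # carry the excluded-sex counters through pooling
    pooled.n_other, pooled.d_other = table.n_other, table.d_other
    return pooled


def write_outputs(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a run report with suppression applied.

    Writes ``prevalence_report.csv``, ``multiplicity.csv``,
    ``cooccurrence.csv`` and ``run_report.json``; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    masked = suppress(
        report.prevalence_table,
        cfg.suppression_threshold_counts,
        cfg.suppression_threshold_sex_other,
    )
    paths = {
        "prevalence": out / "prevalence_report.csv",
        "multiplicity": out / "multiplicity.csv",
        "cooccurrence": out / "cooccurrence.csv",
        "report": out / "run_report.json",
    }
    masked.to_csv(paths["prevalence"], index=False)

    dist = report.multiplicity
    mult = pd.DataFrame(
        {
            "k": [dist.label(k) for k in sorted(dist.counts)],
            "count": [dist.counts[k] for k in sorted(dist.counts)],
            "percent": [dist.percentages[k] for k in sorted(dist.counts)],
        }
    )
    mult.to_csv(paths["multiplicity"], index=False)

    cooc = mp.suppress_cooccurrence(
        report.cooccurrence, cfg.suppression_threshold_counts
    )
    cooc_long = (
        cooc.stack().rename("count").rename_axis(["disease_i", "disease_j"])
        .reset_index()
    )
    cooc_long.to_csv(paths["cooccurrence"], index=False)

    n_other_total = report.prevalence_table.get("n_other")
    payload = {
        "config": cfg.echo(),
        "counters": _suppress_counters(report.counters, cfg),
        "aggregate": {
            "projected_count": round(report.aggregate.projected_count, 1),
            "prevalence_pct": round(report.aggregate.prevalence_pct, 4),
            "ci_low": round(report.aggregate.ci_low, 1),
            "ci_high": round(report.aggregate.ci_high, 1),
            "raw_n": report.aggregate.raw_n,
            "raw_d": report.aggregate.raw_d,
        },
        "multiplicity": {
            dist.label(k): {"count": dist.counts[k], "percent": dist.percentages[k]}
            for k in sorted(dist.counts)
        },
        "warnings": report.warnings,
    }
    paths["report"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return paths


def _suppress_counters(counters: dict, cfg: StudyConfig) -> dict:
    out = dict(counters)
    per_disease = out.get("per_disease_members")
    if isinstance(per_disease, dict):
        t = cfg.suppression_threshold_counts
        out["per_disease_members"] = {
            did: (f"<{t}" if 0 < n < t else n) for did, n in per_disease.items()
        }
    return out
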