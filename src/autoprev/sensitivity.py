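"""Sensitivity analysis over code counts and date windows.

The qualification rule has two dials on each side — the number of codes and
the date window, for numerator and denominator independently.  The sweep
recomputes the whole cohort pipeline from scratch for every setting pair (no
incremental shortcuts, so every grid row equals an independent one-off run)
and reports numerator count, denominator count, crude prevalence and
census-projected prevalence.  The overstatement comparison quantifies how
much a laxer numerator rule (e.g. a single code with no window) inflates
case counts relative to a reference rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cohort import build_all_cohorts, build_denominator
from .data_model import (
    CensusTable,
    ParameterError,
    PhenotypeDefinition,
    QualificationParams,
    StudyConfig,
)
from .multiplicity import aggregate_cohort
from .prevalence import project_to_census, stratum_counts

GRID_COLUMNS = [
    "num_min_codes", "num_window_days", "den_min_codes", "den_window_days",
    "numerator_count", "denominator_count",
    "crude_prevalence_pct", "projected_prevalence_pct",
]


def _as_params(setting) -> QualificationParams:
    if isinstance(setting, QualificationParams):
        return setting
    return QualificationParams(*setting)


def sweep(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    phenotypes: Sequence[PhenotypeDefinition],
    numerator_settings: Sequence,
    denominator_settings: Sequence,
    config: StudyConfig,
    census: CensusTable | None = None,
) -> pd.DataFrame:
    """Run the full pipeline for every (numerator, denominator) setting pair.

    Settings are ``QualificationParams`` or ``(min_codes, window_days)``
    tuples; all are validated before any computation starts.  Rows appear in
    the given order (denominator-major), so the output is deterministic.
    The numerator count is the size of the deduplicated aggregate cohort.
    """
    if not numerator_settings or not denominator_settings:
        raise ParameterError("numerator and denominator settings must be non-empty")
    num_params = [_as_params(s) for s in numerator_settings]
    den_params = [_as_params(s) for s in denominator_settings]
    rows = []
    for dp in den_params:
        denominator = build_denominator(
            events, persons, dp, remove_deceased=config.remove_deceased
        )
        for np_ in num_params:
            cohorts = build_all_cohorts(
                events, phenotypes, persons, np_,
                remove_deceased=config.remove_deceased,
            )
            union = aggregate_cohort(cohorts)
            n, d = len(union), len(denominator)
            crude = 100.0 * n / d if d else float("nan")
            projected = float("nan")
            if census is not None and d:
                table = stratum_counts(union, denominator, persons, config,
                                       strict=False)
                projected = project_to_census(table, census).prevalence_pct
            rows.append({
                "num_min_codes": np_.min_codes,
                "num_window_days": np_.window_days,
                "den_min_codes": dp.min_codes,
                "den_window_days": dp.window_days,
                "numerator_count": n,
                "denominator_count": d,
                "crude_prevalence_pct": crude,
                "projected_prevalence_pct": projected,
            })
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


@dataclass
class Overstatement:
    """Percent change of an alternative rule relative to a reference rule.

    Positive means the alternative counts more; ``None`` when the reference
    count is zero (undefined, reported as such rather than raised).
    """

    numerator_pct_change: float | None
    prevalence_pct_change: float | None


def _find_row(grid: pd.DataFrame, setting) -> pd.Series:
    num, den = setting
    num, den = _as_params(num), _as_params(den)
    m = grid[
        (grid["num_min_codes"] == num.min_codes)
        & (grid["num_window_days"] == num.window_days)
        & (grid["den_min_codes"] == den.min_codes)
        & (grid["den_window_days"] == den.window_days)
    ]
    if m.empty:
        raise ParameterError(f"setting {setting} not present in the grid")
    return m.iloc[0]


def overstatement(grid: pd.DataFrame, reference_setting, alternative_setting) -> Overstatement:
    """Compare two grid rows, each a (numerator, denominator) setting pair."""
    ref = _find_row(grid, reference_setting)
    alt = _find_row(grid, alternative_setting)

    def _pct(a: float, r: float) -> float | None:
        if r == 0 or pd.isna(r):
            return None
        return 100.0 * (a - r) / r

    return Overstatement(
        numerator_pct_change=_pct(alt["numerator_count"], ref["numerator_count"]),
        prevalence_pct_change=_pct(
            alt["crude_prevalence_pct"], ref["crude_prevalence_pct"]
        ),
    )
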