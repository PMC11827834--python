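"""Domain types and OMOP-lite table I/O.

The prevalence pipeline operates on two flat tables extracted from an OMOP
common-data-model instance: a *person* table (demographics) and a
*condition-occurrence* table (one coded diagnosis per row).  Only the columns
the algorithms actually touch are kept — the "OMOP-lite" dialect — so a site
can produce the extract with a single SQL query and no database dependency is
needed here:

``person.csv``
    ``person_id,sex,birth_year,death_date,site_id`` (``death_date`` may be
    empty; dates are ISO-8601 calendar dates).
``condition_occurrence.csv``
    ``person_id,vocabulary,code,event_date,site_id``.
``concept_map.csv``
    ``source_vocabulary,source_code,standard_code`` — a many-to-one
    source-to-standard vocabulary mapping (e.g. ICD-9/ICD-10 to SNOMED).
``census.csv``
    ``sex,age_group,population`` — the reference population the stratified
    rates are projected onto.

Parquet files with the same columns are accepted wherever a CSV path is
expected (detected by the ``.parquet`` suffix).

Codes are compared as exact strings after vocabulary qualification; no
hierarchical (descendant) expansion is performed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: vocabulary tag of already-standardized codes
STANDARD_VOCABULARY = "SNOMED"

#: reserved phenotype id for the catch-all "autoimmune disease not otherwise
#: classified" category, which also participates in the NOS-then-specific
#: qualification rule
NOS_DISEASE_ID = "autoimmune_disease_nos"

PERSON_COLUMNS = ["person_id", "sex", "birth_year", "death_date", "site_id"]
EVENT_COLUMNS = ["person_id", "vocabulary", "code", "event_date", "site_id"]


class AutoprevError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(AutoprevError):
    """An input file does not match the documented OMOP-lite dialect."""


class IntegrityError(AutoprevError):
    """Records are internally inconsistent (duplicate ids, dangling refs...)."""


class ConfigError(AutoprevError):
    """A configuration file or object is invalid."""


class ParameterError(AutoprevError):
    """An operation was called with an out-of-range parameter."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER = "other"
    UNKNOWN = "unknown"


_SEX_TOKENS = {
    "female": Sex.FEMALE, "f": Sex.FEMALE,
    "male": Sex.MALE, "m": Sex.MALE,
    "other": Sex.OTHER,
    "unknown": Sex.UNKNOWN, "": Sex.UNKNOWN,
}

#: sexes that enter the 2-sex x 4-age projection strata
PROJECTED_SEXES = (Sex.FEMALE.value, Sex.MALE.value)


def parse_sex(token: str) -> str:
    """Normalize an EHR gender token to one of the four sex categories."""
    try:
        return _SEX_TOKENS[str(token).strip().lower()].value
    except KeyError:
        raise SchemaError(f"unrecognized sex value: {token!r}") from None


@dataclass(frozen=True)
class QualificationParams:
    """Parameters of the temporal code-pair qualification rule.

    A person qualifies when at least ``min_codes`` dated diagnosis events
    exist and the span between the earliest and some later event is at least
    ``window_days`` (inclusive: a span of exactly ``window_days`` qualifies).
    """

    min_codes: int = 2
    window_days: int = 30

    def __post_init__(self) -> None:
        if self.min_codes < 1:
            raise ParameterError(f"min_codes must be >= 1, got {self.min_codes}")
        if self.window_days < 0:
            raise ParameterError(
                f"window_days must be >= 0, got {self.window_days}"
            )


@dataclass(frozen=True)
class StudyConfig:
    """Study window, qualification, stratification and reporting settings.

    Numerator and denominator rules are parameterized independently so the
    date windows can be varied on either side without touching the other.

    Parameters
    ----------
    age_bins
        Ordered lower cut points of the age groups, starting at 0; bins are
        half-open ``[lo, hi)`` and the last bin is unbounded.  The default
        ``(0, 18, 45, 65)`` yields the four groups 0-17, 18-44, 45-64, 65+.
    age_reference
        ``"study_end"`` (age at the end of the study window, the default) or
        ``"first_qualifying_date"`` (age at each person's qualification date).
    suppression_threshold_counts
        Disease-level patient counts below this are masked as ``"<t"`` and
        their projections withheld.
    suppression_threshold_sex_other
        Counts of persons with sex other/unknown below this are masked.
    """

    study_start: date = date(2011, 1, 1)
    study_end: date = date(2022, 6, 1)
    numerator_min_codes: int = 2
    numerator_window_days: int = 30
    denominator_min_codes: int = 2
    denominator_window_days: int = 30
    age_bins: tuple[int, ...] = (0, 18, 45, 65)
    age_reference: str = "study_end"
    suppression_threshold_counts: int = 10
    suppression_threshold_sex_other: int = 20
    remove_deceased: bool = True
    pool_mode: str = "pool_counts"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        bins = tuple(self.age_bins)
        if bins[0] != 0 or any(b >= c for b, c in zip(bins, bins[1:])):
            raise ConfigError(
                "age_bins must start at 0 and be strictly increasing"
            )
        if self.age_reference not in ("study_end", "first_qualifying_date"):
            raise ConfigError(f"unknown age_reference: {self.age_reference!r}")
        if self.pool_mode not in ("pool_counts", "average_projections"):
            raise ConfigError(f"unknown pool_mode: {self.pool_mode!r}")
        object.__setattr__(self, "age_bins", bins)

    @property
    def numerator_params(self) -> QualificationParams:
        return QualificationParams(self.numerator_min_codes, self.numerator_window_days)

    @property
    def denominator_params(self) -> QualificationParams:
        return QualificationParams(self.denominator_min_codes, self.denominator_window_days)

    def age_group_labels(self) -> list[str]:
        """Display labels of the age groups, e.g. ``['0-17', ..., '65+']``."""
        bins = self.age_bins
        labels = [f"{lo}-{hi - 1}" for lo, hi in zip(bins, bins[1:])]
        labels.append(f"{bins[-1]}+")
        return labels

    def echo(self) -> dict:
        """JSON-serializable echo of the configuration for run reports."""
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["age_bins"] = list(self.age_bins)
        return d


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A disease phenotype: a set of standard codes plus NOS-rule flag."""

    disease_id: str
    display_name: str
    code_set: frozenset[str]
    uses_nos_rule: bool = False

    def __post_init__(self) -> None:
        if not self.code_set:
            raise ConfigError(f"phenotype {self.disease_id!r} has an empty code set")
        object.__setattr__(self, "code_set", frozenset(self.code_set))


@dataclass(frozen=True)
class ConceptMap:
    """Source-to-standard code mapping, keyed by (vocabulary, code)."""

    entries: Mapping[tuple[str, str], str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"vocabulary": v, "code": c, "standard_code": s}
            for (v, c), s in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["vocabulary", "code", "standard_code"])


@dataclass
class CensusTable:
    """Reference population counts per (sex, age_group) stratum."""

    table: pd.DataFrame  # columns sex, age_group, population

    def __post_init__(self) -> None:
        t = self.table
        if (t["population"] < 0).any():
            raise ConfigError("census populations must be non-negative")
        if t.duplicated(["sex", "age_group"]).any():
            raise ConfigError("duplicate (sex, age_group) rows in census table")

    @property
    def total(self) -> float:
        return float(self.table["population"].sum())

    def restrict(self, sex: str) -> "CensusTable":
        """Census restricted to one sex (for sex-specific projections)."""
        return CensusTable(self.table[self.table["sex"] == sex].reset_index(drop=True))

    def series(self) -> pd.Series:
        return self.table.set_index(["sex", "age_group"])["population"]


@dataclass
class LoadResult:
    """Validated OMOP-lite tables plus exclusion counters."""

    persons: pd.DataFrame
    events: pd.DataFrame
    n_events_outside_window: int = 0
    n_rows_dropped_lenient: int = 0


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file does not exist: {path}")
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def _parse_dates(s: pd.Series, what: str, lenient: bool) -> pd.Series:
    parsed = pd.to_datetime(s.replace("", pd.NA), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & s.replace("", pd.NA).notna()
    if bad.any() and not lenient:
        raise SchemaError(
            f"{what}: {int(bad.sum())} unparseable date(s), e.g. {s[bad].iloc[0]!r}"
        )
    return parsed


def read_omop_lite(
    person_path: str | Path,
    condition_path: str | Path,
    config: StudyConfig,
    lenient: bool = False,
) -> LoadResult:
    """Read and validate OMOP-lite person and condition-occurrence tables.

    Diagnosis events dated outside ``[study_start, study_end]`` are dropped
    and counted in :attr:`LoadResult.n_events_outside_window`.  Unparseable
    rows raise :class:`SchemaError` unless ``lenient`` is set, in which case
    they are dropped and counted.

    Raises
    ------
    SchemaError
        Missing columns or unparseable values (strict mode).
    IntegrityError
        Duplicate ``person_id``, events referencing unknown persons, or a
        death date before the birth year.
    """
    persons = _read_table(person_path)
    events = _read_table(condition_path)
    _require_columns(persons, PERSON_COLUMNS, "person table")
    _require_columns(events, EVENT_COLUMNS, "condition_occurrence table")
    persons = persons[PERSON_COLUMNS].copy()
    events = events[EVENT_COLUMNS].copy()
    dropped = 0

    dup = persons["person_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"duplicate person_id(s): {sorted(persons['person_id'][dup])[:5]}"
        )
    persons["sex"] = persons["sex"].map(parse_sex)
    birth = pd.to_numeric(persons["birth_year"], errors="coerce")
    if birth.isna().any():
        if lenient:
            dropped += int(birth.isna().sum())
            persons = persons[birth.notna()]
            birth = birth.dropna()
        else:
            raise SchemaError("person table: non-integer birth_year")
    persons["birth_year"] = birth.astype(int)
    if (persons["birth_year"] > config.study_end.year).any():
        raise IntegrityError("birth_year after the end of the study window")
    persons["death_date"] = _parse_dates(persons["death_date"], "death_date", lenient)
    born = pd.to_datetime(persons["birth_year"].astype(str) + "-01-01")
    bad_death = persons["death_date"].notna() & (persons["death_date"] < born)
    if bad_death.any():
        raise IntegrityError(
            f"death before birth for person_id(s): "
            f"{sorted(persons['person_id'][bad_death])[:5]}"
        )

    events["event_date"] = _parse_dates(events["event_date"], "event_date", lenient)
    bad = events["event_date"].isna()
    if bad.any():  # only reachable in lenient mode
        dropped += int(bad.sum())
        events = events[~bad]
    unknown = ~events["person_id"].isin(persons["person_id"])
    if unknown.any():
        raise IntegrityError(
            "condition_occurrence references unknown person_id(s): "
            f"{sorted(set(events['person_id'][unknown]))[:5]}"
        )
    in_window = events["event_date"].between(
        pd.Timestamp(config.study_start), pd.Timestamp(config.study_end)
    )
    n_outside = int((~in_window).sum())
    if n_outside:
        logger.info("dropped %d event(s) outside the study window", n_outside)
    events = events[in_window].reset_index(drop=True)
    return LoadResult(
        persons.reset_index(drop=True), events, n_outside, dropped
    )


def write_omop_lite(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    person_path: str | Path,
    condition_path: str | Path,
) -> None:
    """Write person/condition tables back in the OMOP-lite CSV dialect."""
    p = persons.copy()
    p["death_date"] = p["death_date"].map(
        lambda d: "" if pd.isna(d) else pd.Timestamp(d).date().isoformat()
    )
    p[PERSON_COLUMNS].to_csv(person_path, index=False)
    e = events.copy()
    e["event_date"] = e["event_date"].map(lambda d: pd.Timestamp(d).date().isoformat())
    e[EVENT_COLUMNS].to_csv(condition_path, index=False)


@dataclass
class MappingResult:
    """Outcome of source-to-standard concept mapping (conservation holds:
    ``len(mapped) + len(unmapped) == len(input)``)."""

    mapped: pd.DataFrame
    unmapped: pd.DataFrame


def load_concept_map(path: str | Path) -> ConceptMap:
    """Load a source-to-standard concept mapping table.

    Raises :class:`ConfigError` if any (vocabulary, code) key is mapped to
    two different standard codes.
    """
    df = _read_table(path)
    _require_columns(df, ["source_vocabulary", "source_code", "standard_code"],
                     "concept map")
    entries: dict[tuple[str, str], str] = {}
    for voc, code, std in df[
        ["source_vocabulary", "source_code", "standard_code"]
    ].itertuples(index=False):
        key = (voc, code)
        if entries.get(key, std) != std:
            raise ConfigError(
                f"ambiguous concept mapping for {key}: "
                f"{entries[key]!r} vs {std!r}"
            )
        entries[key] = std
    return ConceptMap(entries)


def map_concepts(events: pd.DataFrame, concept_map: ConceptMap) -> MappingResult:
    """Map source-vocabulary diagnosis codes to the standard vocabulary.

    Events already tagged with :data:`STANDARD_VOCABULARY` pass through
    unchanged; events whose (vocabulary, code) is absent from the map are
    routed to the ``unmapped`` sink, never silently dropped.  The operation
    is idempotent.
    """
    std_mask = events["vocabulary"] == STANDARD_VOCABULARY
    std = events[std_mask]
    rest = events[~std_mask]
    if rest.empty:
        return MappingResult(events.copy(), rest.copy())
    mapping = concept_map.to_frame()
    merged = rest.merge(mapping, on=["vocabulary", "code"], how="left",
                        suffixes=("", "_std"))
    merged.index = rest.index
    hit = merged["standard_code"].notna()
    mapped_rest = rest[hit.values].copy()
    mapped_rest["code"] = merged.loc[hit, "standard_code"].values
    mapped_rest["vocabulary"] = STANDARD_VOCABULARY
    unmapped = rest[~hit.values].copy()
    mapped = pd.concat([std, mapped_rest]).sort_index()
    if len(unmapped):
        logger.warning("%d event(s) could not be mapped to %s",
                       len(unmapped), STANDARD_VOCABULARY)
    return MappingResult(mapped.reset_index(drop=True),
                         unmapped.reset_index(drop=True))


def load_phenotypes(path: str | Path) -> list[PhenotypeDefinition]:
    """Load phenotype definitions from a YAML file.

    Expected layout::

        phenotypes:
          - id: rheumatoid_arthritis
            name: Rheumatoid arthritis
            codes: ["69896004"]
            uses_nos_rule: true

    Overlapping code sets between diseases are permitted (a code may feed
    more than one phenotype) and logged.  Duplicate ids, empty code sets, or
    a repeated reserved NOS id raise :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "phenotypes" not in raw:
        raise ConfigError(f"phenotype file {path} lacks a 'phenotypes' list")
    defs: list[PhenotypeDefinition] = []
    seen: dict[str, frozenset[str]] = {}
    for entry in raw["phenotypes"]:
        pid = str(entry["id"])
        if pid in seen:
            raise ConfigError(f"duplicate disease_id {pid!r} in phenotype file")
        codes = frozenset(str(c) for c in entry.get("codes", []))
        d = PhenotypeDefinition(
            disease_id=pid,
            display_name=str(entry.get("name", pid)),
            code_set=codes,
            uses_nos_rule=bool(entry.get("uses_nos_rule", False)),
        )
        for other_id, other_codes in seen.items():
            shared = codes & other_codes
            if shared:
                logger.warning("phenotypes %s and %s share code(s) %s",
                               pid, other_id, sorted(shared))
        seen[pid] = codes
        defs.append(d)
    return defs


def load_census(path: str | Path, config: StudyConfig | None = None) -> CensusTable:
    """Load the reference census table (``sex,age_group,population``).

    If ``config`` is given, the age-group labels must exactly match the
    labels derived from ``config.age_bins``.
    """
    df = _read_table(path)
    _require_columns(df, ["sex", "age_group", "population"], "census table")
    df = df[["sex", "age_group", "population"]].copy()
    df["sex"] = df["sex"].map(parse_sex)
    df["population"] = pd.to_numeric(df["population"])
    if config is not None:
        expected = set(config.age_group_labels())
        got = set(df["age_group"])
        if got != expected:
            raise ConfigError(
                f"census age groups {sorted(got)} do not match the configured "
                f"bins {sorted(expected)}"
            )
    return CensusTable(df)


def default_census_path() -> Path:
    """Path of the bundled example census (constructed strata, 333.3M total)."""
    return Path(__file__).parent / "data" / "us_census_2022_synthetic_strata.csv"
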