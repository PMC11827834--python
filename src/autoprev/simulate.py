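"""Synthetic OMOP-lite EHR generator.

Emulates the statistical structure the prevalence pipeline assumes so the
whole analysis is testable without access to real patient data:

* a multi-site population with configurable sex and age distributions and a
  death-record rate;
* per-disease true prevalences and female:male prevalence ratios, with
  within-patient co-occurrence induced by a single shared latent factor
  (person i draws u_i ~ N(0,1); disease j is assigned with probability
  ``expit(alpha_j + beta_j * x_sex + load * u_i)``, with the intercept and
  sex effect calibrated jointly by root finding so that the *marginal*
  assignment probability equals ``true_prevalence`` and the female:male
  prevalence ratio equals ``female_male_ratio`` at the configured load);
* diagnosis events: each case receives at least two codes for each assigned
  disease with a total span drawn from the case-span distribution (support
  at or above the numerator window, so cases qualify by construction unless
  the span distribution is deliberately configured below the window);
  non-cases receive a single "provisional diagnosis" code with a configured
  probability (the billing-driven noise the two-code rule filters); and all
  persons receive background diagnosis events at a configured mean rate so
  the denominator rule is satisfied at realistic frequencies.

Seeded runs are bit-reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import (
    ConfigError,
    NOS_DISEASE_ID,
    PhenotypeDefinition,
    STANDARD_VOCABULARY,
    StudyConfig,
    default_census_path,
)

_SEX_X = {"female": 0.5, "male": -0.5, "other": 0.0, "unknown": 0.0}


@dataclass(frozen=True)
class DiseaseSpec:
    """Ground-truth parameters of one simulated disease."""

    disease_id: str
    display_name: str
    codes: tuple[str, ...]
    true_prevalence: float
    female_male_ratio: float
    uses_nos_rule: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.true_prevalence < 1.0):
            raise ConfigError(
                f"{self.disease_id}: true_prevalence must be in (0, 1)"
            )
        if self.female_male_ratio <= 0:
            raise ConfigError(f"{self.disease_id}: female_male_ratio must be > 0")
        if not self.codes:
            raise ConfigError(f"{self.disease_id}: empty code list")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic EHR draw.

    Defaults describe a mid-sized multi-site extract: 50,000 patients across
    six academic sites, a slightly female-skewed adult-heavy population, ten
    autoimmune diseases with prevalences from 0.5% to 8% and female:male
    ratios from 0.5 to 4, plus a small "not otherwise classified" category;
    a shared-factor comorbidity load of 1.0; a 5% per-person provisional
    single-code noise rate; and a mean of 8 background diagnoses per person.
    """

    n_persons: int = 50_000
    sites: tuple[tuple[str, float], ...] = (
        ("site_a", 0.25), ("site_b", 0.20), ("site_c", 0.20),
        ("site_d", 0.15), ("site_e", 0.12), ("site_f", 0.08),
    )
    sex_dist: tuple[tuple[str, float], ...] = (
        ("female", 0.520), ("male", 0.475), ("other", 0.005),
    )
    age_dist: tuple[float, ...] = (0.18, 0.38, 0.26, 0.18)
    max_age: int = 95
    diseases: tuple[DiseaseSpec, ...] = ()
    comorbidity_load: float = 1.0
    provisional_noise_rate: float = 0.05
    background_code_rate: float = 8.0
    n_background_codes: int = 200
    case_extra_code_mean: float = 1.0
    case_span_min: int = 30
    case_span_max: int = 1095
    death_rate: float = 0.01
    study: StudyConfig = field(default_factory=StudyConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("provisional_noise_rate", self.provisional_noise_rate),
            ("death_rate", self.death_rate),
        ):
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be a probability, got {value}")
        for label, dist in (
            ("sites", [w for _, w in self.sites]),
            ("sex_dist", [w for _, w in self.sex_dist]),
            ("age_dist", list(self.age_dist)),
        ):
            if abs(sum(dist) - 1.0) > 1e-9 or any(w < 0 for w in dist):
                raise ConfigError(f"{label} weights must be >= 0 and sum to 1")
        if len(self.age_dist) != len(self.study.age_bins):
            raise ConfigError("age_dist must have one weight per age bin")
        if self.case_span_min < 0 or self.case_span_min > self.case_span_max:
            raise ConfigError("case span support is empty")
        study_days = (self.study.study_end - self.study.study_start).days
        if self.case_span_max > study_days:
            raise ConfigError("case_span_max exceeds the study window length")
        if self.comorbidity_load < 0:
            raise ConfigError("comorbidity_load must be >= 0")

    def specific_diseases(self) -> tuple[DiseaseSpec, ...]:
        return tuple(d for d in self.diseases if d.disease_id != NOS_DISEASE_ID)

    def phenotypes(self) -> list[PhenotypeDefinition]:
        """Phenotype definitions matching the generator's code lists."""
        return [
            PhenotypeDefinition(
                d.disease_id, d.display_name, frozenset(d.codes), d.uses_nos_rule
            )
            for d in self.diseases
        ]


def default_sim_config(seed: int = 0, n_persons: int = 50_000) -> SimConfig:
    """The default study conditions: a 10-disease panel plus NOS.

    Prevalences span 0.5%-8% and female:male ratios 0.5-4; the extreme
    ratios sit on the higher-prevalence diseases, where a ratio is
    estimable with useful precision from a 50,000-person extract.
    """
    prevalences = [0.08, 0.06, 0.05, 0.04, 0.03, 0.02, 0.015, 0.01, 0.008, 0.005]
    ratios = [4.0, 2.0, 3.0, 0.5, 1.7, 1.3, 1.0, 2.0, 0.8, 1.5]
    diseases = [
        DiseaseSpec(
            disease_id=f"d{i + 1:02d}",
            display_name=f"Synthetic autoimmune disease {i + 1}",
            codes=tuple(f"D{i + 1:02d}-{s}" for s in "ABC"),
            true_prevalence=p,
            female_male_ratio=r,
        )
        for i, (p, r) in enumerate(zip(prevalences, ratios))
    ]
    diseases.append(
        DiseaseSpec(
            disease_id=NOS_DISEASE_ID,
            display_name="Autoimmune disease not otherwise classified",
            codes=("NOS-A", "NOS-B"),
            true_prevalence=0.003,
            female_male_ratio=1.5,
            uses_nos_rule=False,
        )
    )
    return SimConfig(n_persons=n_persons, diseases=tuple(diseases), seed=seed)


# ---------------------------------------------------------------------------
# calibration of the latent-factor assignment model

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _sex_rate(alpha: float, beta: float, load: float, x: float) -> float:
    """Disease probability for one sex, integrated over the latent factor."""
    return float(
        np.sum(_GH_WEIGHTS * expit(alpha + beta * x + load * _GH_NODES))
    )


def _marginal(alpha: float, beta: float, load: float,
              sex_weights: Sequence[tuple[str, float]]) -> float:
    return sum(
        w * _sex_rate(alpha, beta, load, _SEX_X[s]) for s, w in sex_weights
    )


def calibrate_disease(
    spec: DiseaseSpec, load: float, sex_weights: Sequence[tuple[str, float]]
) -> tuple[float, float]:
    """Solve for (alpha, beta) hitting the target marginal prevalence and
    female:male prevalence ratio at the given comorbidity load.

    Nested bisection: for each candidate sex effect beta the intercept is
    recalibrated to preserve the marginal, and beta is then solved so the
    implied prevalence ratio matches the target.
    """

    def alpha_for(beta: float) -> float:
        return brentq(
            lambda a: _marginal(a, beta, load, sex_weights) - spec.true_prevalence,
            -40.0, 40.0, xtol=1e-12,
        )

    target = spec.female_male_ratio
    if target == 1.0:
        return alpha_for(0.0), 0.0

    def ratio_gap(beta: float) -> float:
        a = alpha_for(beta)
        pf = _sex_rate(a, beta, load, _SEX_X["female"])
        pm = _sex_rate(a, beta, load, _SEX_X["male"])
        return pf / pm - target

    beta = brentq(ratio_gap, -12.0, 12.0, xtol=1e-10)
    return alpha_for(beta), beta


# ---------------------------------------------------------------------------
# sampling

@dataclass
class SimResult:
    """A complete synthetic dataset plus ground truth (testing only; the
    pipeline never consumes ``truth``)."""

    persons: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame  # person_id, disease_id (assigned, pre-coding)
    config: SimConfig


def sample_population(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the person table: ids, sex, birth year, site, death dates."""
    n = config.n_persons
    if n == 0:
        return pd.DataFrame(
            columns=["person_id", "sex", "birth_year", "death_date", "site_id"]
        )
    person_id = np.array([f"p{i:07d}" for i in range(n)], dtype=object)
    sexes = np.array([s for s, _ in config.sex_dist], dtype=object)
    sex = rng.choice(sexes, size=n, p=[w for _, w in config.sex_dist])
    bins = np.asarray(config.study.age_bins)
    uppers = np.append(bins[1:], config.max_age + 1)
    bin_idx = rng.choice(len(bins), size=n, p=list(config.age_dist))
    age = rng.integers(bins[bin_idx], uppers[bin_idx])
    birth_year = config.study.study_end.year - age
    sites = np.array([s for s, _ in config.sites], dtype=object)
    site = rng.choice(sites, size=n, p=[w for _, w in config.sites])
    study_days = (config.study.study_end - config.study.study_start).days
    dead = rng.random(n) < config.death_rate
    # death cannot precede birth: clamp the draw window for persons born
    # inside the study period
    born = pd.to_datetime(pd.Series(birth_year).astype(str) + "-01-01")
    lo = (born - pd.Timestamp(config.study.study_start)).dt.days.clip(
        lower=0, upper=study_days
    ).to_numpy()
    death_offset = rng.integers(lo, study_days + 1)
    death_date = pd.Series(pd.NaT, index=range(n))
    death_date[dead] = pd.Timestamp(config.study.study_start) + pd.to_timedelta(
        death_offset[dead], unit="D"
    )
    return pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_year": birth_year,
            "death_date": death_date,
            "site_id": site,
        }
    )


def assign_diseases(
    persons: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign diseases via the calibrated latent-factor model.

    Returns a boolean frame (person row x disease_id column).  Higher
    ``comorbidity_load`` concentrates disease in high-factor patients,
    producing positive co-occurrence while the calibration preserves every
    marginal prevalence.
    """
    n = len(persons)
    x = persons["sex"].map(_SEX_X).to_numpy(dtype=float)
    u = rng.standard_normal(n)
    cols = {}
    for spec in config.diseases:
        alpha, beta = calibrate_disease(spec, config.comorbidity_load,
                                        config.sex_dist)
        p = expit(alpha + beta * x + config.comorbidity_load * u)
        cols[spec.disease_id] = rng.random(n) < p
    return pd.DataFrame(cols, index=persons.index)


def emit_events(
    persons: pd.DataFrame,
    assignments: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit the condition-occurrence table for an assigned population.

    True cases get ``2 + Poisson(case_extra_code_mean)`` codes per assigned
    disease, first and last codes separated by a span drawn uniformly from
    ``[case_span_min, case_span_max]``; provisional noise gives a non-case a
    single code of one disease they do not have with probability
    ``provisional_noise_rate``; background codes arrive at a Poisson rate
    per person.  All dates fall inside the study window.
    """
    if persons.empty:
        return pd.DataFrame(
            columns=["person_id", "vocabulary", "code", "event_date", "site_id"]
        )
    start = pd.Timestamp(config.study.study_start)
    study_days = (config.study.study_end - config.study.study_start).days
    pid = persons["person_id"].to_numpy(dtype=object)
    site = persons["site_id"].to_numpy(dtype=object)
    parts: list[pd.DataFrame] = []

    def _frame(person_idx: np.ndarray, codes: np.ndarray, offsets: np.ndarray):
        parts.append(
            pd.DataFrame(
                {
                    "person_id": pid[person_idx],
                    "vocabulary": STANDARD_VOCABULARY,
                    "code": codes,
                    "event_date": start + pd.to_timedelta(offsets, unit="D"),
                    "site_id": site[person_idx],
                }
            )
        )

    for spec in config.diseases:
        case_idx = np.flatnonzero(assignments[spec.disease_id].to_numpy())
        m = len(case_idx)
        if m == 0:
            continue
        span = rng.integers(config.case_span_min, config.case_span_max + 1, m)
        t0 = rng.integers(0, study_days - span + 1)
        extra = rng.poisson(config.case_extra_code_mean, m)
        # first and last anchor the span; extras fall uniformly inside it
        anchors_idx = np.repeat(case_idx, 2)
        anchors_off = np.empty(2 * m, dtype=np.int64)
        anchors_off[0::2] = t0
        anchors_off[1::2] = t0 + span
        rep_idx = np.repeat(case_idx, extra)
        rep_t0 = np.repeat(t0, extra)
        rep_span = np.repeat(span, extra)
        mid_off = rep_t0 + rng.integers(0, rep_span + 1)
        all_idx = np.concatenate([anchors_idx, rep_idx])
        all_off = np.concatenate([anchors_off, mid_off])
        codes = np.asarray(spec.codes, dtype=object)[
            rng.integers(0, len(spec.codes), len(all_idx))
        ]
        _frame(all_idx, codes, all_off)

    if config.diseases and config.provisional_noise_rate > 0:
        noisy = np.flatnonzero(rng.random(len(persons)) < config.provisional_noise_rate)
        dz = rng.integers(0, len(config.diseases), len(noisy))
        # a draw landing on a disease the person already has is discarded:
        # provisional codes are noise among non-cases only
        amat = assignments.to_numpy()
        keep = ~amat[noisy, dz]
        noisy, dz = noisy[keep], dz[keep]
        if len(noisy):
            code_lists = [np.asarray(d.codes, dtype=object) for d in config.diseases]
            codes = np.array(
                [code_lists[j][rng.integers(0, len(code_lists[j]))] for j in dz],
                dtype=object,
            )
            offs = rng.integers(0, study_days + 1, len(noisy))
            _frame(noisy, codes, offs)

    if config.background_code_rate > 0 and len(persons):
        counts = rng.poisson(config.background_code_rate, len(persons))
        bg_idx = np.repeat(np.arange(len(persons)), counts)
        if len(bg_idx):
            offs = rng.integers(0, study_days + 1, len(bg_idx))
            codes = np.array(
                [f"BG{c:03d}" for c in rng.integers(0, config.n_background_codes,
                                                    len(bg_idx))],
                dtype=object,
            )
            _frame(bg_idx, codes, offs)

    if not parts:
        return pd.DataFrame(
            columns=["person_id", "vocabulary", "code", "event_date", "site_id"]
        )
    events = pd.concat(parts, ignore_index=True)
    return events.sort_values(
        ["person_id", "event_date", "code"], kind="mergesort"
    ).reset_index(drop=True)


def generate(config: SimConfig) -> SimResult:
    """Run the full generator: population, disease assignment, events."""
    rng = np.random.default_rng(config.seed)
    persons = sample_population(config, rng)
    if persons.empty:
        assignments = pd.DataFrame(
            columns=[d.disease_id for d in config.diseases]
        )
        events = emit_events(persons, assignments, config, rng)
        truth = pd.DataFrame(columns=["person_id", "disease_id"])
        return SimResult(persons, events, truth, config)
    assignments = assign_diseases(persons, config, rng)
    events = emit_events(persons, assignments, config, rng)
    melted = assignments.copy()
    melted["person_id"] = persons["person_id"].values
    truth = (
        melted.melt(id_vars="person_id", var_name="disease_id", value_name="has")
        .query("has")
        .drop(columns="has")
        .sort_values(["person_id", "disease_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SimResult(persons, events, truth, config)


def write_dataset(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the OMOP-lite CSV dialect plus phenotype file and ground truth."""
    from .data_model import write_omop_lite  # avoid import cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "person": out / "person.csv",
        "conditions": out / "condition_occurrence.csv",
        "phenotypes": out / "phenotypes.yaml",
        "census": out / "census.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    write_omop_lite(result.persons, result.events, paths["person"],
                    paths["conditions"])
    pheno = {
        "phenotypes": [
            {
                "id": d.disease_id,
                "name": d.display_name,
                "codes": list(d.codes),
                "uses_nos_rule": d.uses_nos_rule,
            }
            for d in result.config.diseases
        ]
    }
    paths["phenotypes"].write_text(yaml.safe_dump(pheno, sort_keys=False))
    paths["census"].write_bytes(default_census_path().read_bytes())
    result.truth.to_csv(paths["ground_truth"], index=False)
    return paths
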