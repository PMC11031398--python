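"""Reproducible synthetic brain-bank cohorts with planted structure.

Restricted donor records cannot ship with the package, so every downstream
stage is exercised on synthetic cohorts that emulate the three input
families of a brain-bank trajectory study:

* per-donor metadata — neuropathological diagnosis (ND), clinical-diagnosis
  (CD) class list with a controllable misdiagnosis rate, sex, age at death,
  autopsy year, APOE genotype;
* per-donor sign/symptom trajectories — each disease profile assigns its
  attributes an onset-age distribution (normal, in years), a per-year
  observation probability while symptomatic, and an optional bounded
  symptomatic window (``duration_years``). Bounded windows let two disease
  profiles share attributes and lifetime observation counts while differing
  only in onset age — the temporal signal that the age-binned featurization
  is designed to pick up;
* template-rendered clinical-history sentences whose gold multilabel
  vectors are known by construction, for end-to-end classifier testing.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``CohortConfig.seed``; the same config and seed reproduce the cohort
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "AttributeProfile",
    "DiseaseProfile",
    "CohortConfig",
    "SyntheticDonor",
    "uniform_profile",
    "generate_cohort",
    "cohort_metadata",
    "cohort_observations",
    "inject_misdiagnoses",
    "default_template_bank",
    "DEFAULT_DISTRACTORS",
    "render_sentences",
    "coarsen_age",
]


class ConfigurationError(ValueError):
    """A cohort or template configuration violates its contract."""


@dataclass(frozen=True)
class AttributeProfile:
    """How one attribute manifests within one disease profile."""

    onset_mean: float
    onset_sd: float
    obs_prob: float
    duration_years: float | None = None  # None: symptomatic until death

    def __post_init__(self) -> None:
        if not (0.0 <= self.obs_prob <= 1.0):
            raise ConfigurationError(
                f"observation probability {self.obs_prob} outside [0, 1]"
            )
        if self.onset_sd < 0:
            raise ConfigurationError("onset_sd must be non-negative")


@dataclass(frozen=True)
class DiseaseProfile:
    nd_code: str
    prevalence: float
    attributes: Mapping[str, AttributeProfile]
    persistence: bool = True
    death_age_mean: float | None = None  # overrides the cohort default
    death_age_sd: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ConfigurationError(f"prevalence {self.prevalence} outside [0, 1]")


def uniform_profile(
    nd_code: str,
    prevalence: float,
    attribute_ids: Iterable[str],
    onset_mean: float,
    onset_sd: float = 3.0,
    obs_prob: float = 0.5,
    duration_years: float | None = None,
    **kwargs,
) -> DiseaseProfile:
    """Disease profile giving every listed attribute the same parameters."""
    profile = AttributeProfile(onset_mean, onset_sd, obs_prob, duration_years)
    return DiseaseProfile(
        nd_code=nd_code,
        prevalence=prevalence,
        attributes={a: profile for a in attribute_ids},
        **kwargs,
    )


@dataclass(frozen=True)
class CohortConfig:
    n_donors: int
    diseases: Sequence[DiseaseProfile]
    misdiagnosis_rate: float = 0.0
    umbrella_cd_rate: float = 0.0
    umbrella_class: str = "dementia"
    confusion_map: Mapping[str, frozenset[str] | set[str]] = field(
        default_factory=dict
    )
    sex_ratio: float = 0.5  # fraction female
    apoe44_prob_by_disease: Mapping[str, float] = field(default_factory=dict)
    apoe44_baseline: float = 0.02
    death_age_mean: float = 80.0
    death_age_sd: float = 8.0
    autopsy_year_range: tuple[int, int] = (1997, 2020)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ConfigurationError("n_donors must be positive")
        total = sum(d.prevalence for d in self.diseases)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"disease prevalences sum to {total}, not 1")
        for probability in (
            self.misdiagnosis_rate,
            self.umbrella_cd_rate,
            self.sex_ratio,
            self.apoe44_baseline,
            *self.apoe44_prob_by_disease.values(),
        ):
            if not (0.0 <= probability <= 1.0):
                raise ConfigurationError(f"probability {probability} outside [0, 1]")


@dataclass
class SyntheticDonor:
    donor_id: str
    nd_codes: tuple[str, ...]
    cd_classes: frozenset[str]
    true_cd_classes: frozenset[str]
    misdiagnosed: bool
    sex: str  # "F" or "M"
    death_age: int
    autopsy_year: int
    apoe_genotype: str
    # (attribute_id, age, calendar year) per observed symptomatic year
    observations: list[tuple[str, int, int]]

    @property
    def death_year(self) -> int:
        return self.autopsy_year

    @property
    def birth_year(self) -> int:
        return self.autopsy_year - self.death_age

    def to_record(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "nd_codes": ";".join(self.nd_codes),
            "cd_classes": ";".join(sorted(self.cd_classes)),
            "sex": self.sex,
            "death_age": self.death_age,
            "autopsy_year": self.autopsy_year,
            "apoe_genotype": self.apoe_genotype,
            "misdiagnosed": self.misdiagnosed,
        }


def coarsen_age(age: float, width: int = 5, cap: int = 95, floor: int = 35) -> int:
    """Coarsen an exact age to the released-data dialect: 5-year bins with a
    95+ top category and a 35-year bottom category."""
    binned = int(width * round(age / width))
    return max(floor, min(cap, binned))


def generate_cohort(config: CohortConfig) -> list[SyntheticDonor]:
    """Draw a reproducible synthetic cohort from the configured conditions.

    Each donor receives a diagnosis by prevalence, demographic covariates,
    an APOE genotype, a CD list (perturbed by ``misdiagnosis_rate`` through
    ``confusion_map``), and a trajectory: for every attribute in the disease
    profile an onset age is drawn from its (truncated) normal distribution
    and each subsequent integer age inside the symptomatic window is
    observed independently with the attribute's per-year probability.
    """
    rng = np.random.default_rng(config.seed)
    prevalences = np.array([d.prevalence for d in config.diseases])
    donors: list[SyntheticDonor] = []
    for i in range(config.n_donors):
        disease = config.diseases[int(rng.choice(len(config.diseases), p=prevalences))]
        sex = "F" if rng.random() < config.sex_ratio else "M"
        mean = (
            disease.death_age_mean
            if disease.death_age_mean is not None
            else config.death_age_mean
        )
        sd = (
            disease.death_age_sd
            if disease.death_age_sd is not None
            else config.death_age_sd
        )
        death_age = int(np.clip(round(rng.normal(mean, sd)), 40, 105))
        lo, hi = config.autopsy_year_range
        autopsy_year = int(rng.integers(lo, hi + 1))
        p44 = config.apoe44_prob_by_disease.get(
            disease.nd_code, config.apoe44_baseline
        )
        if rng.random() < p44:
            apoe = "4/4"
        else:
            apoe = "3/4" if rng.random() < 0.3 else "3/3"

        birth_year = autopsy_year - death_age
        observations: list[tuple[str, int, int]] = []
        for attr_id in sorted(disease.attributes):
            profile = disease.attributes[attr_id]
            if profile.obs_prob == 0.0:
                continue
            onset = rng.normal(profile.onset_mean, profile.onset_sd)
            onset = max(1.0, onset)
            if onset > death_age:
                continue
            if profile.duration_years is None:
                window_end = float(death_age)
            else:
                window_end = min(float(death_age), onset + profile.duration_years)
            ages = np.arange(int(math.ceil(onset)), int(math.floor(window_end)) + 1)
            if ages.size == 0:
                continue
            hits = rng.random(ages.size) < profile.obs_prob
            for age in ages[hits]:
                observations.append((attr_id, int(age), birth_year + int(age)))

        true_cd: set[str] = {disease.nd_code}
        cd = set(true_cd)
        misdiagnosed = False
        if rng.random() < config.misdiagnosis_rate:
            confusers = config.confusion_map.get(disease.nd_code)
            if confusers:
                cd = set(confusers)
                misdiagnosed = True
        if rng.random() < config.umbrella_cd_rate:
            cd.add(config.umbrella_class)

        donors.append(
            SyntheticDonor(
                donor_id=f"D{i:05d}",
                nd_codes=(disease.nd_code,),
                cd_classes=frozenset(cd),
                true_cd_classes=frozenset(true_cd),
                misdiagnosed=misdiagnosed,
                sex=sex,
                death_age=death_age,
                autopsy_year=autopsy_year,
                apoe_genotype=apoe,
                observations=sorted(observations),
            )
        )
    return donors


def cohort_metadata(cohort: Sequence[SyntheticDonor]) -> pd.DataFrame:
    """Per-donor metadata table in the public TSV dialect."""
    return pd.DataFrame([d.to_record() for d in cohort])


def cohort_observations(cohort: Sequence[SyntheticDonor]) -> pd.DataFrame:
    """Long observation table (donor_id, attribute, age, year)."""
    rows = [
        {"donor_id": d.donor_id, "attribute": a, "age": age, "year": year}
        for d in cohort
        for (a, age, year) in d.observations
    ]
    return pd.DataFrame(rows, columns=["donor_id", "attribute", "age", "year"])


def inject_misdiagnoses(
    cohort: Sequence[SyntheticDonor],
    confusion_map: Mapping[str, Iterable[str]],
    rate: float,
    seed: int,
) -> list[SyntheticDonor]:
    """Replace a random ``rate`` fraction of CD lists with confuser classes.

    Donors whose ND has no entry in ``confusion_map`` are never perturbed.
    The original CD list is retained in ``true_cd_classes``.
    """
    if not (0.0 <= rate <= 1.0):
        raise ConfigurationError(f"rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[SyntheticDonor] = []
    for donor in cohort:
        perturb = rng.random() < rate
        confusers = confusion_map.get(donor.nd_codes[0])
        if perturb and confusers:
            out.append(
                replace(
                    donor,
                    cd_classes=frozenset(confusers),
                    true_cd_classes=donor.true_cd_classes,
                    misdiagnosed=True,
                )
            )
        else:
            out.append(replace(donor))
    return out


DEFAULT_DISTRACTORS = [
    "visited his sister over the weekend",
    "moved to a new apartment",
    "enjoyed gardening in the spring",
    "went on a holiday to the coast",
    "celebrated a birthday with the family",
    "the general practitioner reviewed the medication list",
]


def default_template_bank(attribute_ids: Iterable[str]) -> dict[str, list[str]]:
    """Two surface forms per attribute, derived from the attribute id."""
    bank: dict[str, list[str]] = {}
    for attr_id in attribute_ids:
        phrase = attr_id.replace("_", " ")
        bank[attr_id] = [
            f"showed clear signs of {phrase}",
            f"{phrase} was reported by the family",
        ]
    return bank


def render_sentences(
    cohort: Sequence[SyntheticDonor],
    template_bank: Mapping[str, Sequence[str]] | None = None,
    distractor_rate: float = 0.1,
    conjunction_rate: float = 0.1,
    distractors: Sequence[str] = DEFAULT_DISTRACTORS,
    seed: int = 0,
) -> pd.DataFrame:
    """Render every trajectory observation as a labeled sentence.

    Returns the labeled-sentence table dialect: ``donor_id``, ``sentence``,
    ``year`` and one 0/1 gold-label column per attribute. With probability
    ``conjunction_rate`` two same-year observations share one sentence (a
    two-hot label vector); distractor sentences carry the all-zero vector.
    """
    attribute_ids = sorted({a for d in cohort for (a, _, _) in d.observations})
    if template_bank is None:
        template_bank = default_template_bank(attribute_ids)
    for attr_id in attribute_ids:
        forms = template_bank.get(attr_id)
        if not forms:
            raise ConfigurationError(f"attribute {attr_id!r} has no template")
    all_attrs = sorted(template_bank)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def emit(donor_id: str, year: int, labels: Iterable[str], text: str) -> None:
        row = {"donor_id": donor_id, "sentence": text, "year": year}
        row.update({a: 0 for a in all_attrs})
        for label in labels:
            row[label] = 1
        rows.append(row)

    for donor in cohort:
        by_year: dict[int, list[str]] = {}
        for attr_id, _age, year in donor.observations:
            by_year.setdefault(year, []).append(attr_id)
        for year in sorted(by_year):
            attrs = by_year[year]
            idx = 0
            while idx < len(attrs):
                first = attrs[idx]
                form = template_bank[first][int(rng.integers(len(template_bank[first])))]
                if idx + 1 < len(attrs) and rng.random() < conjunction_rate:
                    second = attrs[idx + 1]
                    form2 = template_bank[second][
                        int(rng.integers(len(template_bank[second])))
                    ]
                    emit(
                        donor.donor_id,
                        year,
                        [first, second],
                        f"In {year} the patient {form} and {form2}.",
                    )
                    idx += 2
                else:
                    emit(
                        donor.donor_id,
                        year,
                        [first],
                        f"In {year} the patient {form}.",
                    )
                    idx += 1
            if rng.random() < distractor_rate:
                filler = distractors[int(rng.integers(len(distractors)))]
                emit(donor.donor_id, year, [], f"In {year} the patient {filler}.")
    columns = ["donor_id", "sentence", "year", *all_attrs]
    return pd.DataFrame(rows, columns=columns)
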