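"""Shared fixtures: hand-writable mini-ontologies and synthetic cohorts."""

from __future__ import annotations

import pandas as pd
import pytest

from neurotraj.ontology import (
    AccuracyDictionary,
    AttributeDef,
    DiagnosisDef,
    build_accuracy_dictionary,
)
from neurotraj.synthetic_data import (
    AttributeProfile,
    CohortConfig,
    DiseaseProfile,
    generate_cohort,
    uniform_profile,
)
from neurotraj.trajectory_builder import Trajectory

FRAME_COLUMNS = ["year", "age", "attribute", "present", "imputed"]


def make_trajectory(
    donor_id: str,
    observations: list[tuple[str, int]],  # (attribute, year)
    death_year: int | None = None,
    age_at_death: float | None = None,
) -> Trajectory:
    rows = []
    for attribute, year in observations:
        age = (
            year - (death_year - age_at_death)
            if death_year is not None and age_at_death is not None
            else float("nan")
        )
        rows.append(
            {
                "year": year,
                "age": float(age),
                "attribute": attribute,
                "present": 1,
                "imputed": False,
            }
        )
    frame = (
        pd.DataFrame(rows, columns=FRAME_COLUMNS)
        if rows
        else pd.DataFrame(columns=FRAME_COLUMNS)
    )
    return Trajectory(
        donor_id=donor_id,
        frame=frame,
        death_year=death_year,
        age_at_death=age_at_death,
    )


@pytest.fixture
def mini_attributes() -> list[AttributeDef]:
    """Eight attributes in two domains — the hand-writable mini-ontology."""
    groups = {
        "psychiatric": ("disturbances in mood and behavior", ["apathy", "depressed_mood", "psychosis", "mania"]),
        "motor": ("extrapyramidal symptoms", ["tremor", "bradykinesia", "rigidity", "ataxia"]),
    }
    out = []
    for domain, (grouping, names) in groups.items():
        for name in names:
            out.append(
                AttributeDef(
                    attribute_id=name,
                    name=name.replace("_", " "),
                    domain=domain,
                    grouping=grouping,
                    diagnostic_importance=frozenset({"PD"})
                    if domain == "motor"
                    else frozenset(),
                    is_neurodegeneration_associated=domain == "motor",
                )
            )
    return out


@pytest.fixture
def full_attributes() -> list[AttributeDef]:
    """A 90-attribute fixture spanning the five domains and 14 groupings."""
    domains = ["psychiatric", "cognitive", "motor", "sensory/autonomic", "general"]
    groupings = [f"grouping_{i}" for i in range(14)]
    out = []
    for i in range(90):
        out.append(
            AttributeDef(
                attribute_id=f"attr{i:02d}",
                name=f"attribute {i}",
                domain=domains[i % 5],
                grouping=groupings[i % 14],
                is_neurodegeneration_associated=(i % 3 == 0),
            )
        )
    return out


@pytest.fixture
def nd_defs() -> list[DiagnosisDef]:
    return [
        DiagnosisDef("AD", "Alzheimer's disease", "progressive neurodegenerative", "G30"),
        DiagnosisDef("PD", "Parkinson's disease", "progressive neurodegenerative", "G20"),
        DiagnosisDef("PDD", "Parkinson's disease with dementia", "progressive neurodegenerative", "G20"),
        DiagnosisDef("MSA", "Multiple system atrophy", "progressive neurodegenerative", "G23.2"),
        DiagnosisDef("FTD", "Frontotemporal dementia", "progressive neurodegenerative", "G31.0"),
        DiagnosisDef("VD", "Vascular dementia", "vascular", "F01"),
        DiagnosisDef("MS", "Multiple sclerosis", "neuroinflammatory", "G35"),
        DiagnosisDef("MDD", "Major depressive disorder", "psychiatric", "F32"),
        DiagnosisDef("CON", "Control donor", "control"),
    ]


# A small disease-class hierarchy: disease-specific classes under umbrella
# terms, mirroring a trimmed human-disease-ontology neighborhood.
CD_HIERARCHY = {
    "AD": ["dementia"],
    "FTD": ["dementia"],
    "VD": ["dementia"],
    "PD": ["movement disorder"],
    "PDD": ["dementia", "movement disorder"],
    "MSA": ["movement disorder"],
    "dementia": ["brain disease"],
    "movement disorder": ["brain disease"],
    "MS": ["brain disease"],
}


@pytest.fixture
def accuracy_dictionary() -> AccuracyDictionary:
    nd_codes = ["AD", "PD", "PDD", "MSA", "FTD", "VD", "MS", "AD-DLB"]
    nd_to_classes = {
        "AD": {"AD"},
        "PD": {"PD", "PDD"},  # combined PD/PDD handling
        "PDD": {"PD", "PDD"},
        "MSA": {"MSA"},
        "FTD": {"FTD"},
        "VD": {"VD"},
        "MS": {"MS"},
        "AD-DLB": {"AD", "DLB"},
    }
    return build_accuracy_dictionary(
        nd_codes,
        CD_HIERARCHY,
        nd_to_classes,
        umbrella_classes={"dementia", "movement disorder"},
    )


@pytest.fixture
def disjoint_cohort():
    """Two diseases with disjoint attribute sets — the workhorse cohort."""
    ad = uniform_profile(
        "AD", 0.5, ["dementia", "memory_impairment", "apathy"], onset_mean=70,
        obs_prob=0.5,
    )
    pd_profile = uniform_profile(
        "PD", 0.5, ["tremor", "bradykinesia", "rigidity"], onset_mean=60,
        obs_prob=0.5,
    )
    config = CohortConfig(n_donors=200, diseases=[ad, pd_profile], seed=1)
    return generate_cohort(config), config


@pytest.fixture(scope="session")
def program_cohort():
    """600 donors over six latent symptom programs; programs P5/P6 share
    their attributes and lifetime observation rates but differ in onset age
    (emulating early- vs late-onset dementia), so only the temporal modality
    can separate them."""
    from neurotraj.synthetic_data import cohort_observations
    from neurotraj.trajectory_builder import trajectories_from_observations

    distinct = {i: [f"a{i}_{j}" for j in range(4)] for i in range(1, 5)}
    shared = [f"s_{j}" for j in range(4)]
    profiles = [
        uniform_profile("P1", 1 / 6, distinct[1], onset_mean=65, obs_prob=0.6,
                        duration_years=8),
        uniform_profile("P2", 1 / 6, distinct[2], onset_mean=65, obs_prob=0.6,
                        duration_years=8),
        uniform_profile("P3", 1 / 6, distinct[3], onset_mean=65, obs_prob=0.6,
                        duration_years=8),
        uniform_profile("P4", 1 / 6, distinct[4], onset_mean=65, obs_prob=0.6,
                        duration_years=8),
        uniform_profile("P5", 1 / 6, shared, onset_mean=45, onset_sd=3,
                        obs_prob=0.6, duration_years=8,
                        death_age_mean=85, death_age_sd=4),
        uniform_profile("P6", 1 / 6, shared, onset_mean=72, onset_sd=3,
                        obs_prob=0.6, duration_years=8,
                        death_age_mean=85, death_age_sd=4),
    ]
    config = CohortConfig(n_donors=600, diseases=profiles, seed=7)
    cohort = generate_cohort(config)
    trajectories = trajectories_from_observations(cohort_observations(cohort))
    truth = pd.Series({d.donor_id: d.nd_codes[0] for d in cohort})
    return cohort, trajectories, truth


@pytest.fixture
def null_cohort_config():
    """Two groups with identical symptom profiles — no real enrichment."""

    def build(seed: int) -> CohortConfig:
        shared = [f"x{i}" for i in range(8)]
        return CohortConfig(
            n_donors=60,
            diseases=[
                uniform_profile("A", 0.5, shared, onset_mean=65, obs_prob=0.3,
                                duration_years=10),
                uniform_profile("B", 0.5, shared, onset_mean=65, obs_prob=0.3,
                                duration_years=10),
            ],
            seed=seed,
        )

    return build
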