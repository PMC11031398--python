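"""From sentence-level predictions to per-donor disease trajectories.

A clinical disease trajectory is a binary year x attribute presence matrix
per donor: multiple sentences flagging the same attribute in the same year
collapse to a single presence. Observations whose year could not be
resolved are kept in a side table — they count toward general exploration
but are excluded from temporal profiling, modeling and dimensionality
reduction.

Two cohort-level rules follow:

* persistence imputation — a neurodegeneration-associated attribute, once
  observed in a donor with a progressive neurodegenerative disease, is
  assumed to remain present in every year up to death (new rows are marked
  ``imputed``); the rule is gated on both ontology flags and is idempotent;
* cohort selection — donors enter downstream analyses only if the autopsy
  was performed in or after 1997, the source summary had more than 500
  characters, and (for non-control donors) the trajectory holds at least
  five observations. Imputed rows do not count toward the observation
  minimum by default (``count_imputed`` switches this). Analysis-specific
  diagnosis allow-lists select single-ND donors (plus AD-DLB) for modeling,
  and additionally psychiatric and mixed-dementia codes for clustering.

Ages derive from the year of death and the age at death:
``age = year - (death_year - age_at_death)``. When only 5-year-coarsened
public ages are available the bin midpoint is used and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .corpus_parser import YEAR_UNKNOWN

__all__ = [
    "Trajectory",
    "DEFAULT_ALLOWED_ND",
    "collapse_predictions",
    "impute_persistence",
    "filter_cohort",
    "trajectories_from_observations",
    "trajectory_table",
]

_FRAME_COLUMNS = ["year", "age", "attribute", "present", "imputed"]

# Diagnosis allow-lists per analysis purpose. Modeling and the clinical
# accuracy analysis use single-ND donors of the common disorders plus the
# AD-DLB combination; clustering additionally admits psychiatric diagnoses
# and mixed/rare dementias. "trajectories" applies no diagnosis filter.
_MODELING_ND = {
    "CON", "AD", "PD", "PDD", "VD", "FTD", "DLB", "ATAXIA", "MND", "PSP",
    "MS", "MSA", "AD-DLB",
}
_CLUSTERING_ND = _MODELING_ND | {
    "MDD", "BP", "SCZ", "PTSD", "ASD", "OCD",
    "CBD", "AD-CA", "AD-VE", "PD-AD", "DLB-SICC", "DEM-SICC",
    "DEM-SICC-AGD", "DEM-VE",
}
DEFAULT_ALLOWED_ND: dict[str, frozenset[str] | None] = {
    "trajectories": None,
    "modeling": frozenset(_MODELING_ND),
    "clustering": frozenset(_CLUSTERING_ND),
}


@dataclass
class Trajectory:
    """Binary year x attribute presence rows for one donor."""

    donor_id: str
    frame: pd.DataFrame  # columns: year, age, attribute, present, imputed
    unknown_year: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["attribute", "present"])
    )
    death_year: int | None = None
    age_at_death: float | None = None
    age_is_coarsened: bool = False

    def n_observations(self, count_imputed: bool = False) -> int:
        frame = self.frame
        if not count_imputed:
            frame = frame[~frame["imputed"]]
        return int(frame["present"].sum())

    def observed_attributes(self) -> set[str]:
        return set(self.frame.loc[self.frame["present"] == 1, "attribute"])


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=_FRAME_COLUMNS).astype(
        {"year": int, "age": float, "attribute": str, "present": int, "imputed": bool}
    )


def collapse_predictions(
    sentence_predictions: pd.DataFrame,
    donor_meta: Mapping[str, tuple[int | None, float | None]] | None = None,
    age_is_coarsened: bool = False,
) -> dict[str, Trajectory]:
    """Collapse per-sentence attribute predictions into donor trajectories.

    ``sentence_predictions`` is the wide dialect: ``donor_id``, ``year``
    (a calendar year or :data:`~neurotraj.corpus_parser.YEAR_UNKNOWN`) and
    one 0/1 column per attribute. ``donor_meta`` maps donor id to
    ``(death_year, age_at_death)`` for age derivation.
    """
    attr_cols = [
        c for c in sentence_predictions.columns if c not in ("donor_id", "year")
    ]
    out: dict[str, Trajectory] = {}
    for donor_id, group in sentence_predictions.groupby("donor_id", sort=True):
        death_year, age_at_death = (None, None)
        if donor_meta is not None and donor_id in donor_meta:
            death_year, age_at_death = donor_meta[donor_id]
        known = group[group["year"] != YEAR_UNKNOWN]
        unknown = group[group["year"] == YEAR_UNKNOWN]

        rows: list[dict] = []
        if len(known):
            melted = known.melt(
                id_vars=["year"],
                value_vars=attr_cols,
                var_name="attribute",
                value_name="present",
            )
            melted = melted[melted["present"] == 1]
            collapsed = (
                melted.groupby(["year", "attribute"], as_index=False)
                .first()
                .sort_values(["year", "attribute"])
            )
            for r in collapsed.itertuples(index=False):
                year = int(r.year)
                age = (
                    year - (death_year - age_at_death)
                    if death_year is not None and age_at_death is not None
                    else float("nan")
                )
                rows.append(
                    {
                        "year": year,
                        "age": float(age),
                        "attribute": r.attribute,
                        "present": 1,
                        "imputed": False,
                    }
                )
        unknown_rows: list[dict] = []
        if len(unknown):
            sums = unknown[attr_cols].sum(axis=0)
            for attribute, total in sums.items():
                if total > 0:
                    unknown_rows.append({"attribute": attribute, "present": 1})
        out[str(donor_id)] = Trajectory(
            donor_id=str(donor_id),
            frame=pd.DataFrame(rows, columns=_FRAME_COLUMNS)
            if rows
            else _empty_frame(),
            unknown_year=pd.DataFrame(
                unknown_rows, columns=["attribute", "present"]
            ),
            death_year=death_year,
            age_at_death=age_at_death,
            age_is_coarsened=age_is_coarsened,
        )
    return out


def impute_persistence(
    trajectory: Trajectory,
    neurodegeneration_attributes: set[str] | frozenset[str],
    donor_is_progressive: bool,
) -> Trajectory:
    """Carry qualifying attributes forward from first observation to death.

    Applies only when the donor has a progressive neurodegenerative disease
    and only to neurodegeneration-associated attributes. Idempotent: rows
    already present (observed or imputed) are left untouched.
    """
    if not donor_is_progressive:
        return replace(trajectory)
    if trajectory.death_year is None:
        warnings.warn(
            f"donor {trajectory.donor_id}: death year missing, imputation skipped",
            stacklevel=2,
        )
        return replace(trajectory)
    frame = trajectory.frame
    new_rows: list[dict] = []
    offset = (
        trajectory.death_year - trajectory.age_at_death
        if trajectory.age_at_death is not None
        else None
    )
    for attribute in sorted(set(frame["attribute"]) & set(neurodegeneration_attributes)):
        observed = frame[(frame["attribute"] == attribute) & (frame["present"] == 1)]
        if observed.empty:
            continue
        first_year = int(observed["year"].min())
        have = set(observed["year"].astype(int))
        for year in range(first_year, trajectory.death_year + 1):
            if year in have:
                continue
            age = year - offset if offset is not None else float("nan")
            new_rows.append(
                {
                    "year": year,
                    "age": float(age),
                    "attribute": attribute,
                    "present": 1,
                    "imputed": True,
                }
            )
    if not new_rows:
        return replace(trajectory)
    merged = (
        pd.concat([frame, pd.DataFrame(new_rows, columns=_FRAME_COLUMNS)])
        .sort_values(["attribute", "year"])
        .reset_index(drop=True)
    )
    return replace(trajectory, frame=merged)


def filter_cohort(
    metadata: pd.DataFrame,
    trajectories: Mapping[str, Trajectory],
    purpose: str = "trajectories",
    min_observations: int = 5,
    min_autopsy_year: int = 1997,
    min_characters: int = 500,
    count_imputed: bool = False,
    allowed_nd: frozenset[str] | set[str] | None = None,
    control_codes: frozenset[str] = frozenset({"CON"}),
) -> tuple[list[str], pd.DataFrame]:
    """Apply the cohort-selection filters for one analysis purpose.

    ``metadata`` needs columns ``donor_id``, ``nd_codes`` (semicolon-joined)
    and ``autopsy_year``; an ``n_characters`` column activates the summary-
    length filter. Returns the selected donor ids plus an exclusion log with
    one reason code per excluded donor (first failing rule wins, in the
    order: characters, autopsy year, diagnosis allow-list, observation
    minimum). Control donors are exempt from the observation minimum.
    """
    if purpose not in DEFAULT_ALLOWED_ND:
        raise ValueError(f"unknown purpose {purpose!r}")
    if allowed_nd is None:
        allowed_nd = DEFAULT_ALLOWED_ND[purpose]

    selected: list[str] = []
    log: list[dict] = []
    for row in metadata.itertuples(index=False):
        donor_id = str(row.donor_id)
        codes = tuple(sorted(str(row.nd_codes).split(";")))
        label = "-".join(codes) if len(codes) > 1 else codes[0]

        def exclude(reason: str) -> None:
            log.append({"donor_id": donor_id, "reason": reason})

        n_chars = getattr(row, "n_characters", None)
        if n_chars is not None and not pd.isna(n_chars) and n_chars <= min_characters:
            exclude("too_few_characters")
            continue
        if int(row.autopsy_year) < min_autopsy_year:
            exclude("autopsy_before_1997")
            continue
        if allowed_nd is not None and label not in allowed_nd:
            exclude("diagnosis_not_allowed")
            continue
        is_control = set(codes) <= control_codes
        if not is_control:
            trajectory = trajectories.get(donor_id)
            n_obs = (
                trajectory.n_observations(count_imputed=count_imputed)
                if trajectory is not None
                else 0
            )
            if n_obs < min_observations:
                exclude("too_few_observations")
                continue
        selected.append(donor_id)
    return selected, pd.DataFrame(log, columns=["donor_id", "reason"])


def trajectories_from_observations(
    observations: pd.DataFrame,
    donor_meta: Mapping[str, tuple[int | None, float | None]] | None = None,
) -> dict[str, Trajectory]:
    """Build trajectories straight from a long (donor_id, attribute, year[,
    age]) observation table, bypassing the sentence stage.

    Useful when observations come from the synthetic generator or from a
    deposited trajectory table rather than from classifier predictions.
    Duplicate (donor, year, attribute) rows collapse to one presence.
    """
    out: dict[str, Trajectory] = {}
    for donor_id, group in observations.groupby("donor_id", sort=True):
        death_year, age_at_death = (None, None)
        if donor_meta is not None and donor_id in donor_meta:
            death_year, age_at_death = donor_meta[donor_id]
        rows = []
        seen: set[tuple[int, str]] = set()
        for r in group.sort_values(["attribute", "year"]).itertuples(index=False):
            year = int(r.year)
            key = (year, str(r.attribute))
            if key in seen:
                continue
            seen.add(key)
            if hasattr(r, "age") and not pd.isna(r.age):
                age = float(r.age)
            elif death_year is not None and age_at_death is not None:
                age = float(year - (death_year - age_at_death))
            else:
                age = float("nan")
            rows.append(
                {
                    "year": year,
                    "age": age,
                    "attribute": str(r.attribute),
                    "present": 1,
                    "imputed": False,
                }
            )
        out[str(donor_id)] = Trajectory(
            donor_id=str(donor_id),
            frame=pd.DataFrame(rows, columns=_FRAME_COLUMNS)
            if rows
            else _empty_frame(),
            death_year=death_year,
            age_at_death=age_at_death,
        )
    return out


def trajectory_table(trajectories: Mapping[str, Trajectory]) -> pd.DataFrame:
    """Long export table (donor_id, year, age, attribute, present, imputed)."""
    frames = []
    for donor_id in sorted(trajectories):
        if trajectories[donor_id].frame.empty:
            continue
        frame = trajectories[donor_id].frame.copy()
        frame.insert(0, "donor_id", donor_id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["donor_id", *_FRAME_COLUMNS])
    return pd.concat(frames, ignore_index=True)
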