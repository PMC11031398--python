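"""Clinical-vs-neuropathological diagnostic concordance and prediction.

The postmortem neuropathological diagnosis (ND) is treated as ground
truth. Each donor's lifetime clinical diagnoses (CDs, mapped to
disease-ontology classes) — or a model's predicted diagnosis — receive one
of three verdicts:

* **accurate** — a CD matches the ND's accurate class set and no CD is
  disease-specific for a different covered disorder;
* **ambiguous** — only umbrella matches (e.g. a bare "dementia" for an AD
  donor), or an accurate CD alongside a conflicting disease-specific CD
  (e.g. both AD and FTD recorded for an AD donor), or — for model
  predictions — a partial match to a combined ND (AD predicted for an
  AD-DLB donor);
* **inaccurate** — everything else.

Verdicts partition the cohort. Concordance is summarized as an ND x CD
confusion matrix (row-normalized by total ND observations), per-disorder
Jaccard indices between ND and CD donor sets, and directional percentages.

The prediction harness mirrors the trajectory-based diagnosis experiment:
diagnosis-stratified 5-fold assignment, a multinomial logistic baseline on
aggregated trajectory features (per-attribute observation-year counts and
first-observation ages, sex, age at death), each donor's diagnosis
predicted exactly once by a model that never saw it, then verdict counting
against the ND.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .ontology import AccuracyDictionary
from .trajectory_builder import Trajectory

__all__ = [
    "AccuracyVerdict",
    "ConcordanceSummary",
    "PredictionResult",
    "nd_label",
    "assign_cd_verdict",
    "assign_model_verdict",
    "jaccard",
    "concordance_summary",
    "aggregate_features",
    "run_prediction_harness",
]

VERDICTS = ("accurate", "ambiguous", "inaccurate")


@dataclass(frozen=True)
class AccuracyVerdict:
    donor_id: str
    verdict: str  # accurate | ambiguous | inaccurate
    matched_classes: frozenset[str]
    rationale: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def nd_label(nd_codes: Iterable[str]) -> str:
    """Canonical label for a (possibly combined) diagnosis: sorted codes
    joined by '-', e.g. ('DLB', 'AD') -> 'AD-DLB'."""
    codes = sorted(set(nd_codes))
    return "-".join(codes)


def assign_cd_verdict(
    cd_classes: Iterable[str],
    nd_codes: Iterable[str] | str,
    dictionary: AccuracyDictionary,
    donor_id: str = "",
    strict_umbrella: bool = False,
) -> AccuracyVerdict:
    """Verdict for a donor's lifetime clinical-diagnosis list.

    Any-match semantics: one accurate CD suffices — unless another CD is
    disease-specific for a different covered disorder, which demotes the
    donor to ambiguous. Umbrella-only matches are ambiguous. With
    ``strict_umbrella`` an umbrella CD alongside an exact one also demotes
    to ambiguous (default keeps exact-match precedence).
    """
    label = nd_codes if isinstance(nd_codes, str) else nd_label(nd_codes)
    cds = frozenset(cd_classes)
    accurate_set = dictionary.accurate_for(label)  # KeyError if ND not covered
    umbrella_set = dictionary.ambiguous_for(label)
    disease_specific = dictionary.disease_specific_classes()

    matched = cds & accurate_set
    umbrella = cds & umbrella_set
    conflicting = cds & (disease_specific - accurate_set - umbrella_set)

    if matched and not conflicting and not (strict_umbrella and umbrella):
        return AccuracyVerdict(
            donor_id, "accurate", matched, f"CD matches {label} class set"
        )
    if matched and conflicting:
        return AccuracyVerdict(
            donor_id,
            "ambiguous",
            matched | conflicting,
            f"accurate CD alongside conflicting diagnosis {sorted(conflicting)}",
        )
    if matched and strict_umbrella and umbrella:
        return AccuracyVerdict(
            donor_id,
            "ambiguous",
            matched | umbrella,
            "exact match demoted by umbrella CD (strict mode)",
        )
    if umbrella:
        return AccuracyVerdict(
            donor_id,
            "ambiguous",
            umbrella,
            f"only umbrella match {sorted(umbrella)}",
        )
    return AccuracyVerdict(donor_id, "inaccurate", frozenset(), "no matching CD")


def assign_model_verdict(
    predicted_nd: str,
    true_nd_codes: Iterable[str] | str,
    donor_id: str = "",
) -> AccuracyVerdict:
    """Verdict for a single predicted diagnosis against the true ND.

    Exact match (full combined label) is accurate; partial overlap with a
    combined ND (e.g. AD predicted for an AD-DLB donor) is ambiguous;
    anything else is inaccurate.
    """
    true_set = (
        set(true_nd_codes.split("-"))
        if isinstance(true_nd_codes, str)
        else {c for code in true_nd_codes for c in code.split("-")}
    )
    pred_set = set(predicted_nd.split("-"))
    if pred_set == true_set:
        return AccuracyVerdict(
            donor_id, "accurate", frozenset(pred_set), "exact diagnosis match"
        )
    if pred_set & true_set:
        return AccuracyVerdict(
            donor_id,
            "ambiguous",
            frozenset(pred_set & true_set),
            "partial match to combined diagnosis",
        )
    return AccuracyVerdict(donor_id, "inaccurate", frozenset(), "diagnosis mismatch")


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A intersect B| / |A union B|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class ConcordanceSummary:
    confusion: pd.DataFrame  # ND x CD observation counts
    confusion_normalized: pd.DataFrame  # counts / total ND observations per row
    per_disorder: pd.DataFrame  # jaccard, directional %, donor counts
    verdicts: pd.DataFrame  # donor_id, verdict, matched, rationale
    verdict_counts: dict[str, int] = field(default_factory=dict)


def concordance_summary(
    donors: pd.DataFrame,
    dictionary: AccuracyDictionary,
    strict_umbrella: bool = False,
) -> ConcordanceSummary:
    """Concordance of CD with ND over a cohort.

    ``donors`` needs columns ``donor_id``, ``nd`` (canonical label) and
    ``cd_classes`` (an iterable of CD ontology classes per donor).
    """
    verdict_rows = []
    confusion_counts: dict[tuple[str, str], int] = {}
    for row in donors.itertuples(index=False):
        verdict = assign_cd_verdict(
            row.cd_classes,
            row.nd,
            dictionary,
            donor_id=str(row.donor_id),
            strict_umbrella=strict_umbrella,
        )
        verdict_rows.append(
            {
                "donor_id": verdict.donor_id,
                "verdict": verdict.verdict,
                "matched_classes": ";".join(sorted(verdict.matched_classes)),
                "rationale": verdict.rationale,
            }
        )
        for cd in row.cd_classes:
            key = (row.nd, cd)
            confusion_counts[key] = confusion_counts.get(key, 0) + 1

    nd_order = sorted(donors["nd"].unique())
    cd_order = sorted({cd for (_, cd) in confusion_counts})
    confusion = pd.DataFrame(0, index=nd_order, columns=cd_order, dtype=int)
    for (nd, cd), count in confusion_counts.items():
        confusion.loc[nd, cd] = count
    row_totals = confusion.sum(axis=1).replace(0, 1)
    normalized = confusion.div(row_totals, axis=0)

    per_disorder_rows = []
    for disorder in sorted(dictionary.covered_nds):
        accurate_set = dictionary.accurate_for(disorder)
        nd_set = set(donors.loc[donors["nd"] == disorder, "donor_id"])
        cd_set = {
            str(row.donor_id)
            for row in donors.itertuples(index=False)
            if set(row.cd_classes) & accurate_set
        }
        inter = nd_set & cd_set
        per_disorder_rows.append(
            {
                "disorder": disorder,
                "n_nd": len(nd_set),
                "n_cd": len(cd_set),
                "jaccard": jaccard(nd_set, cd_set),
                "pct_nd_with_cd": len(inter) / len(nd_set) if nd_set else 0.0,
                "pct_cd_with_nd": len(inter) / len(cd_set) if cd_set else 0.0,
            }
        )
    verdicts = pd.DataFrame(verdict_rows)
    counts = {v: int((verdicts["verdict"] == v).sum()) for v in VERDICTS}
    return ConcordanceSummary(
        confusion=confusion,
        confusion_normalized=normalized,
        per_disorder=pd.DataFrame(per_disorder_rows).set_index("disorder"),
        verdicts=verdicts,
        verdict_counts=counts,
    )


# ---------------------------------------------------------------------------
# trajectory-based diagnosis prediction


def aggregate_features(
    trajectories: Mapping[str, Trajectory],
    metadata: pd.DataFrame,
    attributes: Sequence[str],
    missing_onset: float = -1.0,
) -> pd.DataFrame:
    """Per-donor aggregated trajectory features for the baseline classifier.

    Columns: per-attribute observation-year counts, per-attribute
    first-observation age (``missing_onset`` when never observed), sex
    (female = 1) and age at death. Row index is donor id.
    """
    rows = []
    for row in metadata.itertuples(index=False):
        donor_id = str(row.donor_id)
        trajectory = trajectories.get(donor_id)
        features: dict[str, float] = {}
        for attribute in attributes:
            if trajectory is None:
                features[f"count_{attribute}"] = 0.0
                features[f"onset_{attribute}"] = missing_onset
                continue
            block = trajectory.frame[
                (trajectory.frame["attribute"] == attribute)
                & (trajectory.frame["present"] == 1)
            ]
            features[f"count_{attribute}"] = float(len(block))
            features[f"onset_{attribute}"] = (
                float(block["age"].min()) if len(block) else missing_onset
            )
        features["sex_female"] = 1.0 if str(row.sex).upper().startswith("F") else 0.0
        features["age_at_death"] = float(row.death_age)
        features["donor_id"] = donor_id
        rows.append(features)
    return pd.DataFrame(rows).set_index("donor_id")


@dataclass
class PredictionResult:
    predictions: pd.DataFrame  # donor_id, true_nd, predicted_nd, verdict, fold
    verdict_counts: dict[str, int]
    accuracy: float
    fold_accuracies: list[float]


def _default_classifier():
    return make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000)
    )


def run_prediction_harness(
    features: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    seed: int = 0,
    n_folds: int = 5,
    min_class_size: int = 5,
    rare_label: str = "OTHER",
    classifier_factory: Callable[[], object] | None = None,
) -> PredictionResult:
    """Diagnosis-stratified 5-fold prediction with verdict counting.

    Classes with fewer than ``min_class_size`` donors are folded into a
    single rare stratum (with a warning) so that stratification remains
    possible; their verdicts are still scored against the original ND.
    Deterministic under ``seed`` for the baseline classifier.
    """
    labels = pd.Series(labels).reindex(features.index)
    if labels.isna().any():
        raise ValueError("every donor in the feature table needs a label")
    class_sizes = labels.value_counts()
    rare = set(class_sizes.index[class_sizes < min_class_size])
    if rare:
        warnings.warn(
            f"classes {sorted(rare)} have <{min_class_size} donors; folded into "
            f"{rare_label!r} for training",
            stacklevel=2,
        )
    train_labels = labels.where(~labels.isin(rare), rare_label)

    X = features.to_numpy(dtype=float)
    y = train_labels.to_numpy()
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    factory = classifier_factory or _default_classifier
    records = []
    fold_accuracies = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[train_idx])) < 2:
            # degenerate single-class cohort: constant prediction
            predicted = np.full(len(test_idx), y[train_idx][0], dtype=object)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sklearn solver chatter
                model = factory()
                model.fit(X[train_idx], y[train_idx])
                predicted = model.predict(X[test_idx])
        hits = 0
        for idx, pred in zip(test_idx, predicted):
            donor_id = str(features.index[idx])
            true = str(labels.iloc[idx])
            verdict = assign_model_verdict(str(pred), true, donor_id=donor_id)
            hits += verdict.verdict == "accurate"
            records.append(
                {
                    "donor_id": donor_id,
                    "true_nd": true,
                    "predicted_nd": str(pred),
                    "verdict": verdict.verdict,
                    "fold": fold,
                }
            )
        fold_accuracies.append(hits / len(test_idx))
    predictions = pd.DataFrame(records)
    counts = {v: int((predictions["verdict"] == v).sum()) for v in VERDICTS}
    return PredictionResult(
        predictions=predictions,
        verdict_counts=counts,
        accuracy=float((predictions["verdict"] == "accurate").mean()),
        fold_accuracies=fold_accuracies,
    )
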