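"""Multilabel sign/symptom sentence classification baselines.

The extraction task is multilabel: one clinical-history sentence may
describe several signs or symptoms at once, and most attributes are rare,
so the evaluation design matters as much as the model. This module carries

* the split design — a held-out test fraction of 20% plus 5-fold
  cross-validation on the remainder, both stratified with the iterative
  multilabel stratification algorithm (Sechidis, Tsoumakas & Vlahavas,
  2011) so that scarce labels are spread evenly across folds;
* two linear baselines wrapped one-vs-rest over attributes: a bag-of-words
  logistic regression on word frequencies and a linear SVM, both after
  stop-word removal and count vectorization;
* micro-averaged precision/recall/F1 evaluation (counts pooled over all
  sentence x attribute pairs — appropriate for imbalanced label sets);
* the model-selection rule: random hyperparameter search maximizing mean
  micro-F1 across the 5 folds, then, among the top five trials by micro-F1,
  the one with the highest micro-precision wins (precision is favoured over
  exhaustive recall);
* the attribute-retention rule: an attribute is kept for corpus-wide
  prediction iff its precision >= 0.8 or its F1 >= 0.8 on held-out data;
* Cohen's kappa for interannotator agreement.

Zero-division conventions: precision/recall/F1 are reported as 0.0 when
their denominator is empty (with a warning); kappa is undefined (NaN) when
both annotators are constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

__all__ = [
    "SplitPlan",
    "MetricReport",
    "ModelSpec",
    "TrialResult",
    "iterative_stratification",
    "make_split",
    "build_model",
    "evaluate",
    "tune",
    "select_final",
    "retain_attributes",
    "cohen_kappa",
    "predict_corpus",
]


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SplitPlan:
    """Test/train partition plus cross-validation folds over the train part."""

    test_idx: np.ndarray  # sentence indices of the held-out test set
    fold_assignments: np.ndarray  # fold id per sentence; -1 marks test
    n_folds: int
    test_fraction: float

    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments >= 0)

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) indices for one cross-validation fold."""
        val = np.flatnonzero(self.fold_assignments == fold)
        train = np.flatnonzero(
            (self.fold_assignments >= 0) & (self.fold_assignments != fold)
        )
        return train, val


def iterative_stratification(
    Y: np.ndarray, proportions: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Assign each row of a binary label matrix to one of len(proportions)
    subsets, balancing every label's positives across subsets.

    Implements the iterative-stratification heuristic: repeatedly take the
    label with the fewest unassigned positive examples and deal those
    examples to the subset whose desired count for that label is largest
    (ties broken by overall remaining capacity, then randomly).
    """
    Y = np.asarray(Y, dtype=bool)
    n, n_labels = Y.shape
    proportions = np.asarray(proportions, dtype=float)
    proportions = proportions / proportions.sum()
    n_subsets = len(proportions)

    desired_size = proportions * n
    desired_label = proportions[:, None] * Y.sum(axis=0)[None, :]

    assignment = np.full(n, -1, dtype=int)
    remaining = np.ones(n, dtype=bool)

    def place(example: int, scores: np.ndarray) -> None:
        best = np.flatnonzero(scores == scores.max())
        if len(best) > 1:
            cap = desired_size[best]
            best = best[cap == cap.max()]
        choice = int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])
        assignment[example] = choice
        remaining[example] = False
        desired_size[choice] -= 1
        desired_label[choice] -= Y[example]

    while True:
        counts = (Y[remaining].sum(axis=0)).astype(float)
        counts[counts == 0] = np.inf
        if np.isinf(counts).all():
            break
        label = int(np.argmin(counts))
        for example in np.flatnonzero(remaining & Y[:, label]):
            place(example, desired_label[:, label])
    # Label-free examples: deal by remaining capacity.
    for example in np.flatnonzero(remaining):
        place(example, desired_size)
    return assignment


def make_split(
    Y: np.ndarray | pd.DataFrame,
    seed: int,
    test_fraction: float = 0.20,
    n_folds: int = 5,
) -> SplitPlan:
    """Multilabel-stratified test split plus cross-validation folds.

    Attributes without a single positive sentence are excluded from
    stratification with a warning (they cannot be balanced).
    """
    Y = np.asarray(Y, dtype=bool)
    positives = Y.sum(axis=0)
    if (positives == 0).any():
        warnings.warn(
            f"{int((positives == 0).sum())} attribute(s) have no positive "
            "sentences and are excluded from stratification",
            stacklevel=2,
        )
        Y = Y[:, positives > 0]
    rng = np.random.default_rng(seed)
    top = iterative_stratification(Y, [1.0 - test_fraction, test_fraction], rng)
    test_idx = np.flatnonzero(top == 1)
    train_idx = np.flatnonzero(top == 0)
    folds = iterative_stratification(Y[train_idx], [1.0 / n_folds] * n_folds, rng)
    fold_assignments = np.full(Y.shape[0], -1, dtype=int)
    fold_assignments[train_idx] = folds
    return SplitPlan(
        test_idx=test_idx,
        fold_assignments=fold_assignments,
        n_folds=n_folds,
        test_fraction=test_fraction,
    )


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one baseline family."""

    family: str  # "bow_logreg" | "linear_svm"
    C: float = 1.0
    ngram_range: tuple[int, int] = (1, 1)
    min_df: int = 1

    def __post_init__(self) -> None:
        if self.family not in {"bow_logreg", "linear_svm"}:
            raise ValueError(f"unsupported model family {self.family!r}")


def build_model(spec: ModelSpec) -> Pipeline:
    """Vectorizer + one-vs-rest linear classifier for one spec."""
    if spec.family == "bow_logreg":
        estimator = LogisticRegression(C=spec.C, max_iter=2000)
    else:
        estimator = LinearSVC(C=spec.C)
    return Pipeline(
        [
            (
                "vectorize",
                CountVectorizer(
                    stop_words="english",
                    ngram_range=spec.ngram_range,
                    min_df=spec.min_df,
                ),
            ),
            ("classify", OneVsRestClassifier(estimator)),
        ]
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class MetricReport:
    micro_precision: float
    micro_recall: float
    micro_f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    per_attribute: pd.DataFrame  # precision, recall, f1, tp, fp, fn, tn per row

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def evaluate(
    predictions: np.ndarray | pd.DataFrame,
    gold: np.ndarray | pd.DataFrame,
    attribute_names: Sequence[str] | None = None,
) -> MetricReport:
    """Micro-averaged and per-attribute precision/recall/F1 from pooled counts."""
    if attribute_names is None and isinstance(gold, pd.DataFrame):
        attribute_names = list(gold.columns)
    pred = np.asarray(predictions, dtype=bool)
    true = np.asarray(gold, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if attribute_names is None:
        attribute_names = [f"attr_{i}" for i in range(true.shape[1])]

    tp = (pred & true).sum(axis=0)
    fp = (pred & ~true).sum(axis=0)
    fn = (~pred & true).sum(axis=0)
    tn = (~pred & ~true).sum(axis=0)
    if (tp + fp).sum() == 0:
        warnings.warn("no positive predictions: precision set to 0", stacklevel=2)

    rows = []
    for i, name in enumerate(attribute_names):
        p, r, f = _prf(tp[i], fp[i], fn[i])
        rows.append(
            {
                "attribute": name,
                "precision": p,
                "recall": r,
                "f1": f,
                "tp": int(tp[i]),
                "fp": int(fp[i]),
                "fn": int(fn[i]),
                "tn": int(tn[i]),
            }
        )
    micro_p, micro_r, micro_f = _prf(tp.sum(), fp.sum(), fn.sum())
    return MetricReport(
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=micro_f,
        tp=int(tp.sum()),
        fp=int(fp.sum()),
        fn=int(fn.sum()),
        tn=int(tn.sum()),
        per_attribute=pd.DataFrame(rows).set_index("attribute"),
    )


# ---------------------------------------------------------------------------
# tuning and selection


@dataclass
class TrialResult:
    index: int
    spec: ModelSpec
    mean_micro_f1: float
    mean_micro_precision: float
    fold_reports: list[MetricReport] = field(default_factory=list)


_NGRAMS = [(1, 1), (1, 2)]
_MIN_DF = [1, 2, 5]


def _sample_spec(family: str, rng: np.random.Generator) -> ModelSpec:
    log_c = rng.uniform(np.log(1e-3), np.log(1e3))
    return ModelSpec(
        family=family,
        C=float(np.exp(log_c)),
        ngram_range=_NGRAMS[int(rng.integers(len(_NGRAMS)))],
        min_df=_MIN_DF[int(rng.integers(len(_MIN_DF)))],
    )


def tune(
    family: str,
    sentences: Sequence[str],
    Y: np.ndarray | pd.DataFrame,
    plan: SplitPlan,
    n_trials: int = 25,
    seed: int = 0,
    search_space: Sequence[ModelSpec] | None = None,
) -> tuple[ModelSpec, list[TrialResult]]:
    """Random hyperparameter search over the cross-validation folds.

    Each trial trains on four folds and validates on the fifth; the score
    is the mean micro-F1 across folds. The returned spec is chosen by
    :func:`select_final`. Failed trials are skipped with a warning.
    """
    sentences = np.asarray(sentences, dtype=object)
    Y = np.asarray(Y, dtype=int)
    rng = np.random.default_rng(seed)
    trials: list[TrialResult] = []
    for t in range(n_trials):
        spec = (
            search_space[t % len(search_space)]
            if search_space is not None
            else _sample_spec(family, rng)
        )
        reports: list[MetricReport] = []
        try:
            for fold in range(plan.n_folds):
                train, val = plan.fold_split(fold)
                model = build_model(spec)
                model.fit(list(sentences[train]), Y[train])
                pred = model.predict(list(sentences[val]))
                reports.append(evaluate(pred, Y[val]))
        except Exception as exc:  # noqa: BLE001 - a bad spec must not kill the search
            warnings.warn(f"trial {t} ({spec}) failed: {exc}", stacklevel=2)
            continue
        trials.append(
            TrialResult(
                index=t,
                spec=spec,
                mean_micro_f1=float(np.mean([r.micro_f1 for r in reports])),
                mean_micro_precision=float(
                    np.mean([r.micro_precision for r in reports])
                ),
                fold_reports=reports,
            )
        )
    if not trials:
        raise RuntimeError("all tuning trials failed")
    return select_final(trials), trials


def select_final(trials: Sequence[TrialResult], top_k: int = 5) -> ModelSpec:
    """Two-stage rule: among the top-``top_k`` trials by mean micro-F1,
    return the one with the highest mean micro-precision (ties: lowest
    trial index)."""
    if not trials:
        raise ValueError("no trials to select from")
    by_f1 = sorted(trials, key=lambda t: (-t.mean_micro_f1, t.index))[:top_k]
    best = sorted(by_f1, key=lambda t: (-t.mean_micro_precision, t.index))[0]
    return best.spec


def retain_attributes(report: MetricReport, threshold: float = 0.8) -> list[str]:
    """Attributes kept for corpus-wide prediction: precision >= threshold
    OR F1 >= threshold on held-out data."""
    per = report.per_attribute
    keep = (per["precision"] >= threshold) | (per["f1"] >= threshold)
    return list(per.index[keep])


# ---------------------------------------------------------------------------
# agreement and corpus prediction


def cohen_kappa(
    labels_a: np.ndarray | pd.DataFrame,
    labels_b: np.ndarray | pd.DataFrame,
    attribute_names: Sequence[str] | None = None,
) -> tuple[pd.Series, float]:
    """Cohen's kappa per attribute plus pooled over all pairs.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the annotators' marginal
    positive rates. Constant labels on both sides make kappa undefined
    (reported as NaN).
    """
    if attribute_names is None and isinstance(labels_a, pd.DataFrame):
        attribute_names = list(labels_a.columns)
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if attribute_names is None:
        attribute_names = [f"attr_{i}" for i in range(a.shape[1])]

    def kappa(x: np.ndarray, y: np.ndarray) -> float:
        p_o = float(np.mean(x == y))
        px, py = float(x.mean()), float(y.mean())
        p_e = px * py + (1 - px) * (1 - py)
        if p_e >= 1.0:
            return float("nan")
        return (p_o - p_e) / (1 - p_e)

    per = pd.Series(
        {name: kappa(a[:, i], b[:, i]) for i, name in enumerate(attribute_names)},
        name="kappa",
    )
    return per, kappa(a.ravel(), b.ravel())


def predict_corpus(
    model: Pipeline,
    sentences: Sequence[str],
    attribute_names: Sequence[str],
    retained: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Binary attribute predictions per sentence, restricted to the retained
    attribute set when given."""
    if len(sentences) == 0:
        return pd.DataFrame(columns=list(attribute_names))
    pred = np.asarray(model.predict(list(sentences)), dtype=int)
    frame = pd.DataFrame(pred, columns=list(attribute_names))
    if retained is not None:
        frame = frame[[a for a in attribute_names if a in set(retained)]]
    return frame
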