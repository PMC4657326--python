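"""Confusion metrics, per-characteristic screening, jackknife validation,
ROC analysis, and the predictable-portion group comparison.

Conventions: a "positive" is a crystallized protein (label 1). Accuracy,
sensitivity and specificity are percentages:

    accuracy    = (TP + TN) / (TP + FP + TN + FN) * 100
    sensitivity =  TP / (TP + FN) * 100
    specificity =  TN / (TN + FP) * 100

A zero denominator yields ``None`` (reported as missing, never as 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dynamic import pair_predictability
from .models import CrystallizationNet, LogisticPropensityModel
from .sequences import LabeledDataset


# ---------------------------------------------------------------------------
# confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(predicted: Sequence[int], actual: Sequence[int]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from parallel binary vectors."""
    predicted = np.asarray(predicted)
    actual = np.asarray(actual)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    for name, v in (("predicted", predicted), ("actual", actual)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(((predicted == 1) & (actual == 1)).sum()),
        tn=int(((predicted == 0) & (actual == 0)).sum()),
        fp=int(((predicted == 1) & (actual == 0)).sum()),
        fn=int(((predicted == 0) & (actual == 1)).sum()),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float | None, float | None]:
    """(accuracy %, sensitivity %, specificity %); None on a 0 denominator."""
    if counts.n < 1:
        raise ValueError("need at least one prediction")
    acc = 100.0 * (counts.tp + counts.tn) / counts.n
    sens = (100.0 * counts.tp / (counts.tp + counts.fn)
            if counts.tp + counts.fn else None)
    spec = (100.0 * counts.tn / (counts.tn + counts.fp)
            if counts.tn + counts.fp else None)
    return acc, sens, spec


@dataclass
class EvaluationReport:
    """Outcome of evaluating one model/encoding on a dataset."""

    counts: ConfusionCounts
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    per_sample: list[tuple[str, float, int, int]]  # (id, score, pred, actual)
    mode: str = "fit"
    source: str = ""
    flagged_folds: list[int] = field(default_factory=list)

    @classmethod
    def from_predictions(cls, ids, scores, predicted, actual, mode, source="",
                         flagged=()):
        c = confusion(predicted, actual)
        acc, sens, spec = metrics(c)
        per_sample = list(zip(ids, map(float, scores),
                              map(int, predicted), map(int, actual)))
        return cls(c, acc, sens, spec, per_sample, mode, source, list(flagged))

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s, _, _ in self.per_sample])

    @property
    def actual(self) -> np.ndarray:
        return np.array([a for _, _, _, a in self.per_sample])


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _make_model(model_kind: str, seed: int):
    if model_kind == "logistic":
        return LogisticPropensityModel()
    if model_kind == "nn":
        return CrystallizationNet(random_state=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _fold_seed(seed: int, fold: int) -> int:
    """Deterministic per-fold seed below 2**31."""
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0]
               % (2**31))


def evaluate_fit(dataset: LabeledDataset, encoder, model_kind: str = "logistic",
                 seed: int = 0) -> EvaluationReport:
    """Train on the full dataset and evaluate on the same proteins.

    This is the first-stage "is the model workable at all" check; honest
    generalisation estimates come from :func:`jackknife_delete1`.
    """
    X = encoder.fit(dataset.records).transform(dataset.records)
    y = np.asarray(dataset.y)
    model = _make_model(model_kind, seed).fit(X, y)
    scores = model.predict_proba(X)[:, 1]
    predicted = (scores >= 0.5).astype(int)
    return EvaluationReport.from_predictions(
        [r.id for r in dataset.records], scores, predicted, y,
        mode="fit", source=getattr(encoder, "source_", ""),
    )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_characteristics(
    dataset: LabeledDataset,
    encodings: Iterable[tuple[str, object]],
    model_kind: str = "logistic",
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every (source, encoder) pair in fit mode, one row each.

    Rows are sorted by accuracy (descending), ties broken by source id.
    A failing encoding flags its row (``error`` column) and screening
    continues.
    """
    y = np.asarray(dataset.y)
    if len(np.unique(y)) < 2:
        raise ValueError("screening needs both classes present")
    rows = []
    for source, encoder in encodings:
        try:
            report = evaluate_fit(dataset, encoder, model_kind, seed)
            rows.append({
                "source": source, "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "mode": "fit", "error": "",
            })
        except Exception as exc:  # noqa: BLE001 - row-level isolation
            warnings.warn(f"screening {source} failed: {exc}", stacklevel=2)
            rows.append({
                "source": source, "accuracy": np.nan, "sensitivity": np.nan,
                "specificity": np.nan, "mode": "fit", "error": str(exc),
            })
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["accuracy", "source"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# delete-1 jackknife
# ---------------------------------------------------------------------------

def jackknife_delete1(dataset: LabeledDataset, encoder,
                      model_kind: str = "logistic",
                      seed: int = 0) -> EvaluationReport:
    """Leave-one-out validation: n models, each predicting its held-out protein.

    Each fold's model seed derives deterministically from (seed, fold index).
    A fold whose training split loses one class is flagged and predicted by
    the training prevalence.
    """
    n = dataset.n
    if n < 3:
        raise ValueError("jackknife needs n >= 3")
    X = encoder.fit(dataset.records).transform(dataset.records)
    y = np.asarray(dataset.y)
    scores = np.empty(n)
    flagged = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if len(np.unique(y_train)) < 2:
            flagged.append(i)
            scores[i] = y_train.mean()
            continue
        model = _make_model(model_kind, _fold_seed(seed, i))
        model.fit(X[mask], y_train)
        scores[i] = model.predict_proba(X[i][None, :])[0, 1]
    predicted = (scores >= 0.5).astype(int)
    return EvaluationReport.from_predictions(
        [r.id for r in dataset.records], scores, predicted, y,
        mode="jackknife", source=getattr(encoder, "source_", ""),
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """ROC sweep over score thresholds.

    ``points`` holds (sensitivity %, specificity %) pairs — the historical
    sensitivity-vs-specificity plotting convention; ``fpr``/``tpr`` give the
    standard sensitivity-vs-(1 - specificity) convention in fractions. The
    AUC is always the trapezoidal area in the standard convention.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return [(100.0 * t, 100.0 * (1.0 - f))
                for t, f in zip(self.tpr, self.fpr)]


def roc(scores: Sequence[float], actual: Sequence[int]) -> RocCurve:
    """ROC curve and trapezoidal AUC from continuous scores."""
    actual = np.asarray(actual)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(actual)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(actual, scores, drop_intermediate=False)
    return RocCurve(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# predictable-portion group comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    u_statistic: float
    p_value: float
    n_high: int
    n_low: int
    median_high: float
    median_low: float
    iqr_high: tuple[float, float]
    iqr_low: tuple[float, float]
    cutoff: float


def predictable_portion_group_test(
    per_protein: Sequence[tuple[str, float, float]],
    cutoff: float = 90.0,
) -> GroupTestResult:
    """Compare predictable portions between well- and poorly-predicted proteins.

    ``per_protein`` rows are (id, accuracy %, predictable portion %). Proteins
    with accuracy >= ``cutoff`` form the high group. The predictable portions
    of the two groups are compared with a two-sided Mann-Whitney U test —
    exact when both groups are small (min n <= 8) and tie-free, otherwise the
    normal approximation with tie correction.
    """
    high = [p for _, a, p in per_protein if a >= cutoff]
    low = [p for _, a, p in per_protein if a < cutoff]
    if not high or not low:
        raise ValueError(
            f"cutoff {cutoff}: both accuracy groups must be nonempty "
            f"(high={len(high)}, low={len(low)})"
        )
    has_ties = len(set(high) | set(low)) < len(high) + len(low)
    method = "exact" if (min(len(high), len(low)) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(high, low, alternative="two-sided", method=method)
    q_high = np.percentile(high, [25, 75])
    q_low = np.percentile(low, [25, 75])
    return GroupTestResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        n_high=len(high), n_low=len(low),
        median_high=float(np.median(high)), median_low=float(np.median(low)),
        iqr_high=(float(q_high[0]), float(q_high[1])),
        iqr_low=(float(q_low[0]), float(q_low[1])),
        cutoff=cutoff,
    )


def per_protein_accuracy(
    dataset: LabeledDataset, encoder, model_kind: str = "nn",
    mode: str = "fit", n_repeats: int = 20, seed: int = 0,
    pair_rule: str = "strict",
) -> list[tuple[str, float, float]]:
    """Per-protein accuracy over repeated stochastic fits, plus pair portions.

    Each protein's accuracy is the percentage of ``n_repeats`` model
    trainings (differing only in seed) in which it is classified correctly —
    using the full-data model in ``fit`` mode or its held-out jackknife
    prediction in ``jackknife`` mode. Returned rows are
    (id, accuracy %, predictable portion %), ready for
    :func:`predictable_portion_group_test`.
    """
    if mode not in ("fit", "jackknife"):
        raise ValueError(f"unknown mode {mode!r}")
    y = np.asarray(dataset.y)
    correct = np.zeros(dataset.n)
    for rep in range(n_repeats):
        rep_seed = _fold_seed(seed, 10_000 + rep)
        if mode == "fit":
            report = evaluate_fit(dataset, encoder, model_kind, rep_seed)
        else:
            report = jackknife_delete1(dataset, encoder, model_kind, rep_seed)
        predicted = np.array([p for _, _, p, _ in report.per_sample])
        correct += predicted == y
    portions = [pair_predictability(r, rule=pair_rule)[1]
                for r in dataset.records]
    return [
        (r.id, 100.0 * correct[i] / n_repeats, portions[i])
        for i, r in enumerate(dataset.records)
    ]
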