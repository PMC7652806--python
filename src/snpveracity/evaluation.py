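"""Classification quality metrics and probability-cutoff estimation.

The positive class is the *incorrect* SNP call.  A row with predicted
probability >= cutoff is classified incorrect (so cutoff 0 classifies
everything as incorrect).  Two summary metrics quantify a classifier:

* ``F1   = 2 TP / (2 TP + FN + FP)``
* ``SUMSS = TN/(TN+FP) + TP/(TP+FN)``  (specificity + sensitivity, in [0, 2])

The metric-optimal cutoff is found exhaustively over the candidate set
{distinct observed probabilities} ∪ {0, 1}, returning the smallest
candidate attaining the maximum.  The final cutoff estimate is the mean of
per-resample optima over bootstrap resamples (full-size draws with
replacement), with a robustness check across independent sub-samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ContractViolationError, UndefinedMetricError

logger = logging.getLogger(__name__)

METRICS = ("f1", "sumss")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP with the incorrect call as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_incorrect(self) -> int:
        return self.tp + self.fn

    @property
    def n_correct(self) -> int:
        return self.tn + self.fp


def _as_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "US":
        arr = (arr == "incorrect").astype(int)
    return arr.astype(int)


def confusion(labels, probabilities, cutoff: float) -> ConfusionCounts:
    """Tally the four categories at a cutoff (rule: p >= cutoff -> incorrect)."""
    y = _as_labels(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(y) != len(p):
        raise ContractViolationError(
            f"length mismatch: {len(y)} labels vs {len(p)} probabilities"
        )
    if not 0.0 <= cutoff <= 1.0:
        raise ContractViolationError(f"cutoff must be in [0, 1], got {cutoff}")
    pred = p >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
    )


def f1_metric(c: ConfusionCounts) -> float:
    """F1 = 2TP/(2TP+FN+FP); 0 when the denominator is 0."""
    den = 2 * c.tp + c.fn + c.fp
    return 2.0 * c.tp / den if den else 0.0


def sumss_metric(c: ConfusionCounts) -> float:
    """Specificity + sensitivity; requires both classes non-empty."""
    if c.n_correct == 0 or c.n_incorrect == 0:
        raise UndefinedMetricError(
            f"SUMSS undefined with class sizes ({c.n_correct}, {c.n_incorrect})"
        )
    return c.tn / c.n_correct + c.tp / c.n_incorrect


def precision_metric(c: ConfusionCounts) -> float:
    den = c.tp + c.fp
    return c.tp / den if den else 0.0


def recall_metric(c: ConfusionCounts) -> float:
    den = c.tp + c.fn
    return c.tp / den if den else 0.0


def _metric_curve(y: np.ndarray, p: np.ndarray, metric: str):
    """Vectorized metric over the candidate cutoff set.

    Returns (candidates ascending, metric values)."""
    metric = metric.lower()
    if metric not in METRICS:
        raise ContractViolationError(f"metric must be in {METRICS}, got {metric!r}")
    cands = np.unique(np.concatenate([p, [0.0, 1.0]]))
    pos = np.sort(p[y == 1])
    neg = np.sort(p[y == 0])
    tp = len(pos) - np.searchsorted(pos, cands, side="left")
    fp = len(neg) - np.searchsorted(neg, cands, side="left")
    fn = len(pos) - tp
    tn = len(neg) - fp
    if metric == "f1":
        den = 2 * tp + fn + fp
        vals = np.where(den > 0, 2.0 * tp / np.maximum(den, 1), 0.0)
    else:
        if len(pos) == 0 or len(neg) == 0:
            raise UndefinedMetricError("SUMSS needs both classes present")
        vals = tn / len(neg) + tp / len(pos)
    return cands, vals


def optimal_cutoff(labels, probabilities, metric: str = "f1") -> float:
    """Smallest cutoff candidate attaining the global metric maximum.

    Candidates are the distinct observed probabilities plus 0 and 1, so the
    search is exact (the metric is piecewise constant between candidates).
    """
    y = _as_labels(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.min() == y.max():
        raise UndefinedMetricError("cutoff optimization needs both classes present")
    cands, vals = _metric_curve(y, p, metric)
    return float(cands[int(np.argmax(vals))])  # first occurrence = smallest


@dataclass(frozen=True)
class CutoffEstimate:
    metric: str
    point_cutoff: float
    bootstrap_mean: float
    bootstrap_sd: float
    n_bootstrap: int
    seed: int
    cutoffs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.point_cutoff <= 1.0 or self.bootstrap_sd < 0:
            raise ContractViolationError("invalid cutoff estimate")


def bootstrap_cutoff(
    labels,
    probabilities,
    metric: str = "f1",
    n_bootstrap: int = 100,
    seed: int = 0,
    retry_cap: int = 100,
) -> CutoffEstimate:
    """Bootstrap-mean cutoff: full-size resamples with replacement, the
    metric-optimal cutoff of each, averaged.

    A resample containing a single class is redrawn (logged), up to
    ``retry_cap`` attempts per resample.
    """
    y = _as_labels(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.min() == y.max():
        raise UndefinedMetricError("bootstrap cutoff needs both classes present")
    rng = np.random.default_rng(seed)
    n = len(y)
    cutoffs = []
    for _ in range(n_bootstrap):
        for attempt in range(retry_cap):
            idx = rng.integers(0, n, size=n)
            if y[idx].min() != y[idx].max():
                break
            logger.info("single-class bootstrap resample redrawn (attempt %d)", attempt + 1)
        else:
            raise UndefinedMetricError(
                f"could not draw a two-class resample in {retry_cap} attempts"
            )
        cutoffs.append(optimal_cutoff(y[idx], p[idx], metric))
    arr = np.asarray(cutoffs)
    return CutoffEstimate(
        metric=metric.lower(),
        point_cutoff=optimal_cutoff(y, p, metric),
        bootstrap_mean=float(arr.mean()),
        bootstrap_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_bootstrap=n_bootstrap,
        seed=seed,
        cutoffs=tuple(float(c) for c in arr),
    )


def subsample_robustness(
    labels,
    probabilities,
    metric: str = "f1",
    n_subsamples: int = 20,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> dict:
    """Spread of the bootstrap cutoff estimate across independent
    sub-samples (full-size resamples with replacement) of the data."""
    y = _as_labels(labels)
    p = np.asarray(probabilities, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    estimates = []
    for k in range(n_subsamples):
        idx = rng.integers(0, n, size=n)
        est = bootstrap_cutoff(
            y[idx], p[idx], metric, n_bootstrap=n_bootstrap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        estimates.append(est.bootstrap_mean)
    arr = np.asarray(estimates)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return {
        "metric": metric.lower(),
        "cutoffs": [float(c) for c in arr],
        "mean": float(arr.mean()),
        "sd": sd,
        "degenerate": len(arr) < 2,
    }


def evaluate(labels, probabilities, cutoff: float) -> dict:
    """Full evaluation report at one cutoff.

    TP% = TP/(TP+FN)*100 and TN% = TN/(TN+FP)*100 (the percentage of each
    true class properly recovered), rounded to two decimals; F1 and SUMSS
    where defined; precision and recall.
    """
    c = confusion(labels, probabilities, cutoff)
    try:
        sumss = sumss_metric(c)
    except UndefinedMetricError:
        sumss = None
    return {
        "cutoff": float(cutoff),
        "tp": c.tp,
        "fn": c.fn,
        "tn": c.tn,
        "fp": c.fp,
        "f1": f1_metric(c),
        "sumss": sumss,
        "precision": precision_metric(c),
        "recall": recall_metric(c),
        "tp_pct": round(100.0 * c.tp / c.n_incorrect, 2) if c.n_incorrect else None,
        "tn_pct": round(100.0 * c.tn / c.n_correct, 2) if c.n_correct else None,
    }


def evaluate_classifier(classifier, matrix, cutoff: float) -> dict:
    """Evaluate a trained classifier on an encoded matrix at a cutoff."""
    probs = classifier.predict_incorrect_probability(matrix)
    return evaluate(matrix.y, probs, cutoff)
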