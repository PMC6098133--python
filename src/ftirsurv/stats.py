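"""ROC analysis, cost-weighted cutoff selection and rank-based tests.

The dichotomisation rule for each spectral feature is chosen from the ROC
curve by minimising the expected misclassification cost

    cost(t) = C_FN * w_pos * (1 - Se(t)) + C_FP * w_neg * (1 - Sp(t)),

with the false-negative penalty ``C_FN = cost_ratio`` times the
false-positive penalty (default ratio 2: missing a poor-prognosis patient is
twice as costly as over-calling one).  With prevalence weighting on, the
class weights are the observed class counts; with it off, both weights are
equal and the criterion reduces (up to an affine rescaling) to the
cost-tilted Youden index J_c = Se + Sp/c, and at c = 1 to the classic Youden
J = Se + Sp - 1.

ROC construction and AUC are implemented directly — thresholds are the
distinct observed scores plus infinite sentinels, sensitivity and
specificity are exact fractions, and the trapezoid AUC provably equals the
tie-adjusted rank (Mann-Whitney) formulation, which the test suite verifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "CutoffSpec",
    "roc_curve",
    "rank_auc",
    "select_cutoff",
    "dichotomize",
    "dichotomize_values",
    "mann_whitney",
    "spearman",
]

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"


@dataclass(frozen=True)
class ROCResult:
    """An ROC curve: thresholds with exact Se/Sp fractions plus the AUC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str
    n_positive: int
    n_negative: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class CutoffSpec:
    """A dichotomisation rule: ``feature >= threshold`` or ``feature < threshold``.

    ``direction`` is ``"ge"`` (value >= threshold is positive, boundary
    included) or ``"lt"`` (value < threshold is positive, boundary excluded).
    """

    feature: str
    threshold: float
    direction: str
    cost_ratio: float = 2.0
    prevalence_weighting: bool = True
    auc: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    expected_cost: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("ge", "lt"):
            raise ValueError(f"direction must be 'ge' or 'lt', got {self.direction!r}")
        if self.cost_ratio <= 0:
            raise ValueError("cost_ratio must be positive")

    def rule_text(self) -> str:
        op = ">=" if self.direction == "ge" else "<"
        return f"{self.feature} {op} {self.threshold:g} cm^-1"

    def classify(self, value: float) -> int:
        if self.direction == "ge":
            return int(value >= self.threshold)
        return int(value < self.threshold)


def _validate_binary(labels: np.ndarray) -> None:
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got values {sorted(uniq)}")


def roc_curve(
    scores: Sequence[float], labels: Sequence[int], orientation: str = HIGHER
) -> ROCResult:
    """Build the ROC curve over all attainable thresholds.

    ``orientation`` states which tail of the score is classified positive:
    with ``higher_is_positive`` the candidate rules are ``score >= t``; with
    ``lower_is_positive`` they are ``score < t``.  Thresholds run through all
    distinct observed scores plus -inf/+inf sentinels so both trivial
    classifiers (nobody / everybody positive) appear and the curve spans
    (0, 1) to (1, 0) in (1 - Sp, Se) space.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    if np.isnan(scores).any():
        raise ValueError("missing scores must be dropped (with logging) upstream")
    _validate_binary(labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes non-empty")
    if orientation not in (HIGHER, LOWER):
        raise ValueError(f"unknown orientation {orientation!r}")

    candidates = np.concatenate(([-np.inf], np.unique(scores), [np.inf]))
    se = np.empty(candidates.size)
    sp = np.empty(candidates.size)
    for k, t in enumerate(candidates):
        pred = scores >= t if orientation == HIGHER else scores < t
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        se[k] = tp / n_pos
        sp[k] = tn / n_neg

    # trapezoid AUC over the curve sorted by false-positive rate
    fpr = 1.0 - sp
    order = np.lexsort((se, fpr))
    auc = float(np.trapezoid(se[order], fpr[order]))
    return ROCResult(
        thresholds=candidates,
        sensitivity=se,
        specificity=sp,
        auc=auc,
        orientation=orientation,
        n_positive=n_pos,
        n_negative=n_neg,
        scores=scores,
        labels=labels,
    )


def rank_auc(
    scores: Sequence[float], labels: Sequence[int], orientation: str = HIGHER
) -> float:
    """Tie-adjusted rank (Mann-Whitney) formulation of the AUC.

    Probability that a random positive outscores a random negative in the
    positive direction, with half credit for ties.  Used as the independent
    cross-check of the trapezoid AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    oriented = scores if orientation == HIGHER else -scores
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("rank AUC requires both classes non-empty")
    greater = np.sum(pos[:, None] > neg[None, :])
    ties = np.sum(pos[:, None] == neg[None, :])
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def select_cutoff(
    roc: ROCResult,
    cost_ratio: float = 2.0,
    prevalence_weighting: bool = True,
    feature: str = "score",
) -> CutoffSpec:
    """Pick the threshold minimising expected misclassification cost.

    Ties among cost-minimising thresholds are broken toward higher
    sensitivity, then toward the lower threshold.  The reported threshold is
    an attainable boundary: the smallest score classified positive for a
    ``>=`` rule, the smallest score classified negative for a ``<`` rule, so
    the printed rule reproduces the classification exactly.
    """
    if cost_ratio <= 0:
        raise ValueError("cost_ratio must be positive")
    w_pos = roc.n_positive if prevalence_weighting else 1.0
    w_neg = roc.n_negative if prevalence_weighting else 1.0
    cost = cost_ratio * w_pos * (1.0 - roc.sensitivity) + w_neg * (1.0 - roc.specificity)

    best = None
    for k in range(roc.thresholds.size):
        key = (cost[k], -roc.sensitivity[k], roc.thresholds[k])
        if best is None or key < best[0]:
            best = (key, k)
    k = best[1]
    t_raw = roc.thresholds[k]

    # report an attainable boundary value
    scores = roc.scores
    if roc.orientation == HIGHER:
        positive = scores[scores >= t_raw]
        threshold = float(positive.min()) if positive.size else float("inf")
        direction = "ge"
    else:
        negative = scores[scores >= t_raw]
        threshold = float(negative.min()) if negative.size else float("inf")
        direction = "lt"

    return CutoffSpec(
        feature=feature,
        threshold=threshold,
        direction=direction,
        cost_ratio=cost_ratio,
        prevalence_weighting=prevalence_weighting,
        auc=roc.auc,
        sensitivity=float(roc.sensitivity[k]),
        specificity=float(roc.specificity[k]),
        expected_cost=float(cost[k]),
    )


def dichotomize_values(
    values: Sequence[float | None], spec: CutoffSpec
) -> list[int | None]:
    """Apply a cutoff rule to feature values; None/NaN propagates to None."""
    out: list[int | None] = []
    n_missing = 0
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out.append(None)
            n_missing += 1
        else:
            out.append(spec.classify(float(v)))
    if n_missing:
        logger.info(
            "dichotomize %s: %d of %d values missing, excluded downstream",
            spec.feature,
            n_missing,
            len(out),
        )
    return out


def dichotomize(features: Sequence, spec: CutoffSpec) -> dict[str, int | None]:
    """Apply a cutoff rule to per-patient spectral features.

    Returns a mapping patient_id -> 1 (high-risk), 0 (low-risk) or None when
    the feature is missing for that patient.
    """
    values = [f.get(spec.feature) for f in features]
    labels = dichotomize_values(values, spec)
    return {f.patient_id: lab for f, lab in zip(features, labels)}


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    U is computed from midranks.  The p-value is exact (enumeration over
    label arrangements) when there are no ties and the number of
    arrangements C(n_x + n_y, n_x) does not exceed 1e5; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires both samples non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    exact = not has_ties and comb(x.size + y.size, x.size) <= 100_000
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples differ in length")
    if x.size < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance: a sample is constant")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
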