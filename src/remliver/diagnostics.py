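"""Diagnostic-test evaluation: confusion matrices, ROC-AUC, rank tests.

Includes an exhaustive integer reconstruction of a 2x2 confusion matrix
from published summary metrics: given the class sizes and one to four
metrics printed at two decimals, it enumerates every (tp, tn) pair and
returns the matrix whose metrics round back to the printed values.  This
turns a published performance table into a checkable object and surfaces
rounding inconsistencies instead of absorbing them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "RankTestResult",
    "ReconstructionResult",
    "confusion",
    "metrics",
    "round_half_up",
    "reconstruct_confusion",
    "rounding_mismatches",
    "roc_auc",
    "mann_whitney",
]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2x2 outcome of a binary classifier against a reference."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five 2x2 summary metrics plus an optional AUC.

    A metric with a zero denominator is ``None`` (not available), never 0.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES + ("auc",)}


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U statistic and two-sided p-value."""

    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal-approximation"


@dataclass(frozen=True)
class ReconstructionResult:
    """Outcome of an exhaustive confusion-matrix reconstruction."""

    matrix: ConfusionMatrix
    unique: bool
    n_candidates: int
    candidates: tuple[ConfusionMatrix, ...] = field(repr=False, default=())


def confusion(predicted: Sequence[bool], reference: Sequence[bool]) -> ConfusionMatrix:
    """Tabulate predictions against a boolean reference standard."""
    pred = np.asarray(predicted, dtype=bool)
    ref = np.asarray(reference, dtype=bool)
    if pred.shape != ref.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("predicted and reference must be equal-length, non-empty 1-D")
    return ConfusionMatrix(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        tn=int(np.sum(~pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricSet:
    """Sensitivity, specificity, PPV, NPV and accuracy of a 2x2 matrix."""
    return MetricSet(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        auc=auc,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (publication style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def reconstruct_confusion(
    n_pos: int,
    n_neg: int,
    anchors: Mapping[str, float],
    ndigits: int = 2,
) -> ReconstructionResult:
    """Recover the integer confusion matrix behind printed summary metrics.

    Enumerates all (tp, tn) with 0 <= tp <= ``n_pos`` and 0 <= tn <=
    ``n_neg`` and keeps the matrices whose anchored metrics round
    (half-up, ``ndigits`` decimals) to the anchor values.  If several
    qualify, the one with the smallest summed squared deviation from the
    anchors is returned and ``unique`` is False.

    Raises
    ------
    ValueError
        If no matrix reproduces the anchors; the message names the nearest
        candidate.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be at least 1")
    anchors = dict(anchors)
    if not 1 <= len(anchors) <= 4:
        raise ValueError("provide between 1 and 4 anchors")
    unknown = set(anchors) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown anchor metrics: {sorted(unknown)}")

    qualifiers: list[tuple[float, ConfusionMatrix]] = []
    best_any: tuple[float, ConfusionMatrix] | None = None
    for tp, tn in itertools.product(range(n_pos + 1), range(n_neg + 1)):
        cm = ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
        m = metrics(cm).as_dict()
        dev = 0.0
        ok = True
        for name, target in anchors.items():
            value = m[name]
            if value is None:
                ok = False
                dev = math.inf
                break
            dev += (value - target) ** 2
            if round_half_up(value, ndigits) != round(target, ndigits):
                ok = False
        if ok:
            qualifiers.append((dev, cm))
        if best_any is None or dev < best_any[0]:
            best_any = (dev, cm)

    if not qualifiers:
        assert best_any is not None
        raise ValueError(
            "no confusion matrix reproduces the anchors "
            f"{anchors}; nearest candidate is {best_any[1]} "
            f"with metrics {metrics(best_any[1]).as_dict()}"
        )
    qualifiers.sort(key=lambda pair: pair[0])
    cms = tuple(cm for _, cm in qualifiers)
    return ReconstructionResult(
        matrix=cms[0],
        unique=len(cms) == 1,
        n_candidates=len(cms),
        candidates=cms,
    )


def rounding_mismatches(
    m: MetricSet, printed: Mapping[str, float], ndigits: int = 2
) -> dict[str, tuple[float, float]]:
    """Compare computed metrics against printed values at printed precision.

    Returns ``{metric: (computed_rounded, printed)}`` for every metric
    whose half-up rounding disagrees with the printed figure — the honest
    way to surface a publication rounding slip.
    """
    out: dict[str, tuple[float, float]] = {}
    for name, target in printed.items():
        value = m.as_dict()[name]
        if value is None:
            continue
        got = round_half_up(value, ndigits)
        if got != round(target, ndigits):
            out[name] = (got, target)
    return out


def roc_auc(
    scores: Sequence[float],
    reference: Sequence[bool],
    orientation: str = "higher_is_positive",
) -> float:
    """Area under the ROC curve, equal to the concordance probability.

    ``orientation="lower_is_positive"`` handles scores where *low* values
    indicate the positive (diseased) class — the natural direction for
    liver-function scores, where low function means dysfunction.  The flag
    is mandatory thinking: passing the wrong orientation silently inverts
    the AUC around 0.5.
    """
    if orientation not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(reference, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and reference must be equal-length 1-D")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute an AUC")
    if orientation == "lower_is_positive":
        s = -s
    return float(roc_auc_score(y, s))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of group a via midranks (ties contribute half a pair)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[: a.size].sum())
    return r1 - a.size * (a.size + 1) / 2.0


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> RankTestResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    The null distribution is enumerated exactly over all assignments of
    the pooled values to the two groups when the combined sample size is
    at most 12; beyond that a normal approximation with tie and continuity
    corrections is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= 12:
        pooled = np.concatenate([a, b])
        idx = range(n1 + n2)
        d_obs = abs(u_obs - mu)
        hits = total = 0
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                hits += 1
        return RankTestResult(u_statistic=u_obs, p_value=hits / total, method="exact")

    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # every value tied
        return RankTestResult(u_statistic=u_obs, p_value=1.0,
                              method="normal-approximation")
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return RankTestResult(u_statistic=u_obs, p_value=float(p),
                          method="normal-approximation")
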