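"""Survival analysis: univariable Cox regression and Kaplan-Meier curves.

The Cox fit maximises the Breslow partial likelihood for a single
untransformed covariate by Newton-Raphson with analytic gradient and
Hessian; the standard error comes from the observed information.  The
hazard ratio is therefore per unit of the covariate — for erLF, per
%/min of estimated remnant function, so an HR below 1 means better
predicted remnant function lowers the death hazard.

Breslow tie handling is the fixed choice here; with the near-continuous
covariates this package produces, ties are rare and the Breslow/Efron
difference is negligible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "KMCurve",
    "cox_univariable",
    "kaplan_meier",
    "km_by_class",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up time in days and whether death was observed."""

    time: float
    event: bool

    def __post_init__(self):
        if not (math.isfinite(self.time) and self.time > 0):
            raise ValueError("time must be finite and positive")


@dataclass(frozen=True)
class CoxFit:
    """Univariable Cox estimate: log-hazard, Wald inference, HR with 95% CI."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve over the event-time grid of one stratum.

    ``times`` are the distinct event (death) times in ascending order,
    ``survival`` the estimate S(t) just after each, ``at_risk`` the number
    at risk just before.  S(0) = 1 and the curve is constant between event
    times.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        """S(t): step-function evaluation (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _partial_likelihood_terms(
    beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray
):
    """Breslow log-likelihood, gradient and Hessian for one covariate."""
    order = np.argsort(times, kind="stable")
    t, d, xv = times[order], events[order], x[order]
    w = np.exp(beta * xv)
    # risk set at time t = subjects with time >= t; reverse cumulative sums
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    s2 = np.cumsum((w * xv * xv)[::-1])[::-1]
    # ties share the risk set of the first record at that time
    first = np.searchsorted(t, t, side="left")
    ev = d.astype(bool)
    f = first[ev]
    ll = float(np.sum(beta * xv[ev] - np.log(s0[f])))
    grad = float(np.sum(xv[ev] - s1[f] / s0[f]))
    hess = float(-np.sum(s2[f] / s0[f] - (s1[f] / s0[f]) ** 2))
    return ll, grad, hess


def cox_univariable(
    records: Sequence[SurvivalRecord],
    covariate: Sequence[float],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a univariable Cox proportional-hazards model.

    Newton-Raphson on the Breslow partial likelihood, starting at beta = 0,
    converging when the step falls below ``tol``.  The covariate enters
    untransformed, so ``hr`` is the hazard ratio per covariate unit.

    Raises
    ------
    ValueError
        Fewer than 2 events, zero covariate variance, or length mismatch.
    RuntimeError
        Newton iteration failed to converge within ``max_iter`` steps.
    """
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    x = np.asarray(covariate, dtype=float)
    if x.shape != times.shape:
        raise ValueError("covariate length must match the number of records")
    n_events = int(events.sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events, got {n_events}")
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance; hazard ratio undefined")
    # center for numerical stability; beta is translation-invariant
    xc = x - x.mean()

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, grad, hess = _partial_likelihood_terms(beta, times, events, xc)
        if hess >= 0:
            raise RuntimeError("non-concave point in partial likelihood")
        step = grad / hess
        beta -= step
        if abs(step) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(last beta {beta:.6g})"
        )
    _, _, hess = _partial_likelihood_terms(beta, times, events, xc)
    se = math.sqrt(-1.0 / hess)
    z = 1.959963984540054  # two-sided 95% normal quantile
    return CoxFit(
        beta=beta,
        se=se,
        hr=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p_value=float(2.0 * stats.norm.sf(abs(beta) / se)),
        n_events=n_events,
        converged=converged,
    )


def kaplan_meier(records: Sequence[SurvivalRecord], label: str = "") -> KMCurve:
    """Product-limit survival estimate.

    Censored observations leave the risk set without producing a step; at
    each distinct death time S is multiplied by (1 - d/n).
    """
    if len(records) == 0:
        raise ValueError("no records")
    times = np.asarray([r.time for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    event_times = np.unique(times[events])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    # exact rational product so that, without censoring, the telescoping
    # identity S(t) = #{times > t}/n holds bit-exactly in the float output
    s = Fraction(1)
    for i, t in enumerate(event_times):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum(events & (times == t)))
        s *= Fraction(n_at_risk - d, n_at_risk)
        surv[i] = float(s)
        at_risk[i] = n_at_risk
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk, label=label)


def km_by_class(
    records: Sequence[SurvivalRecord], classes: Sequence
) -> Mapping[str, KMCurve]:
    """One Kaplan-Meier curve per stratum label.

    Strata with no members are omitted with a warning rather than
    producing an empty curve.
    """
    if len(records) == 0:
        raise ValueError("no records")
    if len(classes) != len(records):
        raise ValueError("classes must align with records")
    labels = [str(getattr(c, "value", c)) for c in classes]
    curves: dict[str, KMCurve] = {}
    for label in dict.fromkeys(labels):  # preserve first-seen order
        members = [r for r, l in zip(records, labels) if l == label]
        if not members:
            warnings.warn(f"empty stratum {label!r} omitted", stacklevel=2)
            continue
        curves[label] = kaplan_meier(members, label=label)
    return curves
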