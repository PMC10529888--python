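"""Indocyanine green (ICG) clearance kinetics and patient classification.

ICG is a dye cleared exclusively by hepatocytes; the plasma disappearance
rate (PDR, %/min) and the 15-minute retention fraction (R15, %) are the
established bedside measures of global liver function.  A bolus dose decays
monoexponentially, so both quantities follow from a log-linear fit of the
concentration curve with backward extrapolation to the injection time.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "IcgCurve",
    "PdrResult",
    "IcgClassRule",
    "PreopClass",
    "PostopClass",
    "fit_monoexponential",
    "classify_preop",
    "classify_postop",
]


class PreopClass(str, Enum):
    """Preoperative liver-function class from the ICG test."""

    NLF = "NLF"
    LDF = "LDF"


class PostopClass(str, Enum):
    """Postoperative liver-function class (three-level)."""

    PNLF = "PNLF"
    AT_RISK = "at_risk"
    PLDF = "PLDF"


@dataclass(frozen=True)
class IcgCurve:
    """A sampled ICG concentration curve.

    Parameters
    ----------
    times
        Sampling times in minutes, non-negative and strictly increasing.
    concentrations
        Plasma ICG concentrations in mg/L, strictly positive.
    """

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("times and concentrations must be 1-D and of equal length")
        if t.size == 0:
            raise ValueError("empty ICG curve")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PdrResult:
    """Fitted monoexponential clearance parameters.

    ``pdr`` is the plasma disappearance rate in %/min (100 times the decay
    constant ``decay_k``), ``r15`` the modelled percentage of dye remaining
    at 15 minutes, and ``c0`` the back-extrapolated initial concentration.
    """

    pdr: float
    r15: float
    c0: float
    decay_k: float


@dataclass(frozen=True)
class IcgClassRule:
    """Clinical cut-offs for ICG-based liver-function classes.

    Preoperatively a PDR below ``preop_pdr_cutoff`` (%/min) *or* an R15
    above ``preop_r15_cutoff`` (%) flags liver dysfunction (LDF).
    Postoperatively the three-level partition is PLDF below
    ``postop_lower``, PNLF above ``postop_upper``, and "at risk" on the
    closed interval in between.
    """

    preop_pdr_cutoff: float = 17.0
    preop_r15_cutoff: float = 8.0
    postop_lower: float = 10.0
    postop_upper: float = 17.0

    def __post_init__(self):
        if not self.postop_lower < self.postop_upper:
            raise ValueError("postop_lower must be below postop_upper")


DEFAULT_RULE = IcgClassRule()


def fit_monoexponential(curve: IcgCurve) -> PdrResult:
    """Fit a monoexponential decay to an ICG concentration curve.

    Ordinary least squares on log-concentration versus time gives the decay
    constant (negative slope) and the back-extrapolated initial
    concentration (intercept).  PDR is 100 times the decay constant,
    clamped at zero when the fitted slope is non-negative; R15 is the
    modelled retention ``100 * exp(-15 k)``.

    Raises
    ------
    ValueError
        If the curve has fewer than 3 samples or any non-positive
        concentration.
    """
    if len(curve) < 3:
        raise ValueError("monoexponential fit needs at least 3 samples")
    if np.any(curve.concentrations <= 0):
        raise ValueError("concentrations must be positive for a log-linear fit")
    slope, intercept = np.polyfit(curve.times, np.log(curve.concentrations), 1)
    k = max(-float(slope), 0.0)
    return PdrResult(
        pdr=100.0 * k,
        r15=100.0 * float(np.exp(-15.0 * k)),
        c0=float(np.exp(intercept)),
        decay_k=k,
    )


def classify_preop(pdr: float, r15: float, rule: IcgClassRule = DEFAULT_RULE) -> PreopClass:
    """Classify preoperative liver function from ICG measurements.

    LDF if PDR is strictly below the PDR cut-off *or* R15 strictly above
    the R15 cut-off; NLF otherwise.  Boundary values count as NLF because
    both inequalities are strict.
    """
    if not (np.isfinite(pdr) and np.isfinite(r15)):
        raise ValueError("pdr and r15 must be finite")
    if pdr < 0 or r15 < 0:
        raise ValueError("pdr and r15 must be non-negative")
    if pdr < rule.preop_pdr_cutoff or r15 > rule.preop_r15_cutoff:
        return PreopClass.LDF
    return PreopClass.NLF


def classify_postop(pdr: float, rule: IcgClassRule = DEFAULT_RULE) -> PostopClass:
    """Classify postoperative liver function from the postoperative PDR.

    PLDF strictly below ``postop_lower``, PNLF strictly above
    ``postop_upper``; values on the closed interval [lower, upper] are "at
    risk".
    """
    if not np.isfinite(pdr):
        raise ValueError("pdr must be finite")
    if pdr < 0:
        raise ValueError("pdr must be non-negative")
    if pdr < rule.postop_lower:
        return PostopClass.PLDF
    if pdr > rule.postop_upper:
        return PostopClass.PNLF
    return PostopClass.AT_RISK
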