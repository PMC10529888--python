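"""Volume-assisted estimation of (remnant) liver function from T1 relaxometry.

Gadoxetic acid (Gd-EOB-DTPA) is taken up by functioning hepatocytes and
shortens the T1 relaxation time of liver tissue.  The percent shortening
between the pre-contrast map (T1plain) and the hepatobiliary-phase map
(T1HBP) — the reduction rate RR — is a per-tissue surrogate of hepatocyte
function.  Combining RR with the functional liver volume gives an estimate
of global liver function on the scale of the ICG plasma disappearance rate:

    eLF  = scale * exp(a * RR) * exp(b * LV / u)
    erLF = scale * exp(a * RR) * exp(b * rLV / u)

with defaults scale = 0.84 %/min, a = 0.038 per % RR and b = 0.045 per
u = 100 mL of liver.  Substituting the future remnant volume rLV for LV
predicts the *postoperative* function before the knife falls, which is the
quantity that matters for resection planning.

This module also encodes the clinical outcome rules used to grade
post-hepatectomy courses: acute dysfunction (bilirubin or INR rise on
postoperative days 3-7) and severe failure (the 50/50 criterion —
bilirubin > 50 umol/L = 2.92 mg/dL with INR > 1.7 — or peak bilirubin
above 7 mg/dL).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .icg import DEFAULT_RULE, IcgClassRule, PostopClass, classify_postop

__all__ = [
    "T1Pair",
    "ModelCoefficients",
    "FunctionScore",
    "OutcomeRule",
    "OutcomeFlags",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_OUTCOME_RULE",
    "reduction_rate",
    "estimated_function",
    "classify_erlf",
    "clinical_outcome",
    "convert_bilirubin",
]


@dataclass(frozen=True)
class T1Pair:
    """Pre-contrast and hepatobiliary-phase T1 relaxation times in ms."""

    t1_plain: float
    t1_hbp: float

    def __post_init__(self):
        if self.t1_plain <= 0:
            raise ValueError("t1_plain must be positive")
        if self.t1_hbp <= 0:
            raise ValueError("t1_hbp must be positive")


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients of the exponential liver-function model.

    ``vol_coeff`` applies per ``vol_unit_ml`` millilitres of liver; the
    default is 0.045 per 100 mL, which places eLF on the same scale as
    ICG-PDR (a per-mL reading of the published coefficient would blow the
    volume exponent up to ~70 for a normal liver and is dimensionally
    untenable).  The unit is configurable rather than hard-coded.
    """

    scale: float = 0.84
    rr_coeff: float = 0.038
    vol_coeff: float = 0.045
    vol_unit_ml: float = 100.0

    def __post_init__(self):
        for name in ("scale", "rr_coeff", "vol_coeff", "vol_unit_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_COEFFICIENTS = ModelCoefficients()


@dataclass(frozen=True)
class FunctionScore:
    """Derived per-patient function values: RR (%), eLF and erLF (%/min)."""

    rr: float
    elf: float
    erlf: float

    def __post_init__(self):
        for name in ("rr", "elf", "erlf"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.rr > 100:
            raise ValueError("rr cannot exceed 100%")


@dataclass(frozen=True)
class OutcomeRule:
    """Thresholds for postoperative dysfunction and severe failure.

    Acute dysfunction: bilirubin above ``bili_dysfunction_mg_dl`` or INR
    above ``inr_dysfunction``, in each case also above the preoperative
    value, on any postoperative day in the window.  Severe failure: the
    50/50 criterion (bilirubin above ``fifty_fifty_bili_umol_l`` umol/L
    *and* INR above ``fifty_fifty_inr`` on the same day) or bilirubin
    above ``severe_bili_mg_dl``.
    """

    bili_dysfunction_mg_dl: float = 1.0
    inr_dysfunction: float = 1.15
    fifty_fifty_bili_umol_l: float = 50.0
    fifty_fifty_inr: float = 1.7
    severe_bili_mg_dl: float = 7.0
    window_days: tuple[int, int] = (3, 7)
    bilirubin_molar_mass_g_mol: float = 584.66

    def __post_init__(self):
        lo, hi = self.window_days
        if lo > hi:
            raise ValueError("window_days must be a non-empty POD range")


DEFAULT_OUTCOME_RULE = OutcomeRule()


@dataclass(frozen=True)
class OutcomeFlags:
    """Outcome of the clinical grading; severe failure implies dysfunction."""

    acute_dysfunction: bool
    severe_failure: bool

    def __post_init__(self):
        if self.severe_failure and not self.acute_dysfunction:
            raise ValueError("severe_failure implies acute_dysfunction")


def reduction_rate(t1: T1Pair) -> float:
    """Percent T1 shortening from pre-contrast to hepatobiliary phase.

    RR = (T1plain - T1HBP) / T1plain * 100.  A negative RR (post-contrast
    T1 longer than baseline, e.g. from mistimed acquisition) is returned
    with a warning rather than rejected.
    """
    rr = (t1.t1_plain - t1.t1_hbp) / t1.t1_plain * 100.0
    if rr < 0:
        warnings.warn(
            f"negative reduction rate {rr:.2f}% (T1HBP exceeds T1plain); "
            "check contrast timing",
            stacklevel=2,
        )
    return rr


def estimated_function(
    rr: float,
    volume: float,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Exponential liver-function estimate from RR and a liver volume.

    With the total liver volume this is eLF; with the remnant volume it is
    erLF.  Strictly increasing in both arguments.

    Raises
    ------
    ValueError
        If ``volume`` is negative or ``rr`` non-finite.
    """
    if not math.isfinite(rr):
        raise ValueError("rr must be finite")
    if volume < 0:
        raise ValueError("volume must be non-negative")
    return coeffs.scale * math.exp(
        coeffs.rr_coeff * rr + coeffs.vol_coeff * volume / coeffs.vol_unit_ml
    )


def classify_erlf(erlf: float, rule: IcgClassRule = DEFAULT_RULE) -> PostopClass:
    """Three-level dysfunction class of an erLF value.

    Applies the same partition as the postoperative ICG classification
    (PLDF < 10, at-risk 10-17, PNLF > 17), keeping the imaging-based and
    dye-based assessments on one scale.
    """
    return classify_postop(erlf, rule)


def convert_bilirubin(value_umol_l: float, rule: OutcomeRule = DEFAULT_OUTCOME_RULE) -> float:
    """Convert a bilirubin concentration from umol/L to mg/dL.

    mg/dL = umol/L * molar mass (g/mol) * 1e-4; with bilirubin's
    584.66 g/mol, 50 umol/L is 2.92 mg/dL.
    """
    if value_umol_l < 0:
        raise ValueError("concentration must be non-negative")
    return value_umol_l * rule.bilirubin_molar_mass_g_mol * 1e-4


def _window_values(
    series: Iterable[tuple[int, float]], rule: OutcomeRule
) -> dict[int, float]:
    lo, hi = rule.window_days
    out: dict[int, float] = {}
    for pod, value in series:
        pod = int(pod)
        if not 1 <= pod <= 90:
            raise ValueError(f"POD {pod} outside the plausible 1-90 range")
        if value <= 0 or not math.isfinite(value):
            raise ValueError(f"non-positive lab value {value} on POD {pod}")
        if lo <= pod <= hi:
            out[pod] = float(value)
    return out


def clinical_outcome(
    preop_bili: float,
    bili_series: Sequence[tuple[int, float]],
    preop_inr: float,
    inr_series: Sequence[tuple[int, float]],
    rule: OutcomeRule = DEFAULT_OUTCOME_RULE,
) -> OutcomeFlags:
    """Grade a postoperative course from bilirubin and INR series.

    ``bili_series`` / ``inr_series`` are (postoperative day, value) pairs;
    bilirubin in mg/dL.  Only days inside the rule's window (default POD
    3-7) are considered.  If the window is entirely uncovered the flags
    are computed on what is available (i.e. remain False) with a warning.
    """
    bili = _window_values(bili_series, rule)
    inr = _window_values(inr_series, rule)
    if not bili and not inr:
        warnings.warn(
            "no lab values inside the POD window; outcome flags computed on "
            "available data only",
            stacklevel=2,
        )
    fifty_fifty_mg_dl = convert_bilirubin(rule.fifty_fifty_bili_umol_l, rule)

    acute = any(
        v > rule.bili_dysfunction_mg_dl and v > preop_bili for v in bili.values()
    ) or any(v > rule.inr_dysfunction and v > preop_inr for v in inr.values())

    severe = any(
        bili[pod] > fifty_fifty_mg_dl and inr[pod] > rule.fifty_fifty_inr
        for pod in bili.keys() & inr.keys()
    ) or any(v > rule.severe_bili_mg_dl for v in bili.values())

    return OutcomeFlags(acute_dysfunction=acute or severe, severe_failure=severe)
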