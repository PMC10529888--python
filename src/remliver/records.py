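"""Per-patient record and cohort containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .function_model import FunctionScore, T1Pair
from .survival import SurvivalRecord
from .volumetry import VolumeSet

__all__ = ["IcgMeasurement", "LabSeries", "PatientRecord", "Cohort"]


@dataclass(frozen=True)
class IcgMeasurement:
    """An ICG test result: PDR in %/min and R15 in percent."""

    pdr: float
    r15: float

    def __post_init__(self):
        if self.pdr < 0:
            raise ValueError("pdr must be non-negative")
        if not 0 <= self.r15 <= 100:
            raise ValueError("r15 must lie in [0, 100]")


@dataclass(frozen=True)
class LabSeries:
    """Preoperative baselines and postoperative-day lab series.

    ``bili`` and ``inr`` map postoperative day -> value; bilirubin in
    mg/dL, INR dimensionless.
    """

    bili_preop: float
    inr_preop: float
    bili: dict[int, float] = field(default_factory=dict)
    inr: dict[int, float] = field(default_factory=dict)

    def bili_items(self) -> list[tuple[int, float]]:
        return sorted(self.bili.items())

    def inr_items(self) -> list[tuple[int, float]]:
        return sorted(self.inr.items())


@dataclass
class PatientRecord:
    """One subject's imaging, volumetric, ICG, lab and survival data.

    ``derived`` holds the pipeline-computed function scores (RR, eLF,
    erLF) and must always be recomputable from the raw fields.
    """

    id: str
    t1: T1Pair
    volumes: VolumeSet
    icg_pre: IcgMeasurement
    icg_post: Optional[IcgMeasurement]
    labs: LabSeries
    survival: SurvivalRecord
    derived: Optional[FunctionScore] = None


@dataclass
class Cohort:
    """An ordered collection of patient records with provenance.

    ``provenance`` is either the generator-parameter mapping that produced
    a synthetic cohort or the string ``"observed"``.
    """

    records: list[PatientRecord]
    provenance: object = "observed"

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("patient identifiers must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)
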