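"""Cohort CSV schema and flat key=value run configuration.

Cohorts travel as one CSV row per patient (schema v1, see
``COHORT_COLUMNS``): T1 times, volumes, pre/postoperative ICG results,
preoperative baselines plus wide lab columns ``bili_pod3..bili_pod7`` /
``inr_pod3..inr_pod7``, and the survival pair.  Missing values are empty
fields; write followed by read is the identity on numeric fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .function_model import (
    DEFAULT_COEFFICIENTS,
    DEFAULT_OUTCOME_RULE,
    ModelCoefficients,
    OutcomeRule,
    T1Pair,
)
from .icg import DEFAULT_RULE, IcgClassRule
from .records import Cohort, IcgMeasurement, LabSeries, PatientRecord
from .survival import SurvivalRecord
from .synthetic import GeneratorParams
from .volumetry import VolumeSet

__all__ = [
    "COHORT_COLUMNS",
    "SCHEMA_HEADER",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "cohort_frame",
    "RunConfig",
]

SCHEMA_HEADER = "# remliver cohort schema v1"

_PODS = range(3, 8)

MANDATORY_COLUMNS = (
    "patient_id",
    "t1_plain_ms",
    "t1_hbp_ms",
    "lv_ml",
    "resected_ml",
    "pdr_pre",
    "r15_pre",
    "bili_preop",
    "inr_preop",
    "survival_days",
    "death_observed",
)

COHORT_COLUMNS = (
    MANDATORY_COLUMNS[:5]
    + ("rlv_ml",)
    + MANDATORY_COLUMNS[5:7]
    + ("pdr_post", "r15_post", "bili_preop")
    + tuple(f"bili_pod{p}" for p in _PODS)
    + ("inr_preop",)
    + tuple(f"inr_pod{p}" for p in _PODS)
    + ("survival_days", "death_observed", "rr_pct", "elf", "erlf")
)
# deduplicate while preserving order
COHORT_COLUMNS = tuple(dict.fromkeys(COHORT_COLUMNS))


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the documented schema."""


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to the schema-v1 DataFrame."""
    rows = []
    for r in cohort:
        row: dict[str, object] = {
            "patient_id": r.id,
            "t1_plain_ms": r.t1.t1_plain,
            "t1_hbp_ms": r.t1.t1_hbp,
            "lv_ml": r.volumes.lv,
            "resected_ml": r.volumes.resected,
            "rlv_ml": r.volumes.rlv,
            "pdr_pre": r.icg_pre.pdr,
            "r15_pre": r.icg_pre.r15,
            "pdr_post": r.icg_post.pdr if r.icg_post else np.nan,
            "r15_post": r.icg_post.r15 if r.icg_post else np.nan,
            "bili_preop": r.labs.bili_preop,
            "inr_preop": r.labs.inr_preop,
            "survival_days": r.survival.time,
            "death_observed": int(r.survival.event),
            "rr_pct": r.derived.rr if r.derived else np.nan,
            "elf": r.derived.elf if r.derived else np.nan,
            "erlf": r.derived.erlf if r.derived else np.nan,
        }
        for p in _PODS:
            row[f"bili_pod{p}"] = r.labs.bili.get(p, np.nan)
            row[f"inr_pod{p}"] = r.labs.inr.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as schema-v1 CSV with a versioned header comment."""
    path = Path(path)
    frame = cohort_frame(cohort)
    with open(path, "w") as fh:
        fh.write(SCHEMA_HEADER + "\n")
        # %.17g round-trips every IEEE double bit-exactly
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_cohort(path) -> Cohort:
    """Read a schema-v1 cohort CSV.

    Raises
    ------
    CohortFormatError
        Missing mandatory columns, non-numeric cells (reported with line
        numbers), or duplicate patient identifiers.
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#", dtype={"patient_id": str},
                        float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    numeric_cols = [c for c in frame.columns if c != "patient_id"]
    offenders = []
    for col in numeric_cols:
        raw = frame[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & coerced.isna()
        for i in frame.index[bad]:
            offenders.append(f"line {i + 3}: column {col!r} value {raw[i]!r}")
        frame[col] = coerced
    if offenders:
        raise CohortFormatError("non-numeric cells: " + "; ".join(offenders))

    records = []
    for i, row in frame.iterrows():
        icg_post = None
        if not (pd.isna(row.get("pdr_post")) or pd.isna(row.get("r15_post"))):
            icg_post = IcgMeasurement(pdr=row["pdr_post"], r15=row["r15_post"])
        lv, resected = row["lv_ml"], row["resected_ml"]
        rlv = row.get("rlv_ml")
        if rlv is None or pd.isna(rlv):
            rlv = lv - resected
        derived = None
        labs = LabSeries(
            bili_preop=row["bili_preop"],
            inr_preop=row["inr_preop"],
            bili={
                p: float(row[f"bili_pod{p}"])
                for p in _PODS
                if f"bili_pod{p}" in frame.columns and not pd.isna(row[f"bili_pod{p}"])
            },
            inr={
                p: float(row[f"inr_pod{p}"])
                for p in _PODS
                if f"inr_pod{p}" in frame.columns and not pd.isna(row[f"inr_pod{p}"])
            },
        )
        records.append(
            PatientRecord(
                id=str(row["patient_id"]),
                t1=T1Pair(t1_plain=row["t1_plain_ms"], t1_hbp=row["t1_hbp_ms"]),
                volumes=VolumeSet(lv=lv, resected=resected, rlv=rlv),
                icg_pre=IcgMeasurement(pdr=row["pdr_pre"], r15=row["r15_pre"]),
                icg_post=icg_post,
                labs=labs,
                survival=SurvivalRecord(
                    time=row["survival_days"], event=bool(row["death_observed"])
                ),
                derived=derived,
            )
        )
    return Cohort(records=records, provenance="observed")


# --------------------------------------------------------------------------
# Run configuration: flat key=value file
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through a flat
    ``key = value`` file (``#`` starts a comment)."""

    coefficients: ModelCoefficients = field(default_factory=lambda: DEFAULT_COEFFICIENTS)
    class_rule: IcgClassRule = field(default_factory=lambda: DEFAULT_RULE)
    outcome_rule: OutcomeRule = field(default_factory=lambda: DEFAULT_OUTCOME_RULE)
    generator: Optional[GeneratorParams] = None
    cohort_path: Optional[str] = None
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def to_file(self, path) -> None:
        lines = ["# remliver run configuration"]

        def put(key, value):
            lines.append(f"{key} = {value!r}" if isinstance(value, str) else
                         f"{key} = {value}")

        put("seed", self.seed)
        put("log_level", self.log_level)
        if self.cohort_path is not None:
            put("cohort_path", self.cohort_path)
        if self.output_dir is not None:
            put("output_dir", self.output_dir)
        c = self.coefficients
        for k in ("scale", "rr_coeff", "vol_coeff", "vol_unit_ml"):
            put(f"model.{k}", getattr(c, k))
        r = self.class_rule
        for k in ("preop_pdr_cutoff", "preop_r15_cutoff", "postop_lower",
                  "postop_upper"):
            put(f"rule.{k}", getattr(r, k))
        o = self.outcome_rule
        for k in ("bili_dysfunction_mg_dl", "inr_dysfunction",
                  "fifty_fifty_bili_umol_l", "fifty_fifty_inr",
                  "severe_bili_mg_dl", "bilirubin_molar_mass_g_mol"):
            put(f"outcome.{k}", getattr(o, k))
        put("outcome.window_lo", o.window_days[0])
        put("outcome.window_hi", o.window_days[1])
        if self.generator is not None:
            g = self.generator
            put("gen.enabled", True)
            for k in ("n", "t1_plain_mean", "t1_plain_sd", "rr_mean_nlf",
                      "rr_mean_ldf", "rr_sd", "lv_mean", "lv_sd",
                      "ldf_fraction", "pdr_link_noise_sd",
                      "survival_log_hazard_per_erlf", "baseline_hazard_per_day",
                      "censor_rate", "followup_cap_days", "lab_noise_sd",
                      "seed"):
                put(f"gen.{k}", getattr(g, k))
            put(
                "gen.resection_fractions",
                ",".join(f"{lab}:{f}:{w}" for lab, f, w in g.resection_fractions),
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()

        def pop(prefix):
            keys = [k for k in kv if k.startswith(prefix + ".")]
            return {k[len(prefix) + 1:]: kv.pop(k) for k in keys}

        def conv(v: str):
            if v.startswith(("'", '"')) and v.endswith(("'", '"')):
                return v[1:-1]
            if v in ("True", "False"):
                return v == "True"
            try:
                return int(v)
            except ValueError:
                return float(v)

        model = {k: conv(v) for k, v in pop("model").items()}
        rule = {k: conv(v) for k, v in pop("rule").items()}
        outcome = {k: conv(v) for k, v in pop("outcome").items()}
        gen = {k: conv(v) for k, v in pop("gen").items()}

        coefficients = replace(DEFAULT_COEFFICIENTS, **model)
        class_rule = replace(DEFAULT_RULE, **rule)
        window = (outcome.pop("window_lo", 3), outcome.pop("window_hi", 7))
        outcome_rule = replace(
            DEFAULT_OUTCOME_RULE, window_days=(int(window[0]), int(window[1])),
            **outcome,
        )
        generator = None
        if gen.pop("enabled", False):
            rf = gen.pop("resection_fractions", None)
            if rf:
                parts = []
                for item in rf.split(","):
                    lab, f, w = item.split(":")
                    parts.append((lab, float(f), float(w)))
                gen["resection_fractions"] = tuple(parts)
            gen["n"] = int(gen.get("n", 71))
            gen["seed"] = int(gen.get("seed", 0))
            generator = replace(
                GeneratorParams(coefficients=coefficients), **gen
            )
        cfg = cls(
            coefficients=coefficients,
            class_rule=class_rule,
            outcome_rule=outcome_rule,
            generator=generator,
            cohort_path=conv(kv.pop("cohort_path")) if "cohort_path" in kv else None,
            output_dir=conv(kv.pop("output_dir")) if "output_dir" in kv else None,
            seed=int(kv.pop("seed", 0)),
            log_level=str(conv(kv.pop("log_level", "'INFO'"))),
        )
        if kv:
            raise ValueError(f"unknown configuration keys: {sorted(kv)}")
        return cfg

    def __post_init__(self):
        if not math.isfinite(self.seed):
            raise ValueError("seed must be finite")
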