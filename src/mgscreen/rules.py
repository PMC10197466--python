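"""Suspicion-parameter rules for monoclonal gammopathy (MG) screening.

This module turns raw laboratory values into the six boolean suspicion
flags used by the triage algorithm — hyperproteinemia, hypercalcemia,
anemia, renal function deterioration, immunoparesis, and bone
involvement — and interprets the serum free light chain (FLC) kappa/lambda
ratio, widening its reference interval in renal impairment.

All cutoffs are strict inequalities: a value sitting exactly on a cutoff
is normal. Units are fixed (calcium, hemoglobin and total protein in
per-dL units; immunoglobulins in g/L; free light chains in mg/L; eGFR in
mL/min/1.73 m²); readers do not convert between unit systems.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .errors import InvalidConfigError, InvalidInputError, MissingAnalyteError

__all__ = [
    "ReferenceRanges",
    "PatientRecord",
    "AlterationProfile",
    "ALTERATION_NAMES",
    "compute_mdrd4",
    "flc_ratio_positive",
    "flag_alterations",
]

#: Canonical order of the six suspicion parameters.
ALTERATION_NAMES = (
    "hyperproteinemia",
    "hypercalcemia",
    "anemia",
    "renal",
    "immunoparesis",
    "bone",
)

ASSAYS = ("SPEP", "SIFE", "UIFE", "SFLCA")
TRUTH_LABELS = ("none", "MM", "AL", "SP", "MGUS")


@dataclass(frozen=True)
class ReferenceRanges:
    """Cutoffs and reference intervals for the six suspicion parameters.

    Defaults are the manufacturer reference ranges of the originating
    laboratory: Ca > 10.2 mg/dL, Cr > 1.8 mg/dL or eGFR < 60,
    Hb < 12 g/dL (women) / < 13 g/dL (men), TP > 8.7 g/dL,
    IgG < 7 / IgA < 0.7 / IgM < 0.4 g/L, kappa/lambda ratio outside
    0.26–1.65 (0.37–3.1 when eGFR < 40).
    """

    ca_upper: float = 10.2
    cr_upper: float = 1.8
    egfr_renal_flag_threshold: float = 60.0
    hb_lower_female: float = 12.0
    hb_lower_male: float = 13.0
    tp_upper: float = 8.7
    igg_lower: float = 7.0
    iga_lower: float = 0.7
    igm_lower: float = 0.4
    flc_ratio_normal: tuple[float, float] = (0.26, 1.65)
    flc_ratio_renal: tuple[float, float] = (0.37, 3.1)
    egfr_ratio_switch_threshold: float = 40.0

    def __post_init__(self) -> None:
        for name in ("flc_ratio_normal", "flc_ratio_renal"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidConfigError(f"{name}: lower bound {lo} must be < upper bound {hi}")
        if not self.flc_ratio_renal[1] > self.flc_ratio_normal[1]:
            raise InvalidConfigError(
                "renal FLC ratio interval must extend above the normal interval"
            )
        for name in (
            "ca_upper", "cr_upper", "egfr_renal_flag_threshold", "hb_lower_female",
            "hb_lower_male", "tp_upper", "igg_lower", "iga_lower", "igm_lower",
            "egfr_ratio_switch_threshold",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferenceRanges":
        """Load ranges from a JSON or YAML key-value file.

        Keys missing from the file keep their built-in defaults; unknown
        keys are rejected. Interval fields accept two-element lists.
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidConfigError(f"{path}: expected a mapping of range names to values")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"{path}: unknown range keys: {sorted(unknown)}")
        for key in ("flc_ratio_normal", "flc_ratio_renal"):
            if key in data:
                data[key] = tuple(float(v) for v in data[key])
        return cls(**data)


@dataclass
class PatientRecord:
    """One subject's demographics, laboratory values, and request profile.

    ``None`` marks a genuinely missing optional value and is distinct
    from zero. ``truth_label`` is the gold-standard diagnosis used only
    for evaluation ("none" = confirmed non-MG control; ``None`` =
    unlabelled).
    """

    id: str
    sex: str  # "female" | "male"
    ca: Optional[float] = None  # mg/dL
    cr: Optional[float] = None  # mg/dL
    hb: Optional[float] = None  # g/dL
    tp: Optional[float] = None  # g/dL
    igg: Optional[float] = None  # g/L
    iga: Optional[float] = None  # g/L
    igm: Optional[float] = None  # g/L
    age: Optional[float] = None  # years
    egfr: Optional[float] = None  # mL/min/1.73m²
    flc_kappa: Optional[float] = None  # mg/L
    flc_lambda: Optional[float] = None  # mg/L
    bone_involvement: bool = False
    prior_mg: bool = False
    al_suspicion: bool = False
    requested_tests: frozenset[str] = field(default_factory=frozenset)
    truth_label: Optional[str] = None
    mp_type: Optional[str] = None  # set by the synthetic generator for diseased subjects

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise InvalidInputError(f"record {self.id!r}: sex must be 'female' or 'male'")
        self.requested_tests = frozenset(self.requested_tests)
        bad = self.requested_tests - {"SPEP", "SIFE", "UIFE"}
        if bad:
            raise InvalidInputError(f"record {self.id!r}: unknown requested tests {sorted(bad)}")
        if self.truth_label is not None and self.truth_label not in TRUTH_LABELS:
            raise InvalidInputError(f"record {self.id!r}: unknown truth label {self.truth_label!r}")
        for name in ("ca", "cr", "hb", "tp", "igg", "iga", "igm", "flc_kappa", "flc_lambda"):
            v = getattr(self, name)
            if v is not None and (math.isnan(v) or v < 0):
                raise InvalidInputError(f"record {self.id!r}: {name}={v} must be non-negative")

    @property
    def diseased(self) -> Optional[bool]:
        """True for a confirmed MG diagnosis, False for a control, None if unlabelled."""
        if self.truth_label is None:
            return None
        return self.truth_label != "none"


@dataclass(frozen=True)
class AlterationProfile:
    """The six suspicion flags for one patient."""

    hyperproteinemia: bool
    hypercalcemia: bool
    anemia: bool
    renal: bool
    immunoparesis: bool
    bone: bool

    @property
    def count(self) -> int:
        """Number of altered parameters (0–6)."""
        return sum(getattr(self, name) for name in ALTERATION_NAMES)

    def as_dict(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in ALTERATION_NAMES}


def compute_mdrd4(cr: float, age: float, sex: str, black: bool = False) -> float:
    """Estimate GFR (mL/min/1.73 m²) with the IDMS-traceable 4-variable MDRD formula.

    175 x Cr^-1.154 x age^-0.203, x 0.742 if female, x 1.212 if Black.
    """
    if cr is None or not cr > 0:
        raise InvalidInputError(f"creatinine must be positive, got {cr}")
    if age is None or not age > 0:
        raise InvalidInputError(f"age must be positive, got {age}")
    if sex not in ("female", "male"):
        raise InvalidInputError(f"sex must be 'female' or 'male', got {sex!r}")
    egfr = 175.0 * cr ** (-1.154) * age ** (-0.203)
    if sex == "female":
        egfr *= 0.742
    if black:
        egfr *= 1.212
    return egfr


def flc_ratio_positive(
    kappa: float,
    lam: float,
    egfr: Optional[float],
    ranges: ReferenceRanges = ReferenceRanges(),
) -> bool:
    """Is the free kappa/lambda ratio outside its applicable reference interval?

    The renal interval (default 0.37–3.1) applies when eGFR is below the
    switch threshold (default 40); otherwise the standard interval
    (0.26–1.65) is used. A ratio exactly on an interval bound is normal.
    If eGFR is missing the standard interval is used and a warning is
    emitted.
    """
    if lam is None or not lam > 0:
        raise InvalidInputError(f"flc_lambda must be positive to form a ratio, got {lam}")
    if kappa is None or kappa < 0:
        raise InvalidInputError(f"flc_kappa must be non-negative, got {kappa}")
    if egfr is None:
        warnings.warn(
            "eGFR missing: interpreting kappa/lambda ratio against the standard interval",
            stacklevel=2,
        )
        lo, hi = ranges.flc_ratio_normal
    elif egfr < ranges.egfr_ratio_switch_threshold:
        lo, hi = ranges.flc_ratio_renal
    else:
        lo, hi = ranges.flc_ratio_normal
    ratio = kappa / lam
    return ratio < lo or ratio > hi


def _resolve_egfr(record: PatientRecord) -> Optional[float]:
    if record.egfr is not None:
        return record.egfr
    if record.cr is not None and record.cr > 0 and record.age is not None:
        return compute_mdrd4(record.cr, record.age, record.sex)
    return None


def flag_alterations(
    record: PatientRecord,
    ranges: ReferenceRanges = ReferenceRanges(),
    min_igs_low: int = 1,
) -> AlterationProfile:
    """Evaluate the six suspicion parameters for one patient.

    The renal flag is positive when creatinine exceeds its cutoff OR the
    eGFR (supplied, or computed by MDRD-4 from creatinine/age/sex when
    absent) falls below the flag threshold. Immunoparesis requires at
    least ``min_igs_low`` of IgG/IgA/IgM strictly below their lower
    limits (default 1; set 2 for a stricter two-class rule).
    """
    missing = [
        name for name in ("ca", "cr", "hb", "tp", "igg", "iga", "igm")
        if getattr(record, name) is None
    ]
    egfr = _resolve_egfr(record)
    if record.cr is not None and egfr is None:
        missing.append("egfr")
    if missing:
        raise MissingAnalyteError(record.id, missing)

    hb_lower = ranges.hb_lower_female if record.sex == "female" else ranges.hb_lower_male
    n_igs_low = sum(
        (
            record.igg < ranges.igg_lower,
            record.iga < ranges.iga_lower,
            record.igm < ranges.igm_lower,
        )
    )
    return AlterationProfile(
        hyperproteinemia=record.tp > ranges.tp_upper,
        hypercalcemia=record.ca > ranges.ca_upper,
        anemia=record.hb < hb_lower,
        renal=(record.cr > ranges.cr_upper) or (egfr < ranges.egfr_renal_flag_threshold),
        immunoparesis=n_igs_low >= min_igs_low,
        bone=bool(record.bone_involvement),
    )
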