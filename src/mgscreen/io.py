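"""CSV readers/writers for patient cohorts, assay results and decisions.

The patient schema is one row per subject with columns named exactly as
the :class:`~mgscreen.rules.PatientRecord` fields; an empty cell is a
missing value (distinct from zero). ``requested_tests`` is a
``|``-separated list; assay-result columns (``spep_positive`` etc.) are
optional and empty when the assay was not performed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .rules import AlterationProfile, PatientRecord
from .screening import AssayResults, ScreeningDecision

__all__ = [
    "records_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "decisions_to_frame",
]

_NUMERIC = ("age", "ca", "cr", "egfr", "hb", "tp", "igg", "iga", "igm",
            "flc_kappa", "flc_lambda")
_BOOLS = ("bone_involvement", "prior_mg", "al_suspicion")
_RESULT_COLS = ("spep_positive", "sife_positive", "uife_positive", "flc_ratio_abnormal")


def records_to_frame(
    records: Sequence[PatientRecord],
    results: Optional[Sequence[AssayResults]] = None,
) -> pd.DataFrame:
    """Serialise records (and optional assay results) to a DataFrame."""
    rows = []
    for i, rec in enumerate(records):
        row: dict = {
            "id": rec.id,
            "sex": rec.sex,
            **{k: getattr(rec, k) for k in _NUMERIC},
            **{k: getattr(rec, k) for k in _BOOLS},
            "requested_tests": "|".join(sorted(rec.requested_tests)),
            "truth_label": rec.truth_label,
            "mp_type": rec.mp_type,
        }
        if results is not None:
            res = results[i]
            row.update({k: getattr(res, k) for k in _RESULT_COLS})
        rows.append(row)
    return pd.DataFrame(rows)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value, default: Optional[bool] = None) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return default
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise InvalidInputError(f"cannot parse boolean value {value!r}")


def frame_to_records(
    frame: pd.DataFrame,
) -> tuple[list[PatientRecord], Optional[list[AssayResults]]]:
    """Parse a cohort DataFrame back into records (and results, if present)."""
    required = {"id", "sex"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidInputError(f"cohort table lacks required column(s): {sorted(missing)}")
    have_results = any(c in frame.columns for c in _RESULT_COLS)
    records, results = [], []
    for _, row in frame.iterrows():
        requested = row.get("requested_tests", "")
        if requested is None or (isinstance(requested, float) and np.isnan(requested)):
            requested = ""
        truth = row.get("truth_label")
        if isinstance(truth, float) and np.isnan(truth):
            truth = None
        mp_type = row.get("mp_type")
        if isinstance(mp_type, float) and np.isnan(mp_type):
            mp_type = None
        records.append(
            PatientRecord(
                id=str(row["id"]),
                sex=str(row["sex"]),
                **{k: _opt_float(row.get(k)) for k in _NUMERIC},
                **{k: bool(_opt_bool(row.get(k), default=False)) for k in _BOOLS},
                requested_tests=frozenset(t for t in str(requested).split("|") if t),
                truth_label=truth,
                mp_type=mp_type,
            )
        )
        if have_results:
            results.append(
                AssayResults(**{k: _opt_bool(row.get(k)) for k in _RESULT_COLS})
            )
    return records, (results if have_results else None)


def write_cohort_csv(
    path: str | Path,
    records: Sequence[PatientRecord],
    results: Optional[Sequence[AssayResults]] = None,
) -> None:
    records_to_frame(records, results).to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path,
) -> tuple[list[PatientRecord], Optional[list[AssayResults]]]:
    return frame_to_records(pd.read_csv(path))


def decisions_to_frame(
    records: Sequence[PatientRecord],
    profiles: Sequence[AlterationProfile],
    decisions: Sequence[ScreeningDecision],
) -> pd.DataFrame:
    """Tabulate screening decisions for CSV export."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "count": [p.count for p in profiles],
            "triaged_in": [d.triaged_in for d in decisions],
            "first_line": ["|".join(sorted(d.first_line)) for d in decisions],
            "reflex": ["|".join(sorted(d.reflex)) for d in decisions],
            "final_call": [d.final_call if d.final_call is not None else "pending"
                           for d in decisions],
            "reason": [d.reason for d in decisions],
        }
    )
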