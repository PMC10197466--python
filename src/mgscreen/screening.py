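"""Triage and reflex-testing algorithm for monoclonal gammopathy screening.

The working algorithm triages a patient into the screening pathway when
either (a) serum protein electrophoresis (SPEP) was requested and the
patient shows at least ``threshold`` suspicious alterations (default 2,
the prospectively validated rule), or (b) serum/urine immunofixation
(SIFE/UIFE) was requested for a patient without a previous MG diagnosis.
Triaged-in patients receive SPEP plus the serum free light chain assay
(SFLCA) as first-line tests; immunofixation is performed only as a
reflex, when a first-line test is positive or AL amyloidosis is
suspected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .errors import IncompleteResultsError, InvalidInputError
from .rules import AlterationProfile, PatientRecord

__all__ = [
    "AssayResults",
    "ScreeningDecision",
    "triage",
    "reflex_decision",
    "combo_positive",
    "screen_patient",
]

FIRST_LINE = frozenset({"SPEP", "SFLCA"})
DEFAULT_REFLEX_ASSAYS = frozenset({"SIFE", "UIFE"})

_RESULT_FIELD = {
    "SPEP": "spep_positive",
    "SIFE": "sife_positive",
    "UIFE": "uife_positive",
    "SFLCA": "flc_ratio_abnormal",
}


@dataclass(frozen=True)
class AssayResults:
    """Per-assay positivity for one patient; ``None`` means not performed."""

    spep_positive: Optional[bool] = None
    sife_positive: Optional[bool] = None
    uife_positive: Optional[bool] = None
    flc_ratio_abnormal: Optional[bool] = None

    def result(self, assay: str) -> Optional[bool]:
        try:
            return getattr(self, _RESULT_FIELD[assay])
        except KeyError:
            raise InvalidInputError(f"unknown assay {assay!r}") from None


@dataclass(frozen=True)
class ScreeningDecision:
    """Outcome of triage and, once completed, of the reflex rule.

    ``final_call`` is ``None`` while first-line results are pending for a
    triaged-in patient; :func:`reflex_decision` completes it.
    """

    triaged_in: bool
    first_line: frozenset[str]
    reflex: frozenset[str]
    final_call: Optional[str]  # "screen_negative" | "screen_positive" | "not_triaged"
    reason: str

    def __post_init__(self) -> None:
        if self.reflex and (not self.triaged_in or self.first_line != FIRST_LINE):
            raise InvalidInputError("reflex testing requires a triaged-in first-line panel")


def triage(
    record: PatientRecord,
    profile: AlterationProfile,
    threshold: int = 2,
) -> ScreeningDecision:
    """Apply the entry rule of the screening algorithm.

    Returns a partially filled decision: triaged-in patients get the
    first-line panel {SPEP, SFLCA} and a pending final call; a
    non-triaged SPEP request keeps its physician-ordered SPEP only.
    """
    if threshold < 1:
        raise InvalidInputError(f"triage threshold must be >= 1, got {threshold}")
    spep_route = "SPEP" in record.requested_tests and profile.count >= threshold
    ife_route = (
        bool(record.requested_tests & {"SIFE", "UIFE"}) and not record.prior_mg
    )
    if spep_route or ife_route:
        reason = "count_ge_threshold" if spep_route else "ife_request_no_prior_mg"
        return ScreeningDecision(
            triaged_in=True,
            first_line=FIRST_LINE,
            reflex=frozenset(),
            final_call=None,
            reason=reason,
        )
    if "SPEP" in record.requested_tests:
        reason = "below_threshold"
    elif record.requested_tests:
        reason = "prior_mg"
    else:
        reason = "no_relevant_request"
    return ScreeningDecision(
        triaged_in=False,
        first_line=frozenset({"SPEP"}) if "SPEP" in record.requested_tests else frozenset(),
        reflex=frozenset(),
        final_call="not_triaged",
        reason=reason,
    )


def reflex_decision(
    decision: ScreeningDecision,
    results: AssayResults,
    al_suspicion: bool = False,
    reflex_assays: Iterable[str] = DEFAULT_REFLEX_ASSAYS,
) -> ScreeningDecision:
    """Complete a triaged-in decision from first-line results.

    Immunofixation (the ``reflex_assays`` mask, jointly) is added iff
    SPEP shows a monoclonal band, the FLC ratio is abnormal, or AL
    amyloidosis is suspected. The final call is positive iff a
    first-line assay is positive; an AL suspicion alone triggers reflex
    testing but not a positive screen.
    """
    if not decision.triaged_in:
        return decision
    missing = [a for a in sorted(decision.first_line) if results.result(a) is None]
    if missing:
        raise IncompleteResultsError(
            f"first-line assay result(s) missing: {', '.join(missing)}"
        )
    positive = bool(results.spep_positive or results.flc_ratio_abnormal)
    do_reflex = positive or al_suspicion
    return replace(
        decision,
        reflex=frozenset(reflex_assays) if do_reflex else frozenset(),
        final_call="screen_positive" if positive else "screen_negative",
        reason=decision.reason if not do_reflex else (
            "first_line_positive" if positive else "al_suspicion"
        ),
    )


def combo_positive(results: AssayResults, combo: Iterable[str]) -> bool:
    """Logical OR of assay positivity over ``combo``.

    The empty combination is negative by convention. Every assay in the
    combination must have been performed.
    """
    combo = tuple(combo)
    missing = [a for a in combo if results.result(a) is None]
    if missing:
        raise IncompleteResultsError(f"assay(s) not performed: {', '.join(sorted(missing))}")
    return any(results.result(a) for a in combo)


def screen_patient(
    record: PatientRecord,
    profile: AlterationProfile,
    results: Optional[AssayResults] = None,
    threshold: int = 2,
    reflex_assays: Iterable[str] = DEFAULT_REFLEX_ASSAYS,
) -> ScreeningDecision:
    """Run triage and, when results are available, the reflex rule."""
    decision = triage(record, profile, threshold=threshold)
    if decision.triaged_in and results is not None:
        decision = reflex_decision(
            decision, results, al_suspicion=record.al_suspicion, reflex_assays=reflex_assays
        )
    return decision
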