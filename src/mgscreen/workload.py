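"""Laboratory time model for the monoclonal-protein screening bench.

Projects the daily hands-on hours each assay consumes from monthly
request volumes and per-assay throughputs, and the impact (tests and
hours saved or added) of switching to the SPEP+SFLCA reflex protocol,
under which immunofixation is run only for first-line-positive patients
or on AL suspicion.

Plate assays are modelled with fractional plates (343 requests on
4-sample plates = 85.75 plates): requests arrive steadily and partial
plates carry proportional time. An integer-ceiling batching mode is
available for the pessimistic reading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "AssayThroughput",
    "WorkloadConfig",
    "WorkloadReport",
    "ImpactReport",
    "DEFAULT_THROUGHPUTS",
    "assay_daily_hours",
    "validation_daily_hours",
    "baseline_workload",
    "protocol_impact",
]


@dataclass(frozen=True)
class AssayThroughput:
    """Bench throughput of one assay.

    Exactly one of ``minutes_per_batch`` (with ``batch_size``, for plate
    assays and the free light chain analyser) or ``samples_per_hour``
    (for continuous-throughput electrophoresis) must be set.
    """

    assay: str
    batch_size: Optional[int] = None
    minutes_per_batch: Optional[float] = None
    samples_per_hour: Optional[float] = None

    def __post_init__(self) -> None:
        batched = self.minutes_per_batch is not None
        rated = self.samples_per_hour is not None
        if batched == rated:
            raise InvalidConfigError(
                f"{self.assay}: set exactly one of minutes_per_batch or samples_per_hour"
            )
        if batched:
            if not self.batch_size or self.batch_size <= 0:
                raise InvalidConfigError(f"{self.assay}: batch_size must be positive")
            if self.minutes_per_batch <= 0:
                raise InvalidConfigError(f"{self.assay}: minutes_per_batch must be positive")
        elif self.samples_per_hour <= 0:
            raise InvalidConfigError(f"{self.assay}: samples_per_hour must be positive")

    def hours_for(self, n_tests: float, integer_batches: bool = False) -> float:
        """Bench hours to process ``n_tests`` samples."""
        if n_tests < 0:
            raise InvalidInputError(f"{self.assay}: negative test count {n_tests}")
        if self.samples_per_hour is not None:
            return n_tests / self.samples_per_hour
        batches = n_tests / self.batch_size
        if integer_batches:
            batches = math.ceil(batches)
        return batches * self.minutes_per_batch / 60.0


#: Throughputs of the originating laboratory: immunofixation plates of 4
#: (serum) and 9 (urine) samples at 75 min each, electrophoresis at 80
#: samples/h, and the light-chain analyser at 50 min per 20 samples.
DEFAULT_THROUGHPUTS: dict[str, AssayThroughput] = {
    "SIFE": AssayThroughput("SIFE", batch_size=4, minutes_per_batch=75.0),
    "UIFE": AssayThroughput("UIFE", batch_size=9, minutes_per_batch=75.0),
    "SPEP": AssayThroughput("SPEP", samples_per_hour=80.0),
    "SFLCA": AssayThroughput("SFLCA", batch_size=20, minutes_per_batch=50.0),
}

DEFAULT_VALIDATION_PER_HOUR = 45.0
DEFAULT_WORKING_DAYS = 22.0

# Display precision mirroring the laboratory's own report (decimal places).
_DISPLAY_DIGITS = {"SIFE": 1, "UIFE": 2, "SPEP": 1, "SFLCA": 1, "validation": 0}


def _round_half_away(x: float, digits: int) -> float:
    scaled = x * 10**digits
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / 10**digits


@dataclass(frozen=True)
class WorkloadConfig:
    """Monthly request volumes plus throughput parameters."""

    monthly_requests: Mapping[str, int]
    throughputs: Mapping[str, AssayThroughput] = field(
        default_factory=lambda: dict(DEFAULT_THROUGHPUTS)
    )
    validation_per_hour: float = DEFAULT_VALIDATION_PER_HOUR
    working_days: float = DEFAULT_WORKING_DAYS
    new_patient_fraction: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.working_days <= 0:
            raise InvalidConfigError("working_days must be positive")
        if self.validation_per_hour <= 0:
            raise InvalidConfigError("validation_per_hour must be positive")
        for assay, n in self.monthly_requests.items():
            if n < 0:
                raise InvalidConfigError(f"{assay}: negative monthly request count {n}")
            if assay not in self.throughputs:
                raise InvalidConfigError(f"{assay}: no throughput configured")
        for assay, f in self.new_patient_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise InvalidConfigError(f"{assay}: new-patient fraction {f} outside [0,1]")


@dataclass(frozen=True)
class WorkloadReport:
    """Daily-hours projection; ``displayed_*`` use report rounding."""

    per_assay_hours: dict[str, float]
    validation_hours: float
    total_hours: float  # unrounded sum
    displayed_per_assay: dict[str, float]
    displayed_validation: float
    displayed_total: float  # sum of displayed components


def assay_daily_hours(
    requests: int,
    throughput: AssayThroughput,
    working_days: float = DEFAULT_WORKING_DAYS,
    integer_batches: bool = False,
) -> float:
    """Mean daily bench hours for one assay from its monthly request volume."""
    if working_days <= 0:
        raise InvalidConfigError("working_days must be positive")
    if requests < 0:
        raise InvalidInputError(f"negative request count {requests}")
    return throughput.hours_for(requests, integer_batches=integer_batches) / working_days


def validation_daily_hours(
    total_tests: int,
    rate: float = DEFAULT_VALIDATION_PER_HOUR,
    working_days: float = DEFAULT_WORKING_DAYS,
) -> float:
    """Mean daily hours spent validating results, at ``rate`` tests/hour."""
    if rate <= 0:
        raise InvalidConfigError(f"validation rate must be positive, got {rate}")
    if working_days <= 0:
        raise InvalidConfigError("working_days must be positive")
    if total_tests < 0:
        raise InvalidInputError(f"negative test count {total_tests}")
    return total_tests / rate / working_days


def baseline_workload(
    config: WorkloadConfig, integer_batches: bool = False
) -> WorkloadReport:
    """Project current daily hours for the configured assays plus validation.

    Validation covers the summed monthly requests of all assays. The
    displayed total is the sum of the components as displayed (1-2
    decimal places per assay, integer hours for validation), mirroring
    the laboratory report format; the unrounded total is also carried.
    """
    missing = {"SPEP", "SIFE", "UIFE"} - set(config.monthly_requests)
    if missing:
        raise InvalidConfigError(f"monthly request volume missing for {sorted(missing)}")
    per_assay = {
        assay: assay_daily_hours(
            n, config.throughputs[assay], config.working_days, integer_batches
        )
        for assay, n in config.monthly_requests.items()
    }
    validation = validation_daily_hours(
        sum(config.monthly_requests.values()), config.validation_per_hour, config.working_days
    )
    displayed = {
        assay: _round_half_away(h, _DISPLAY_DIGITS.get(assay, 1))
        for assay, h in per_assay.items()
    }
    displayed_validation = _round_half_away(validation, _DISPLAY_DIGITS["validation"])
    return WorkloadReport(
        per_assay_hours=per_assay,
        validation_hours=validation,
        total_hours=sum(per_assay.values()) + validation,
        displayed_per_assay=displayed,
        displayed_validation=displayed_validation,
        displayed_total=round(sum(displayed.values()) + displayed_validation, 10),
    )


@dataclass(frozen=True)
class ImpactReport:
    """Projected change from adopting the SPEP+SFLCA reflex protocol.

    Deltas are (tests performed under the new protocol) - (requests
    received), with bench and validation hours over the same period
    derived from the per-assay throughputs.
    """

    tests_received: dict[str, int]
    tests_performed: dict[str, int]
    tests_delta: dict[str, int]
    bench_hours_delta: dict[str, float]
    validation_hours_delta: dict[str, float]
    total_tests_delta: int
    total_bench_hours_delta: float
    total_validation_hours_delta: float


def protocol_impact(
    received: Mapping[str, int],
    n_screened: int,
    n_first_line_positive: int,
    n_al_suspicion: int = 0,
    throughputs: Mapping[str, AssayThroughput] = DEFAULT_THROUGHPUTS,
    validation_per_hour: float = DEFAULT_VALIDATION_PER_HOUR,
) -> ImpactReport:
    """Project test-count and time deltas of the reflex protocol.

    Under the new protocol every screened patient receives SPEP and
    SFLCA, while SIFE and UIFE are performed only for the
    ``n_first_line_positive`` patients with a positive first-line result
    plus the ``n_al_suspicion`` AL suspicions.
    """
    for name, v in (
        ("n_screened", n_screened),
        ("n_first_line_positive", n_first_line_positive),
        ("n_al_suspicion", n_al_suspicion),
    ):
        if v < 0:
            raise InvalidInputError(f"{name} must be non-negative, got {v}")
    if any(v < 0 for v in received.values()):
        raise InvalidInputError("received request counts must be non-negative")
    if n_first_line_positive > n_screened:
        raise InvalidInputError("n_first_line_positive cannot exceed n_screened")

    reflex_n = n_first_line_positive + n_al_suspicion
    performed = {
        "SPEP": n_screened,
        "SFLCA": n_screened,
        "SIFE": reflex_n,
        "UIFE": reflex_n,
    }
    tests_received = {assay: int(received.get(assay, 0)) for assay in performed}
    tests_delta = {a: performed[a] - tests_received[a] for a in performed}
    bench_delta = {
        a: math.copysign(throughputs[a].hours_for(abs(d)), d) if d else 0.0
        for a, d in tests_delta.items()
    }
    validation_delta = {a: d / validation_per_hour for a, d in tests_delta.items()}
    return ImpactReport(
        tests_received=tests_received,
        tests_performed=performed,
        tests_delta=tests_delta,
        bench_hours_delta=bench_delta,
        validation_hours_delta=validation_delta,
        total_tests_delta=sum(tests_delta.values()),
        total_bench_hours_delta=sum(bench_delta.values()),
        total_validation_hours_delta=sum(validation_delta.values()),
    )
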