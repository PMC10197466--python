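"""Diagnostic-performance statistics for the screening rule.

2x2 contingency tables, sensitivity/specificity/PPV/NPV with exact
(Clopper-Pearson) confidence intervals, a two-sided Fisher exact test,
the cumulative alteration-count threshold sweep, and the assay
combination sensitivity matrix.

Proportions are kept unrounded internally; :func:`percent` provides the
report-display rounding (nearest integer, ties away from zero).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import beta as beta_dist

from .errors import IncompleteResultsError, InvalidInputError
from .screening import AssayResults, combo_positive

__all__ = [
    "ContingencyTable",
    "MetricWithCI",
    "ThresholdRow",
    "clopper_pearson",
    "build_contingency",
    "metrics",
    "fisher_exact",
    "threshold_sweep",
    "combo_sensitivity_table",
    "percent",
]


def percent(p: float, digits: int = 0) -> float:
    """Display rounding of a proportion as a percentage, ties away from zero."""
    scaled = p * 100.0 * 10**digits
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / 10**digits


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: prediction (flagged / screen positive) vs truth (diseased)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its exact binomial confidence interval.

    A zero denominator yields an explicitly undefined metric
    (``defined`` is False and all float fields are NaN) rather than a
    silent zero.
    """

    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    level: float = 0.95

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    def __str__(self) -> str:
        if not self.defined:
            return "undefined (0 denominator)"
        return (
            f"{percent(self.estimate):.0f}% "
            f"({percent(self.ci_low):.0f}-{percent(self.ci_high):.0f})"
        )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k successes in n."""
    if n <= 0 or k < 0 or k > n:
        raise InvalidInputError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return low, high


def _metric(k: int, n: int, level: float) -> MetricWithCI:
    if n == 0:
        nan = float("nan")
        return MetricWithCI(nan, nan, nan, numerator=0, denominator=0, level=level)
    low, high = clopper_pearson(k, n, level)
    return MetricWithCI(k / n, low, high, numerator=k, denominator=n, level=level)


def build_contingency(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate predicted positives against gold-standard labels."""
    if len(predicted) != len(truth):
        raise InvalidInputError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} labels"
        )
    if len(predicted) == 0:
        raise InvalidInputError("cannot build a contingency table from empty sequences")
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(pred & tru)),
        fp=int(np.sum(pred & ~tru)),
        fn=int(np.sum(~pred & tru)),
        tn=int(np.sum(~pred & ~tru)),
    )


def metrics(table: ContingencyTable, level: float = 0.95) -> dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV and NPV with exact CIs.

    Predictive values are computed at the sample's prevalence; no
    population-prevalence adjustment is applied.
    """
    if table.n == 0:
        raise InvalidInputError("empty contingency table")
    return {
        "sens": _metric(table.tp, table.tp + table.fn, level),
        "spec": _metric(table.tn, table.tn + table.fp, level),
        "ppv": _metric(table.tp, table.tp + table.fp, level),
        "npv": _metric(table.tn, table.tn + table.fn, level),
    }


# Relative slack when comparing hypergeometric point probabilities, so that
# tables with analytically tied probabilities are counted as "at least as
# extreme" despite floating-point rounding (the convention of R / scipy).
_FISHER_REL_TOL = 1.0 + 1e-7


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Enumerates the hypergeometric distribution at fixed margins and sums
    the probabilities of all tables whose point probability does not
    exceed that of the observed table (the minimum-likelihood
    definition). A table with a zero margin carries no information: p=1
    with a warning.
    """
    a, b, c, d = table.tp, table.fn, table.fp, table.tn
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = table.n
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("Fisher exact test on a table with a zero margin: p=1", stacklevel=2)
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(r2 + 1) - gammaln(c1 - support + 1) - gammaln(r2 - c1 + support + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(c2 + 1))
    )
    pmf = np.exp(logpmf)
    observed = pmf[int(a - support[0])]
    p = float(pmf[pmf <= observed * _FISHER_REL_TOL].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class ThresholdRow:
    """One row of the cumulative alteration-count sweep."""

    threshold: int
    table: ContingencyTable
    metrics: dict[str, MetricWithCI]
    fisher_p: float
    case_fraction_flagged: float
    control_fraction_flagged: float
    case_fraction_zero: float
    control_fraction_zero: float


def threshold_sweep(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    thresholds: Iterable[int] = (1, 2, 3),
    level: float = 0.95,
) -> list[ThresholdRow]:
    """Screening performance of the rule "alteration count >= k" for each k.

    ``case_counts`` / ``control_counts`` are per-patient numbers of
    altered parameters (0-6) in the diseased and control groups.
    """
    cases = np.asarray(case_counts, dtype=int)
    controls = np.asarray(control_counts, dtype=int)
    for arr, label in ((cases, "case"), (controls, "control")):
        if arr.size and (arr.min() < 0 or arr.max() > 6):
            raise InvalidInputError(f"{label} alteration counts must lie in 0-6")
    rows = []
    for k in thresholds:
        tp = int(np.sum(cases >= k))
        fp = int(np.sum(controls >= k))
        table = ContingencyTable(
            tp=tp, fp=fp, fn=int(cases.size - tp), tn=int(controls.size - fp)
        )
        rows.append(
            ThresholdRow(
                threshold=int(k),
                table=table,
                metrics=metrics(table, level),
                fisher_p=fisher_exact(table),
                case_fraction_flagged=tp / cases.size if cases.size else float("nan"),
                control_fraction_flagged=fp / controls.size if controls.size else float("nan"),
                case_fraction_zero=float(np.mean(cases == 0)) if cases.size else float("nan"),
                control_fraction_zero=float(np.mean(controls == 0)) if controls.size else float("nan"),
            )
        )
    return rows


def combo_sensitivity_table(
    results: Sequence[AssayResults],
    combos: Iterable[Iterable[str]],
    level: float = 0.95,
) -> dict[frozenset[str], MetricWithCI]:
    """Detection sensitivity of each assay combination over diseased patients.

    ``results`` are the assay outcomes of gold-standard diseased
    subjects; each entry is the fraction in whom the combination (OR
    over its assays) detects the monoclonal protein. Patients missing a
    result for an assay used by a combination are reported collectively.
    """
    combos = [frozenset(c) for c in combos]
    out: dict[frozenset[str], MetricWithCI] = {}
    for combo in combos:
        offending = [
            (i, assay)
            for i, r in enumerate(results)
            for assay in sorted(combo)
            if r.result(assay) is None
        ]
        if offending:
            raise IncompleteResultsError(
                "missing assay results (patient index, assay): "
                + ", ".join(f"({i}, {a})" for i, a in offending)
            )
        hits = sum(combo_positive(r, combo) for r in results)
        out[combo] = _metric(hits, len(results), level)
    return out
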