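"""Synthetic case/control cohorts for exercising the screening pipeline.

No per-patient data accompany the source study, so this module generates
cohorts with the same statistical structure: per-parameter alteration
frequencies in 54 cases and 120 controls, the five-way request-profile
mixture of the 261-patient prospective series, and per-assay monoclonal
protein detection behaviour by secretion type (including a non-secretory
case invisible to all four assays).

Laboratory values are realised *flag-exactly*: a drawn flag is encoded
as a concrete value strictly inside or strictly outside its reference
interval, so :func:`mgscreen.rules.flag_alterations` recovers the
intended flags with certainty, not just in distribution. Out-of-range
values sit uniformly within 20% beyond their cutoff; in-range values
uniformly within the reference interval.

The six alteration flags are independent by default (only the marginal
frequencies are known); an optional equicorrelation knob (Gaussian
copula with a shared latent factor) lets users mimic the mild positive
dependence real comorbidity induces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import InvalidConfigError, InvalidInputError
from .rules import (
    ALTERATION_NAMES,
    AlterationProfile,
    PatientRecord,
    ReferenceRanges,
    flag_alterations,
)
from .screening import AssayResults
from . import performance

__all__ = [
    "CohortSpec",
    "RoundtripReport",
    "CASE_ALTERATION_PROBS",
    "CONTROL_ALTERATION_PROBS",
    "REQUEST_PROFILES",
    "REQUEST_PROFILE_PROBS",
    "MP_TYPE_MIXTURE",
    "DETECTION_PROBS",
    "sample_cohort",
    "sample_cohort_with_profiles",
    "sample_test_results",
    "poisson_binomial_pmf",
    "calibrate_correlation",
    "simulate",
    "marginal_sensitivity",
    "roundtrip_check",
]

#: Observed alteration frequencies in the 54-case arm.
CASE_ALTERATION_PROBS: dict[str, float] = {
    "hyperproteinemia": 0.35,
    "hypercalcemia": 0.16,
    "anemia": 0.76,
    "renal": 0.22,
    "immunoparesis": 0.79,
    "bone": 0.43,
}

#: Observed alteration frequencies in the 120-control arm.
CONTROL_ALTERATION_PROBS: dict[str, float] = {
    "hyperproteinemia": 0.00,
    "hypercalcemia": 0.07,
    "anemia": 0.22,
    "renal": 0.09,
    "immunoparesis": 0.15,
    "bone": 0.03,
}

#: The five request profiles seen in the prospective series, with their
#: observed frequencies (only-UIFE 3%, UIFE+SPEP 16%, UIFE+SPEP+SIFE 7%,
#: only-SPEP 48%, SPEP+SIFE 26%).
REQUEST_PROFILES: tuple[frozenset[str], ...] = (
    frozenset({"UIFE"}),
    frozenset({"UIFE", "SPEP"}),
    frozenset({"UIFE", "SPEP", "SIFE"}),
    frozenset({"SPEP"}),
    frozenset({"SPEP", "SIFE"}),
)
REQUEST_PROFILE_PROBS: tuple[float, ...] = (0.03, 0.16, 0.07, 0.48, 0.26)

#: Secretion-type mixture among diseased subjects: mostly intact-Ig
#: myeloma, a light-chain-only minority, and one AL amyloidosis and one
#: non-secretory plasmacytoma per 54 cases.
MP_TYPE_MIXTURE: dict[str, float] = {
    "intact": 46 / 54,
    "light_chain_only": 6 / 54,
    "AL": 1 / 54,
    "non_secretory": 1 / 54,
}

#: Per-assay detection probability given secretion type. Chosen so the
#: mixture-weighted single-assay sensitivities land near SPEP 0.80,
#: SIFE 0.93, UIFE 0.78, SFLCA 0.91; the non-secretory type is
#: undetectable by construction. Assays are conditionally independent
#: given the type.
DETECTION_PROBS: dict[str, dict[str, float]] = {
    "intact": {"SPEP": 0.92, "SIFE": 0.975, "UIFE": 0.78, "SFLCA": 0.92},
    "light_chain_only": {"SPEP": 0.15, "SIFE": 0.78, "UIFE": 0.92, "SFLCA": 1.0},
    "AL": {"SPEP": 0.20, "SIFE": 0.85, "UIFE": 0.70, "SFLCA": 1.0},
    "non_secretory": {"SPEP": 0.0, "SIFE": 0.0, "UIFE": 0.0, "SFLCA": 0.0},
}

_TRUTH_BY_TYPE = {"intact": "MM", "light_chain_only": "MM", "AL": "AL", "non_secretory": "SP"}

# In-range reference intervals used to realise normal values (per-dL
# units for Ca/Hb/TP, g/L for immunoglobulins).
_IN_RANGE = {
    "ca": (8.8, 10.2),
    "cr": (0.4, 1.0),
    "tp": (6.6, 8.7),
    "igg": (7.0, 16.0),
    "iga": (0.7, 4.0),
    "igm": (0.4, 2.3),
}
_HB_NORMAL = {"female": (12.0, 15.5), "male": (13.0, 17.5)}
_EGFR_NORMAL = (60.0, 120.0)


def _validate_probs(name: str, probs: Mapping[str, float] | Sequence[float]) -> None:
    values = probs.values() if isinstance(probs, Mapping) else probs
    for p in values:
        if not 0.0 <= p <= 1.0:
            raise InvalidConfigError(f"{name}: probability {p} outside [0,1]")


@dataclass(frozen=True)
class CohortSpec:
    """Generating distribution of a synthetic case/control cohort."""

    n_cases: int = 54
    n_controls: int = 120
    case_alteration_probs: dict[str, float] = field(
        default_factory=lambda: dict(CASE_ALTERATION_PROBS)
    )
    control_alteration_probs: dict[str, float] = field(
        default_factory=lambda: dict(CONTROL_ALTERATION_PROBS)
    )
    mp_type_mixture: dict[str, float] = field(default_factory=lambda: dict(MP_TYPE_MIXTURE))
    detection_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(d) for t, d in DETECTION_PROBS.items()}
    )
    request_profile_probs: tuple[float, ...] = REQUEST_PROFILE_PROBS
    control_false_positive_rate: float = 0.0
    alteration_correlation: float = 0.0  # shared-factor Gaussian copula rho
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise InvalidConfigError("cohort sizes must be non-negative")
        for name, probs in (
            ("case_alteration_probs", self.case_alteration_probs),
            ("control_alteration_probs", self.control_alteration_probs),
        ):
            if set(probs) != set(ALTERATION_NAMES):
                raise InvalidConfigError(f"{name}: must cover exactly {ALTERATION_NAMES}")
            _validate_probs(name, probs)
        _validate_probs("mp_type_mixture", self.mp_type_mixture)
        if abs(sum(self.mp_type_mixture.values()) - 1.0) > 1e-9:
            raise InvalidConfigError("mp_type_mixture must sum to 1")
        unknown = set(self.mp_type_mixture) - set(self.detection_probs)
        if unknown:
            raise InvalidConfigError(f"no detection probabilities for types {sorted(unknown)}")
        for t, probs in self.detection_probs.items():
            _validate_probs(f"detection_probs[{t}]", probs)
        _validate_probs("request_profile_probs", self.request_profile_probs)
        if len(self.request_profile_probs) != len(REQUEST_PROFILES):
            raise InvalidConfigError(
                f"request_profile_probs needs {len(REQUEST_PROFILES)} entries"
            )
        if abs(sum(self.request_profile_probs) - 1.0) > 1e-9:
            raise InvalidConfigError("request_profile_probs must sum to 1")
        if not 0.0 <= self.control_false_positive_rate <= 1.0:
            raise InvalidConfigError("control_false_positive_rate outside [0,1]")
        if not 0.0 <= self.alteration_correlation < 1.0:
            raise InvalidConfigError("alteration_correlation must lie in [0,1)")


def _draw_flags(
    probs: Mapping[str, float], rho: float, rng: np.random.Generator
) -> dict[str, bool]:
    p = np.array([probs[name] for name in ALTERATION_NAMES])
    if rho == 0.0:
        hits = rng.random(len(p)) < p
    else:
        # Shared latent factor: z_i = sqrt(rho)*u + sqrt(1-rho)*e_i,
        # flag_i <=> z_i < Phi^{-1}(p_i); marginals stay exactly p_i.
        u = rng.standard_normal()
        z = math.sqrt(rho) * u + math.sqrt(1.0 - rho) * rng.standard_normal(len(p))
        hits = z < norm.ppf(p)
    return dict(zip(ALTERATION_NAMES, (bool(h) for h in hits)))


def _above(cutoff: float, rng: np.random.Generator) -> float:
    """Uniform draw strictly above ``cutoff``, within 20% beyond it."""
    v = rng.uniform(cutoff, 1.2 * cutoff)
    return float(np.nextafter(cutoff, np.inf)) if v <= cutoff else float(v)


def _below(cutoff: float, rng: np.random.Generator) -> float:
    """Uniform draw strictly below ``cutoff``, within 20% beneath it."""
    v = rng.uniform(0.8 * cutoff, cutoff)
    return float(np.nextafter(cutoff, 0.0)) if v >= cutoff else float(v)


def _within(lo: float, hi: float, rng: np.random.Generator) -> float:
    return float(rng.uniform(lo, hi))


def _realise_record(
    idx: str,
    flags: Mapping[str, bool],
    truth_label: str,
    mp_type: Optional[str],
    rng: np.random.Generator,
    ranges: ReferenceRanges,
) -> PatientRecord:
    sex = "female" if rng.random() < 0.5 else "male"
    hb_lo = ranges.hb_lower_female if sex == "female" else ranges.hb_lower_male
    igs = {k: _within(*_IN_RANGE[k], rng) for k in ("igg", "iga", "igm")}
    if flags["immunoparesis"]:
        which = ("igg", "iga", "igm")[rng.integers(3)]
        lower = {"igg": ranges.igg_lower, "iga": ranges.iga_lower, "igm": ranges.igm_lower}
        igs[which] = _below(lower[which], rng)
    if flags["renal"]:
        cr = _above(ranges.cr_upper, rng)
        egfr = _below(ranges.egfr_renal_flag_threshold, rng)
    else:
        cr = _within(*_IN_RANGE["cr"], rng)
        egfr = _within(*_EGFR_NORMAL, rng)
    return PatientRecord(
        id=idx,
        sex=sex,
        age=float(rng.integers(40, 86)),
        ca=_above(ranges.ca_upper, rng) if flags["hypercalcemia"] else _within(*_IN_RANGE["ca"], rng),
        cr=cr,
        egfr=egfr,
        hb=_below(hb_lo, rng) if flags["anemia"] else _within(*_HB_NORMAL[sex], rng),
        tp=_above(ranges.tp_upper, rng) if flags["hyperproteinemia"] else _within(*_IN_RANGE["tp"], rng),
        bone_involvement=flags["bone"],
        truth_label=truth_label,
        mp_type=mp_type,
        **igs,
    )


def sample_cohort(
    spec: CohortSpec,
    ranges: ReferenceRanges = ReferenceRanges(),
    rng: Optional[np.random.Generator] = None,
) -> list[PatientRecord]:
    """Draw a labelled case/control cohort, deterministic given ``spec.seed``.

    Cases precede controls in the returned list. Each record's
    laboratory values encode its drawn alteration flags exactly, and
    diseased records carry a secretion type drawn from the mixture.
    """
    records, _ = sample_cohort_with_profiles(spec, ranges, rng)
    return records


def sample_cohort_with_profiles(
    spec: CohortSpec,
    ranges: ReferenceRanges = ReferenceRanges(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PatientRecord], list[AlterationProfile]]:
    """As :func:`sample_cohort`, also returning the generating flag profiles."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    types = list(spec.mp_type_mixture)
    type_p = np.array([spec.mp_type_mixture[t] for t in types])
    records: list[PatientRecord] = []
    profiles: list[AlterationProfile] = []
    arms = [
        ("case", spec.n_cases, spec.case_alteration_probs),
        ("control", spec.n_controls, spec.control_alteration_probs),
    ]
    for arm, n, probs in arms:
        for i in range(n):
            flags = _draw_flags(probs, spec.alteration_correlation, rng)
            if arm == "case":
                mp_type = types[int(rng.choice(len(types), p=type_p))]
                truth = _TRUTH_BY_TYPE[mp_type]
            else:
                mp_type, truth = None, "none"
            rec = _realise_record(f"{arm}-{i:05d}", flags, truth, mp_type, rng, ranges)
            rec.requested_tests = REQUEST_PROFILES[
                int(rng.choice(len(REQUEST_PROFILES), p=np.array(spec.request_profile_probs)))
            ]
            records.append(rec)
            profiles.append(AlterationProfile(**flags))
    return records, profiles


def sample_test_results(
    record: PatientRecord,
    spec: CohortSpec,
    rng: Optional[np.random.Generator] = None,
) -> AssayResults:
    """Draw the four assay outcomes for one labelled patient.

    Diseased subjects are detected per-assay with the probabilities of
    their secretion type (drawn from the mixture if the record carries
    none); a non-secretory case is negative on every assay. Controls are
    negative apart from the configured false-positive rate.
    """
    if record.truth_label is None:
        raise InvalidInputError(f"record {record.id!r}: truth label required to draw results")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if record.diseased:
        mp_type = record.mp_type
        if mp_type is None:
            types = list(spec.mp_type_mixture)
            p = np.array([spec.mp_type_mixture[t] for t in types])
            mp_type = types[int(rng.choice(len(types), p=p))]
        det = spec.detection_probs[mp_type]
        draws = {a: bool(rng.random() < det[a]) for a in ("SPEP", "SIFE", "UIFE", "SFLCA")}
    else:
        fp = spec.control_false_positive_rate
        draws = {a: bool(rng.random() < fp) for a in ("SPEP", "SIFE", "UIFE", "SFLCA")}
    return AssayResults(
        spep_positive=draws["SPEP"],
        sife_positive=draws["SIFE"],
        uife_positive=draws["UIFE"],
        flc_ratio_abnormal=draws["SFLCA"],
    )


def _attach_flc_values(
    record: PatientRecord,
    flc_abnormal: bool,
    ranges: ReferenceRanges,
    rng: np.random.Generator,
) -> None:
    """Back-fill kappa/lambda concentrations consistent with the assay call."""
    if record.egfr is not None and record.egfr < ranges.egfr_ratio_switch_threshold:
        lo, hi = ranges.flc_ratio_renal
    else:
        lo, hi = ranges.flc_ratio_normal
    if flc_abnormal:
        # Kappa-restricted clones predominate; draw the high side 2:1.
        if rng.random() < 2 / 3:
            ratio = rng.uniform(1.1 * hi, 6.0 * hi)
        else:
            ratio = rng.uniform(0.1 * lo, 0.9 * lo)
    else:
        ratio = rng.uniform(1.02 * lo, 0.98 * hi)
    lam = rng.uniform(10.0, 26.0)
    record.flc_lambda = float(lam)
    record.flc_kappa = float(ratio * lam)


def simulate(
    spec: CohortSpec,
    ranges: ReferenceRanges = ReferenceRanges(),
) -> tuple[list[PatientRecord], list[AssayResults]]:
    """Generate a full cohort with assay results and consistent FLC values.

    One stream of randomness seeded by ``spec.seed`` drives everything,
    so the same spec always yields the bit-identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    records, _ = sample_cohort_with_profiles(spec, ranges, rng)
    results = []
    for rec in records:
        res = sample_test_results(rec, spec, rng)
        _attach_flc_values(rec, bool(res.flc_ratio_abnormal), ranges, rng)
        results.append(res)
    return records, results


def marginal_sensitivity(spec: CohortSpec, combo: Sequence[str]) -> float:
    """Mixture-implied detection probability of an assay combination.

    P(combo positive | diseased) under conditional independence of the
    assays given the secretion type.
    """
    combo = tuple(combo)
    total = 0.0
    for mp_type, weight in spec.mp_type_mixture.items():
        det = spec.detection_probs[mp_type]
        miss = 1.0
        for assay in combo:
            miss *= 1.0 - det[assay]
        total += weight * (1.0 - miss)
    return total


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Distribution of the number of true flags given independent marginals.

    Dynamic-programming convolution over the (at most six) Bernoulli
    components; entry k is P(count = k).
    """
    pmf = np.array([1.0])
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError(f"probability {p} outside [0,1]")
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def _count_tail_given_rho(probs: np.ndarray, rho: float, threshold: int) -> float:
    """P(count >= threshold) under the shared-factor Gaussian copula.

    Conditional on the latent factor u the flags are independent with
    p_i(u) = Phi((Phi^{-1}(p_i) - sqrt(rho) u) / sqrt(1-rho)); integrate
    over u by Gauss-Hermite quadrature.
    """
    if rho == 0.0:
        return float(poisson_binomial_pmf(probs)[threshold:].sum())
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    thresholds = norm.ppf(np.clip(probs, 0.0, 1.0))
    total = 0.0
    for u, w in zip(nodes, weights):
        cond = norm.cdf((thresholds - math.sqrt(rho) * u) / math.sqrt(1.0 - rho))
        total += w * float(poisson_binomial_pmf(cond)[threshold:].sum())
    return total / math.sqrt(2.0 * math.pi)


def calibrate_correlation(
    probs: Mapping[str, float] | Sequence[float] = None,
    threshold: int = 3,
    target: float = 0.017,
) -> float:
    """Correlation knob reproducing an observed co-occurrence rate.

    Solves for the equicorrelation rho at which the probability of
    ``threshold`` or more simultaneous alterations equals ``target``
    (default: the 1.7% of controls with three or more alterations),
    keeping every marginal frequency fixed. Raises if independence
    already exceeds the target.
    """
    from scipy.optimize import brentq

    if probs is None:
        probs = CONTROL_ALTERATION_PROBS
    p = np.array(
        [probs[name] for name in ALTERATION_NAMES]
        if isinstance(probs, Mapping) else list(probs)
    )
    base = _count_tail_given_rho(p, 0.0, threshold)
    if base > target:
        raise InvalidConfigError(
            f"independent flags already give P(count>={threshold})={base:.4f} > {target}"
        )
    return float(
        brentq(lambda r: _count_tail_given_rho(p, r, threshold) - target, 0.0, 0.95)
    )


@dataclass(frozen=True)
class RoundtripReport:
    """Generating-vs-recovered comparison for one simulated cohort."""

    n_cases: int
    n_controls: int
    flag_mismatches: int  # lab values failing to reproduce their drawn flags
    case_frequencies: dict[str, float]
    control_frequencies: dict[str, float]
    case_probs: dict[str, float]
    control_probs: dict[str, float]
    max_abs_z: float  # worst |recovered - generating| in binomial SEs
    sweep: list[performance.ThresholdRow]
    control_ge3_fraction: float
    combo_sensitivities: dict[frozenset[str], float]
    combo_expected: dict[frozenset[str], float]


def roundtrip_check(
    spec: CohortSpec,
    ranges: ReferenceRanges = ReferenceRanges(),
    combos: Sequence[Sequence[str]] = (
        ("SPEP",), ("SIFE",), ("UIFE",), ("SFLCA",),
        ("SPEP", "SFLCA"), ("SPEP", "SIFE", "UIFE", "SFLCA"),
    ),
) -> RoundtripReport:
    """Simulate a cohort and push it through rules -> screening -> performance.

    Reports recovered per-parameter frequencies against the generating
    probabilities (worst deviation in binomial standard errors), the
    threshold-sweep metrics, and combination sensitivities among
    diseased subjects against the mixture-implied values.
    """
    rng = np.random.default_rng(spec.seed)
    records, intended = sample_cohort_with_profiles(spec, ranges, rng)
    results = []
    for rec in records:
        res = sample_test_results(rec, spec, rng)
        _attach_flc_values(rec, bool(res.flc_ratio_abnormal), ranges, rng)
        results.append(res)

    recovered = [flag_alterations(rec, ranges) for rec in records]
    mismatches = sum(r.as_dict() != i.as_dict() for r, i in zip(recovered, intended))

    case_idx = [i for i, r in enumerate(records) if r.diseased]
    ctrl_idx = [i for i, r in enumerate(records) if not r.diseased]

    def freqs(idx: list[int]) -> dict[str, float]:
        if not idx:
            return {name: float("nan") for name in ALTERATION_NAMES}
        return {
            name: sum(getattr(recovered[i], name) for i in idx) / len(idx)
            for name in ALTERATION_NAMES
        }

    case_freq, ctrl_freq = freqs(case_idx), freqs(ctrl_idx)
    max_z = 0.0
    for freq, probs, n in (
        (case_freq, spec.case_alteration_probs, len(case_idx)),
        (ctrl_freq, spec.control_alteration_probs, len(ctrl_idx)),
    ):
        for name in ALTERATION_NAMES:
            p = probs[name]
            se = math.sqrt(p * (1 - p) / n) if n and 0 < p < 1 else None
            if se:
                max_z = max(max_z, abs(freq[name] - p) / se)
            elif n and p in (0.0, 1.0) and freq[name] != p:
                max_z = math.inf  # degenerate prob must be recovered exactly

    case_counts = [recovered[i].count for i in case_idx]
    ctrl_counts = [recovered[i].count for i in ctrl_idx]
    sweep = performance.threshold_sweep(case_counts, ctrl_counts)
    ge3 = sum(c >= 3 for c in ctrl_counts) / len(ctrl_counts) if ctrl_counts else float("nan")

    diseased_results = [results[i] for i in case_idx]
    combo_table = performance.combo_sensitivity_table(diseased_results, combos)
    return RoundtripReport(
        n_cases=len(case_idx),
        n_controls=len(ctrl_idx),
        flag_mismatches=int(mismatches),
        case_frequencies=case_freq,
        control_frequencies=ctrl_freq,
        case_probs=dict(spec.case_alteration_probs),
        control_probs=dict(spec.control_alteration_probs),
        max_abs_z=float(max_z),
        sweep=sweep,
        control_ge3_fraction=ge3,
        combo_sensitivities={c: m.estimate for c, m in combo_table.items()},
        combo_expected={frozenset(c): marginal_sensitivity(spec, c) for c in combos},
    )
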