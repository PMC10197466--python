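# Methods

## Suspicion model

A patient's MG suspicion level is the count of six binary alterations
evaluated from routine results: hyperproteinemia, hypercalcemia, anemia,
renal function deterioration, immunoparesis, and bone involvement. All
cutoffs are strict (`>` / `<`); a value exactly on a cutoff is normal.
Defaults (per-dL units for Ca/Hb/TP, g/L for immunoglobulins):

| parameter        | rule (default)                                   |
|------------------|--------------------------------------------------|
| hyperproteinemia | TP > 8.7 g/dL                                    |
| hypercalcemia    | Ca > 10.2 mg/dL                                  |
| anemia           | Hb < 12 g/dL (women), < 13 g/dL (men)            |
| renal            | Cr > 1.8 mg/dL **or** eGFR < 60 mL/min/1.73 m²   |
| immunoparesis    | ≥ 1 of IgG < 7, IgA < 0.7, IgM < 0.4 g/L         |
| bone             | supplied boolean (lesions or bone pain)          |

Design choices made where the rules were genuinely open:

- **MDRD-4 form.** When eGFR is absent it is computed with the
  IDMS-traceable four-variable MDRD equation,
  `175 · Cr^−1.154 · age^−0.203 · 0.742(female) · 1.212(Black)` — the
  standard contemporary coefficients; only its < 60 and < 40 thresholds
  feed the model, so the choice of MDRD variant is second-order.
- **Immunoparesis conjunction.** The three immunoglobulin thresholds
  carry no explicit conjunction rule; "any one class suppressed" is the
  default (the permissive reading, consistent with the observed 79%
  case frequency), with `min_igs_low=2` available for sensitivity
  analyses.
- **Renal OR-rule.** If both creatinine and eGFR are present the flag is
  the OR of both criteria; eGFR is derived from creatinine only when
  absent.
- **Units.** Fixed as above; readers treat an empty cell as missing and
  never convert units silently.

The FLC κ/λ ratio is abnormal strictly outside 0.26–1.65, widened to
0.37–3.1 when eGFR < 40 mL/min/1.73 m² (reduced clearance raises both
free light chains asymmetrically, so the standard interval loses
specificity in renal impairment). Positivity uses the ratio only, not
absolute κ or λ concentrations.

## Screening algorithm

Triage (threshold *t*, default 2): a patient enters the screening
pathway iff SPEP was requested and the alteration count ≥ *t*, or
SIFE/UIFE was requested without a previous MG diagnosis. The default
follows the prospectively validated "two or more" rule; the threshold
is exposed because the ≥ 3 rule is the better-justified cutoff on
predictive-value grounds. Triaged-in patients receive SPEP + SFLCA;
SIFE and UIFE are added jointly (a configurable mask) iff a first-line
test is positive or AL amyloidosis is suspected. An AL suspicion with
negative first-line results triggers reflex testing but the screen
itself is called negative — the final call tracks first-line positivity
only. Non-triaged patients keep whatever their physician ordered; the
algorithm only adds or withholds SFLCA/SIFE/UIFE.

## Performance statistics

Sensitivity, specificity, PPV and NPV come directly from the 2×2
counts; confidence intervals are exact Clopper–Pearson (beta-quantile
form), chosen because exact intervals remain valid at the small,
boundary-heavy denominators typical here (e.g. 19/19 → 82–100%).
Wilson or normal approximations are deliberately not used. A metric
with a zero denominator is reported as explicitly undefined, never as 0.

The two-sided Fisher exact test enumerates the hypergeometric
distribution at fixed margins and sums the probabilities of all tables
whose point probability is at most that observed (minimum-likelihood
definition, the convention of R and most clinical software), with a
1e-7 relative tie tolerance. Tables with a zero margin return p = 1
with a warning. Percent display rounds to nearest with ties away from
zero; all computation and comparisons use unrounded proportions.

Predictive values are computed at the sample prevalence (54:120 ≈ 1:2.2
here). True MM prevalence is orders of magnitude lower (4–6 per
100,000), so PPV/NPV from case/control designs do not transfer to an
unselected population; no prevalence adjustment is applied, matching
the source design and its stated limitation.

Known report discrepancies: a handful of published percent cells are
inconsistent with their own counts under any single rounding rule
(e.g. an NPV cell of 90 where the counts give 90.5, a sensitivity cell
of 79 where the counts give 79.6, and a ≥1-row PPV of 49 where the
counts give 50.9, suggesting a transposed numerator; exact .5 values
are printed rounded down). This package always computes from counts.

## Workload model

Daily hours per assay = monthly requests ÷ batch size × minutes per
batch ÷ 60 ÷ working days (22/month) for plate assays, or requests ÷
samples-per-hour ÷ working days for electrophoresis. Defaults: SIFE
75 min per 4-sample plate, UIFE 75 min per 9-sample plate, SPEP 80
samples/h, SFLCA 50 min per 20 samples, validation 45 tests/h shared
across assays. Fractional plates are the default (85.75 plates for 343
requests) — the only reading that reproduces the reference 4.9 and
2.79 h/day; integer-ceiling batching is available as an option.
Reports carry both unrounded component sums and the "displayed" sum of
rounded components (SIFE/SPEP to 1 d.p., UIFE to 2 d.p., validation to
integer), whose total 13.49 h/day matches the reference presentation.

Two source figures are not derivable from the stated throughputs and
are not reproduced: the per-protocol UIFE/SIFE bench-hour savings cells
(stated −6.4 and −19.3 h where the stated per-plate times give −5.6 and
−18.1), and the claim that 31.5% of assay time serves new patients
(which does not follow from the stated 20/50/25% request fractions).
The reference daily throughput of "8 samples/hour" for electrophoresis
also conflicts with its own worked arithmetic, which uses 80/h; the
default here is 80/h. `protocol_impact` reports only quantities that
follow from its inputs: per-assay test deltas, and bench/validation
hours derived from those deltas via the configured throughputs.

## Synthetic cohort generator

The generator emulates the study conditions: 54 cases / 120 controls
with per-parameter alteration probabilities (cases 0.35, 0.16, 0.76,
0.22, 0.79, 0.43; controls 0, 0.07, 0.22, 0.09, 0.15, 0.03 in the
table order above), the five-way request-profile mixture of the
261-patient prospective series (0.03, 0.16, 0.07, 0.48, 0.26), and a
secretion-type mixture of 46/54 intact-Ig, 6/54 light-chain-only, 1/54
AL and 1/54 non-secretory, with per-assay detection probabilities per
type chosen so the mixture-weighted single-assay sensitivities sit near
SPEP 0.80, SIFE 0.93, UIFE 0.78, SFLCA 0.91 and the non-secretory case
is undetectable by all four assays. Detection probabilities are
configuration values reproducing marginal sensitivities, not claims
about the true inter-assay dependence; assays are conditionally
independent given the secretion type.

Flags are realised *flag-exactly*: an out-of-range value is drawn
uniformly within 20% beyond its cutoff (strictly beyond), an in-range
value uniformly within the reference interval, so
`rules.flag_alterations` recovers the drawn flags with certainty.
κ/λ concentrations are back-filled consistently with the drawn SFLCA
result against the interval applicable at the patient's eGFR (λ
uniform on 10–26 mg/L; abnormal ratios drawn high-side 2:1, reflecting
the predominance of κ-restricted clones). One `numpy` generator seeded
by `CohortSpec.seed` drives everything, so equal specs give
bit-identical cohorts.

The six flags are independent by default — only the marginal
frequencies are known. Independence implies a Poisson-binomial
alteration count; it yields ~0.7% of controls with ≥ 3 alterations
versus the observed 1.7%, i.e. real comorbidity is mildly positively
correlated. `calibrate_correlation()` solves (Gauss–Hermite quadrature
+ Brent root-finding) for the shared-factor Gaussian-copula
equicorrelation (ρ ≈ 0.10) that reproduces a target co-occurrence rate
while preserving every marginal.

What the generator does **not** emulate: realistic joint distributions
of analytes (values are uniform within bands, not physiologic),
longitudinal dynamics or MGUS progression, correlated assay errors, and
the 25 excluded retrospective patients whose exclusion criteria are
unstated. Passing tests therefore demonstrate the pipeline's logic and
statistics, not performance on real patients.

## Problem sizes and numerical checks

Unit and property tests run cohorts of 300–8,000 patients;
parameter-recovery checks use 5,000 per arm, where 3 binomial standard
errors is ≈ 1.8 points at p = 0.76. The exact statistics are verified
against independent oracles over every 2×2 table with n ≤ 60
(integer-arithmetic hypergeometric enumeration for Fisher; bisection on
hand-summed binomial tails for Clopper–Pearson), agreeing to < 1e-10.
Combination-monotonicity (OR over a superset never less positive) is
checked on 10,000 simulated result sets. All stochastic tests are
seeded and deterministic.
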