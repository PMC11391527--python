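# Methods

## Decision problem and model structure

The package evaluates hemiarthroplasty (HA) against internal fixation (IF)
for nondisplaced femoral neck fracture in a homogeneous cohort of 80-year-old
patients, payer perspective, 2020 USD, 5-year horizon, 1-year cycles, 3%
annual discounting of both costs and QALYs.

The cohort engine is a discrete-time Markov state-transition model with five
states: `PRIMARY_IF`, `PRIMARY_HA`, `CONVERTED_HA`, `CONVERTED_THA`, `DEAD`.
A four-state formulation (success, success, converted-to-THA, dead) cannot
express the assumption that a salvage hemiarthroplasty fails at the same
annual rate as a primary one, so the salvage destinations are split into
`CONVERTED_HA` (utility `u_ha`, fails at `fail_ha` into `CONVERTED_THA` at
cost `c_ha_to_tha`) and `CONVERTED_THA` (terminal implant, assumed never to
fail within the horizon).

Within a cycle events compose in a fixed order:

1. background (other-cause) death at the age-specific life-table probability
   for age `start_age + cycle − 1`;
2. implant failure among survivors: `PRIMARY_IF` fails with probability
   `fail_if`, split 50/50 between salvage HA and salvage THA;
   `PRIMARY_HA` and `CONVERTED_HA` fail with probability `fail_ha`, always
   to THA;
3. perioperative death of that cycle's conversion surgery (`periop_mort_ha`
   for a salvage HA, `periop_mort_tha` for any THA).

This ordering keeps every per-event probability applied exactly as stated,
with no competing-risk rescaling. Cycle 0 charges the initial procedure cost
(`c_if` or `c_ha`) undiscounted to the whole cohort — the operation precedes
any perioperative death — and applies the initial perioperative mortality;
no utility accrues in cycle 0.

## Reward conventions

Per cycle t = 1..5, end-of-cycle survivors accrue their state utility;
patients converting during the cycle accrue the *destination* state's
utility plus the one-off salvage disutility (−0.15); patients dying during
the cycle (background or perioperative) accrue nothing that cycle.
Conversion costs are charged to everyone undergoing the procedure,
perioperative deaths included. Rewards of cycle t are discounted by
(1 + r)^(−t) by default (`accrual="end"`). Two alternatives are provided and
propagated through the microsimulation oracle: `accrual="begin"` (exponent
t − 1) and `half_cycle_correction=True` (exponent t − ½). The conventions
change only discount timing, not event logic, so switching them rescales
totals by at most one year of discounting.

## Inputs

All scalars live in one validated, immutable record (`ModelParams`); every
violation names the offending field and nothing is silently clamped. Base
case: perioperative mortality 4.1% (IF), 5.3% (HA), 3.9% (THA); annual
failure 3.3% (IF), 1.5% (HA, primary or salvage); utilities 0.63 / 0.68 /
0.70 (IF / HA / THA) with −0.15 salvage disutility; costs $8,632 (IF),
$12,449 (HA), $26,670 (IF→HA), $25,508 (IF→THA), $22,662 (HA→THA); WTP
$11,083/QALY; discount 3%/yr; horizon 5 cycles from age 80. Where published
tabulations of these inputs disagree (an IF failure mean printed once as
2.7% and once as 3.3%; an IF→HA cost printed as 22,670 and 26,670), the
base-case table values 3.3% and 26,670 are used — the Beta(96.67, 2832.64)
parameters back-solve to mean 0.033, identifying the 2.7% as a typo — and
the alternatives remain selectable through the config.

Background mortality is an explicit `LifeTable` input (CSV, `age,qx`, no
extrapolation). The bundled fixture transcribes approximate China 2020
census age-specific mortality for ages 80–85 (q₈₀ ≈ 0.039 rising to
q₈₅ ≈ 0.069). Census-based old-age mortality in 2020 runs low relative to UN
estimates, and any user with a preferred national or subgroup table should
substitute it.

**Reproduction caveat.** Published base-case totals for this comparison
(≈2.94/2.75 QALYs, ≈$13,324/$12,167, ICER ≈ $6,128/QALY) do not print the
life table behind them. Two findings from this implementation, both checked
by `tests/test_acceptance.py`:

- the published QALY totals are matched almost exactly only when background
  mortality is near zero (0.947 × 0.68 × Σₜ1.03⁻ᵗ ≈ 2.94); with the
  realistic fixture the model yields ≈2.57/2.41 QALYs;
- the published incremental cost (≈$1,157) is unattainable under the stated
  inputs in *any* cycle convention: the discounted conversion-cost gap
  between arms is bounded by Σₜ occ·(0.033·26,089 − 0.015·22,662) ≤ ≈$2,420,
  short of the required $12,449 − $8,632 − $1,157 = $2,660. The model here
  yields ΔC ≈ $1,923, hence ICER ≈ $12,186 instead.

Deriving a life table from those published totals would be circular, so the
fixture stays as transcribed and the affected end-to-end checks are expected
to fail at their stated tolerances; the cost totals, the tornado ordering,
the cost and utility thresholds and the share-more-effective PSA statistic
are reproduced within their gates. The engine itself is validated
independently (below), so the residual gaps are attributable to the inputs,
not the integration.

## Deterministic sensitivity analysis

One-way analysis perturbs each of the 14 eligible inputs (probabilities,
utilities, disutility, costs) by a symmetric relative range, ±20% by
default, recording the ICER at both ends; probabilities pushed outside
[0, 1] are clamped with a warning. The WTP, discount rate, horizon,
conversion split and life table are excluded from the tornado by default
but can be passed explicitly. Bar width is |ICER_high − ICER_low| on the
signed ICER scale.

Threshold search solves, by bisection (scipy `brentq`, |f| tolerance ~1e-10
after a 129-point sign-change scan), for the parameter value where HA
becomes exactly cost-effective (net monetary benefit WTP·ΔE − ΔC = 0 — the
NMB root is used rather than the ICER itself because the ratio changes sign
discontinuously when ΔE crosses zero) or exactly dominant (ΔC = 0 with
ΔE > 0). Search domains: [0, 1] for probabilities and utilities, [−1, 0]
for the disutility, [0, 4 × base] for costs (configurable). When no sign
change exists in the domain the result is NA with a reason — e.g. utilities
cannot move costs, so they never produce a dominance threshold. Every
returned threshold is re-evaluated: cost-effective roots satisfy
|ICER − WTP|/WTP < 1e-4 and dominant roots |ΔC| < $0.01.

The two-way analysis classifies each cell of a strictly increasing
parameter grid (by default the two procedure prices) as cost-effective
(dominant included) or not.

## Probabilistic sensitivity analysis

Ten inputs are sampled independently per iteration — `fail_if`, `fail_ha`,
`u_if`, `u_ha`, `u_tha` from Beta distributions and the five costs from
Gamma distributions — each matched by the method of moments to the
base-case mean with SD = 10% of the mean (`cv` configurable):
ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν; Gamma shape = (m/s)², rate =
shape/m. Round-trips are exact to 1e-10 and sampling moments are verified
against analytic values. Perioperative mortalities, the 50/50 split, the
discount rate and the life table stay fixed (no published dispersion).
A single seeded `numpy` generator draws parameters in a fixed order
(the Beta block then the Gamma block, one vector each), making runs
bit-reproducible; 10,000 iterations run in a few seconds.

Acceptability uses the net-monetary-benefit rule (ΔC < WTP·ΔE), which
equals "ICER below WTP" in the costlier-and-more-effective quadrant and
behaves correctly in the dominance quadrants. The CE-plane summary reports
the shares with ΔC > 0, ΔE > 0 and positive NMB, the ICER of means, and a
95% confidence ellipse from the χ²(2 df, 0.95) contour of the sample
mean/covariance of (ΔE, ΔC).

## Synthetic data and validation oracle

- `GompertzLaw(a, b)` generates life tables q(age) = min(1, a·e^{b·age}) —
  the standard old-age mortality law — for tests needing arbitrary age
  coverage; the defaults used in tests (a = 3·10⁻⁵, b = 0.09) give
  q₈₀ ≈ 0.04, consistent with the bundled fixture.
- `generate_random_params` draws uniformly within a clinically plausible
  bounds profile (probabilities well inside (0, 1), costs $3k–$40k) and
  returns only records passing full validation; used for property tests.
- `microsimulate` is an individual-level Monte Carlo oracle: it samples each
  patient's perioperative survival, yearly background death, failure,
  conversion type and conversion survival, applying the same reward and
  discount conventions, but shares no code with the cohort engine's
  transition algebra. Agreement of both discounted totals within 3 Monte
  Carlo standard errors at n = 200,000 — for the base case and 20 random
  parameter sets — is asserted in the suite. (This oracle caught a real
  defect during development: an undiscounted conversion cost.)

## Numerical choices and limitations

- Occupancy vectors are validated to sum to 1 within 1e-9 on entry; traces
  satisfy row sums within 1e-12 and a monotone `DEAD` column.
- ICER is `None` when ΔE = 0 (classification `indeterminate`); dominance
  requires strictly ΔC < 0 and ΔE > 0.
- `well_state_share` (occupancy of the arm's primary-success state at
  horizon end) is reported among survivors by default, among the initial
  cohort on request; the statistic is descriptive only and not used as a
  check, since its published definition is ambiguous.
- Not modelled: salvage-THA failure and its revisions, complications other
  than implant failure (infection, dislocation, hardware removal), cohort
  heterogeneity, time-dependent failure rates, currency conversion, and
  value-of-information analysis.
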