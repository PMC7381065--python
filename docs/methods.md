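# Methods

## Scope and model

`trialcua` implements a trial-based cost-utility analysis (CUA) for a
two-arm parallel trial with patient-reported disability as the clinical
outcome. The effect measure is the quality-adjusted life year (QALY)
obtained by mapping the Oswestry Disability Index (ODI) to SF-6D utility;
the cost measure is protocol-determined direct health-care cost per
participant. The headline estimand is the incremental cost-effectiveness
ratio

ICER = (C_new − C_ref) / (E_new − E_ref),

reported as a numeric naira-per-QALY ratio only in the trade-off quadrants
of the cost-effectiveness plane and as a dominance label otherwise: a new
intervention that is strictly cheaper and strictly more effective is
*dominant* (a ratio of two favourable differences carries no decision
information), and symmetrically *dominated*. A zero incremental effect is
*indeterminate*; no division is attempted.

## Design arithmetic

Per-group sample size uses the two-proportion formula
m = c·[π₁(1−π₁) + π₂(1−π₂)]/(π₁−π₂)², with the power/significance level
folded into c (7.9 for 80% power at two-sided α = 0.05). The fractional
size is rounded up to whole participants per group; the attrition
adjustment multiplies the total by (1 + rate) and rounds to the nearest
integer by default (so a 10% allowance on 42 gives 46), with a ceiling
mode available as a configurable alternative.

Permuted-block randomization draws each block of size 4 uniformly from the
6 distinct balanced orderings of {A,A,B,B} (the multiset coefficient
4!/(2!·2!) = 6; 4! = 24 counts orderings of four *distinct* items, which is
not the number of balanced blocks). Envelope mechanics and allocation
concealment are out of scope; the contract is balance after every complete
block and bit-reproducibility for a fixed seed.

## Outcomes and QALYs

ODI items score 0–5; the total is rescaled to 0–100 over the items actually
answered: 100·Σ/ (5·n_answered). Utility is the linear map
SF-6D = 0.78275 − 0.00518·ODI, which is strictly decreasing and stays
inside (0, 1) for ODI ∈ [0, 100]; out-of-range ODI is rejected rather than
clamped because the mapping is not calibrated there.

QALY convention: with assessments at weeks 4 and 8, the default
(`mean_utility`) holds the average of the two utilities over the full
8-week horizon, QALY = mean(u₄, u₈)·8/52. An alternative
(`period_average`) credits each assessment with its own elapsed duration
and averages the two period QALYs, mean(u₄·4/52, u₈·8/52). The default was
chosen because only it produces arm QALYs of the ~0.085 magnitude that a
utility level of ~0.55 over 8 weeks implies; the alternative yields ~0.063
at the same utility level. Both are selectable.

## Costing

Each resource item is either one-off or recurs at a weekly frequency over
the horizon; per-participant arm totals are exact integer naira when unit
costs are integers (SMS 50×3/week×8 weeks = 1,200; phone 20,000;
consultation 1,000; clinic visits 1,000×24; transport 500×24 — giving
22,200 vs 38,200 naira and a 16,000-naira saving). Costs are
protocol-determined and identical within arm; the data model supports
participant-level variation for extensions.

USD is display-only at 360 naira/USD (back-derived from the paired unit
prices: 1,000 → 2.78, 500 → 1.39, 50 → 0.14, 20,000 → 55.56; the rate is
config, never hard-coded in computation). Two USD views exist because they
genuinely differ: direct conversion of the naira totals (22,200/360 =
61.67) and the per-item display chain used in published cost tables —
per-unit USD rounded to cents, item totals to one decimal, then summed —
which yields 61.8 and 106.3. Incremental costs are always computed in
naira, so display rounding never propagates into the analysis. Medication
and indirect/personal costs are excluded; no discounting over an 8-week
horizon.

## Bootstrap and the cost-effectiveness plane

Uncertainty uses a nonparametric bootstrap: participants are resampled with
replacement *within* each arm (arm sizes preserved; each participant's cost
and effect travel together), arm means and the incremental pair are
recomputed per replicate. Default B = 1000; percentile 95% CIs, with
bias-corrected-and-accelerated (BCa, jackknife acceleration) as an option
since the interval method behind published trial CIs of this kind is rarely
stated. Replicates are bit-identical for a fixed seed (one `default_rng`
stream, arms drawn in a fixed order).

Plane convention: ΔEffect horizontal, ΔCost vertical; SE (ΔE>0, ΔC<0) is
the dominant quadrant. Replicates falling exactly on an axis — probability
~0 with continuous data — are assigned to the quadrant reached next when
sweeping clockwise (+ΔC axis → NE, +ΔE → SE, −ΔC → SW, −ΔE → NW; origin →
NE), so quadrant proportions always sum to exactly 1. The
cost-effectiveness acceptability curve (probability of positive net
monetary benefit λ·ΔE − ΔC over a willingness-to-pay grid) is an optional
extension beyond the core analysis and is labelled as such in reports.

## Clinical-effectiveness statistics

Within-arm improvement is mean(baseline − follow-up) with a t-based 95% CI
(improvement positive). Between-arm contrasts are reported as the
arithmetic difference of mean changes with a Welch unequal-variance CI; a
Mann-Whitney U p-value accompanies them. The Mann-Whitney implementation
uses midranks; the two-sided p-value enumerates all rank assignments
exactly for combined n ≤ 12 (valid under ties because the midrank multiset
is enumerated) and otherwise uses the normal approximation with
tie-corrected variance and continuity correction. The Friedman statistic is
computed on within-participant midranks with the standard tie correction;
when every participant's scores are completely tied the corrected statistic
is defined as 0 (no time effect) rather than 0/0. Significance threshold
0.05 two-sided. No multiplicity adjustment or baseline-covariate adjustment
is applied.

## Synthetic cohort generator

The generator produces participant-level cohorts with the trial's
*summary* structure: arm sizes 21 (telerehabilitation) and 26 (clinic);
age, weight, height and pain-duration from per-arm normals truncated to
plausible ranges (age to the 20–65 eligibility window) by rejection
sampling, so truncation adds no point masses; BMI derived as
weight/height². Week-4 and week-8 ODI change draws are jointly Gaussian
with configured means and a within-participant correlation of 0.7 (an
assumption, configurable); change SDs are back-derived from published
t-based 95% CIs via SD = halfwidth·√n / t₀.₉₇₅,ₙ₋₁ (≈ 4.17/6.28 for the
telerehabilitation arm at weeks 4/8, ≈ 7.55/9.57 for the clinic arm).
Follow-up ODI is baseline − change, clamped to [0, 100].

Baseline ODI is published nowhere, so it is calibrated: arm QALYs of
0.085/0.084 over 8 weeks imply mean post-treatment utilities of
~0.553/0.546, i.e. mean week-4–8 ODI of ~44.4/45.7; adding back the mean
improvements gives default baseline means of 57.5 (telerehabilitation) and
57.2 (clinic). The baseline SD of 10 ODI points is a realistic
moderate-disability spread, chosen once. Costs are attached per protocol
from the cost model.

What the generator does *not* emulate — and hence what passing tests do not
demonstrate about real data: dropout and missing assessments, adherence
variation, baseline covariate imbalance beyond configured means, skewness
or floor effects in ODI, or any cost heterogeneity between participants.
The degenerate within-arm cost distribution makes the bootstrap ΔCost
interval zero-width by construction, exactly as a protocol-costed trial
would.

## Problem sizes and numerical choices

Default analyses run B = 1000 bootstrap replicates on 47-participant
cohorts; calibration checks average 500 simulated cohorts and parameter
recovery uses 500 per arm — sizes at which Monte-Carlo error is a few
percent of the quantities checked and a full run completes in seconds.
Stochastic assertions use 2–3 Monte-Carlo standard errors computed from the
simulations themselves. All randomness flows through
`numpy.random.default_rng(seed)`; the same seed gives bit-identical
cohorts, allocation sequences and replicate sets. Display rounding is
half-up via `decimal` to keep currency tables deterministic across
platforms.

## Known limitations

- The trade-off-quadrant ICER is reported without a bootstrap CI of its
  own: ratio intervals are unstable near ΔE = 0, which is precisely the
  regime of this trial; plane proportions and the CEAC carry the
  uncertainty instead.
- An 8-week horizon supports no extrapolation, discounting, or
  probabilistic sensitivity analysis over parameter distributions; these
  are deliberately out of scope.
- Between-arm effectiveness contrasts are the arithmetic difference of
  mean changes; published contrasts computed by other (unstated) methods
  are not reproduced.
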