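# trialcua

Trial-based cost-utility analysis for two-arm rehabilitation trials, built
around the comparison of telerehabilitation-based versus clinic-based
McKenzie therapy for nonspecific chronic low back pain. The package is aimed
at health economists and trial statisticians who need a tested, reproducible
pipeline from participant-level trial records (or synthetic stand-ins) to an
incremental cost-effectiveness ratio with bootstrap uncertainty.

## What it computes

- **Design arithmetic** — the two-proportion sample-size formula
  *m = c·[π₁(1−π₁) + π₂(1−π₂)] / (π₁−π₂)²* (c = 7.9 for 80% power),
  attrition inflation, and permuted-block allocation sequences (block size 4,
  drawn uniformly from the 6 balanced orderings).
- **Outcomes** — Oswestry Disability Index (ODI) scoring (10 items, 0–5 each,
  rescaled to 0–100), the linear utility mapping
  *SF-6D = 0.78275 − 0.00518·ODI*, and QALYs over the 8-week horizon
  (mean of the week-4 and week-8 utilities × 8/52 years by default).
- **Costing** — protocol-determined per-participant resource costs in exact
  integer naira (SMS reminders, phones, clinic visits, consultation,
  transport), with USD shown as a display conversion.
- **Incremental analysis** — ΔCost and ΔEffect (new arm minus reference),
  ICER = ΔC/ΔE with dominance classification (an arm that is cheaper *and*
  more effective is "dominant"; no numeric ratio is reported), a
  participant-level within-arm bootstrap (percentile or BCa 95% CIs), the
  cost-effectiveness plane with quadrant proportions, and an optional
  cost-effectiveness acceptability curve.
- **Clinical effectiveness** — mean ODI change from baseline with t-based
  CIs, Mann-Whitney U (exact enumeration for combined n ≤ 12, tie-corrected
  normal approximation otherwise) and the Friedman test across the three
  assessments.
- **Synthetic cohorts** — a generator that emulates the trial's structure
  (arm sizes 21/26, demographics, change-score distributions with SDs
  back-derived from published 95% CIs) so the whole pipeline is testable
  without any deposited patient data.

## Worked example

```python
import trialcua as t

cohort = t.generate_cohort(t.default_config(), seed=42)   # 21 TBMT + 26 CBMT
res = t.CostUtilityModel.from_cohort(cohort).fit(reps=1000, seed=42)
print(res.summary())
```

```
Cost-utility analysis (participant-level bootstrap)
==================================================================
arm                n   mean cost (naira)   mean QALY
------------------------------------------------------------------
TBMT              21              22,200      0.0868
CBMT              26              38,200      0.0835
------------------------------------------------------------------
Incremental cost:   -16,000 naira (US $-44.44)
                    95% CI (-16,000, -16,000)
Incremental effect: 0.0033 QALY
                    95% CI (-0.0013, 0.0083)
ICER:               dominant
Plane quadrants (1000 replicates): NE=0.000, SE=0.908, SW=0.092, NW=0.000
CI method: percentile; seed: 42
```

The telerehabilitation arm costs 16,000 naira less per participant — a
protocol-determined saving, hence the zero-width cost interval — and in this
simulated cohort gains 0.0033 QALYs over 8 weeks. Because ΔC < 0 and
ΔE > 0 the new arm dominates: it is cheaper and more effective, so no
numeric ICER is meaningful. 90.8% of bootstrap replicates fall in the
dominant (south-east) quadrant of the cost-effectiveness plane. The true
generating effect difference (0.001 QALYs) is small relative to sampling
noise at n = 47, so single cohorts scatter around it.

The same analysis from a shell:

```bash
trialcua simulate --seed 42 --out cohort.csv
trialcua analyze --cohort cohort.csv --reps 1000 --seed 42
trialcua plot-plane --cohort cohort.csv --reps 1000 --seed 42 --out plane.png
```

## Layout

- `src/trialcua/design.py` — sample size, attrition, permuted blocks
- `src/trialcua/outcomes.py` — ODI scoring, utility mapping, QALYs
- `src/trialcua/costing.py` — resource items, arm totals, currency display
- `src/trialcua/cea.py` — `CostUtilityModel` / `CEAResults`, bootstrap, plane
- `src/trialcua/trial_stats.py` — change summaries, Mann-Whitney, Friedman
- `src/trialcua/synthetic.py` — cohort generator and delimited-text I/O
- `docs/methods.md` — models, conventions, calibration and limitations
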