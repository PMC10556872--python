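# Methods

## Model and assumptions

**Day classification.** A day succeeds iff its 4th case's out-of-room time
is at or before the cutoff (default 15:45:00; the boundary instant counts as
success). The cutoff is the same clock instant on every weekday — no
adjustment for the later Wednesday start, since success is defined by the
end of the overtime-pay buffer, not by elapsed time. Spare time (successful
days) and overtime (unsuccessful days) are aggregated cohort-level; spare
minutes never offset overtime day-by-day. Overtime-cost hours are overtime
hours × the overtime rate (default 1.5).

**Per-day regression.** Each successful day gets its own OLS line of
out-of-room seconds on case number x ∈ {1..k} (1-based, k = 4 for
prediction), solved in closed form from the normal equations; with four
equally spaced abscissae, Sxx = k(k²−1)/12. No pooling, no regularisation,
no iterative optimiser: four points per day make the closed form exact, and
day-to-day heterogeneity in start time and pace is the reason each day is
its own model. The fifth-case prediction is the line at x = 5, reported to
the whole second (half-up). Distribution summaries (mean, median,
population SD) are computed on the unrounded predictions; the 95% CI of the
mean uses the normal approximation mean ± 1.96·sd/√n (Student-t available
via `mean_ci95(..., "t")`; at n ≈ 300 the difference is negligible).

**Savings formula.** OCHS(y) = T − N·x·(1−y) with x = T/n_unsuccessful kept
at full precision (for the study cohort x = 465.375/460 ≈ 1.011685 h, not
the colloquial "about an hour" — the rounded value does not reproduce the
published allocations). The formula is affine in y, zero at the realized
SSR, and equal to T at y = 1. Targets below the realized SSR return
negative savings with a warning rather than an error.

**Allocation and rounding conventions.** The daily grant is
OCHS·3600/N seconds, quantized half-up to a whole second; bi-daily and
weekly grants are exact 2× and 4× multiples *of the quantized daily grant*.
Extra-time grants are scheduled to the second, and quantizing once keeps the
three schemes mutually consistent (1364 s → 2728 s → 5456 s at a 77%
target). The end-time benchmark is the cutoff plus the grant. Per-year
conversion of cohort savings divides by the cohort's span in operating
years (default 7.5).

**Week-skip pooling.** When the weekly grant w falls short of the
full-success threshold Tₘ (the grant at which every predicted fifth case
meets its deadline), pooling c weeks funds s = ⌊c·w/Tₘ⌋ fully covered days.
The planner scans c = 1..max_cycle_weeks (default 8) and keeps the cycle
maximizing s/c, tie-breaking to the shortest cycle; the annual count is
round(weeks_per_year·s/c), half-up. Tₘ defaults to the configured value
when planning from published aggregates (135 min) and is otherwise derived
from the prediction set as (max prediction − cutoff).

**Surplus conversion.** When w ≥ Tₘ, every week hosts one guaranteed case
and the per-week surplus is truncated to whole minutes (grants are
scheduled in whole minutes) before pooling:
extra = ⌊weeks·⌊w − Tₘ⌋/mean_case_minutes⌋ with the 119-minute mean case
duration. The truncation is a scheduling convention, chosen so that
fractional per-week minutes are not treated as bankable.

## Synthetic cohort generator

The hospital dataset is not public. The generator emulates its published
statistical shape so every stage of the pipeline is testable:

    t_k = start + Σ_{j≤k} d_j,   d_j = D + b·I_slow + e_j   (minutes)

- `start`: 07:30 weekdays / 08:00 Wednesdays plus Normal jitter
  (SD 5 min) — the per-day intercept absorbs it, so it widens clock-time
  spreads without touching fit quality;
- `D ~ Normal(119, 1.4)`: the day's base pace (119 min is the published
  mean case duration);
- `e_j ~ Normal(0, 9.3·(1 + 0.30·(j−1)))`: within-day noise whose scale
  grows with case number — cumulative summation alone makes clock-time
  spread grow, but the growth factor is needed to reproduce both the
  published variance increments and the ordering of back-prediction errors
  (4th ≥ 3rd; with homoscedastic noise the 3rd-case error, a pure 2-point
  extrapolation, would dominate);
- slow days (probability 0.60) add a LogNormal(2.24, 0.55) bump to every
  case duration, producing the unsuccessful majority and the right tail of
  4th-case completions past 20:00;
- durations are clipped to [30, 600] min and times rounded to whole seconds
  with strict within-day ordering preserved.

Defaults were calibrated once (method-of-moments by simulation) against the
published cohort summaries — 39.55% SSR, all-cases per-case SDs of ~17:44
(1st) to ~42:05 (4th), per-day fit MAE near 4:45 — and frozen. A
761-day cohort under these defaults lands at SSR ≈ 0.39 ± 0.02, 1st/4th SDs
≈ 17.5/42.5 min, fit MAE ≈ 5.3 min, and back-prediction MAEs ≈ 15–16 min.

`calibrate()` re-runs that procedure for user-supplied targets: a
Sobol scan over (between-day SD, within-day SD, slow-day probability,
slow-day log-location) followed by a Nelder-Mead polish, with common random
numbers so the search is deterministic given its seed.

**What the generator does not emulate.** Case-mix, staffing, and seasonal
structure; any correlation between a day's pace and the calendar;
stage-level durations (anesthesia, turnover); and the exact shape of the
real overtime tail. Passing the synthetic-band tests shows the pipeline's
statistics behave as designed under the published summary structure — not
that the generator is a faithful model of any particular hospital. The
fixed 119-minute mean with the 30-minute-late Wednesday start also caps the
attainable synthetic SSR well below 1, so perfect-success cohorts are out
of this family's reach by construction.

## Numerical choices and degenerate inputs

- Time is integer seconds since midnight (0 ≤ t < 48 h); display rounding
  is half-up to the second, matching published values quoted to the second.
- Population SD (n divisor) throughout; configurable via `ddof` where it
  appears. At cohort sizes of hundreds of days the choice moves printed
  digits negligibly.
- Predictions outside [0, 48 h) raise — they signal pathological input, not
  a representable time.
- A cohort with no unsuccessful days has *undefined* (None) cost-hours per
  unsuccessful day, never zero; savings from such a cohort are zero.
- Constant-time (zero-slope) series fit exactly with w₁ = 0; two-point fits
  interpolate exactly with zero residual.
- Days failing validation on read (wrong row count, duplicate case numbers,
  non-monotone times, weekend dates) are dropped and logged with their id,
  never repaired; `on_invalid="raise"` makes rejection fatal.

## Design choices that were genuinely open

- **Published-figure rounding.** Exact evaluation of the savings formula at
  a 77% target gives 288.2998 h (288:17:59); the published intermediate
  rounding is not recoverable, so exact evaluation is authoritative here.
  The quantize-then-multiply allocation convention above reproduces every
  published 77% allocation and benchmark to the second; the published
  bi-daily minutes at 100% (73:21) are mutually inconsistent with their own
  benchmark (16:58:24 = cutoff + 73:24) and are treated as a typo for the
  exact 2× multiple.
- **Week-skip selection rule.** "First cycle with any funded day" would pick
  1-per-2-weeks at the 77% target; maximizing s/c picks 2-per-3-weeks,
  which is the throughput-optimal reading and matches the published plan.
- **CI method.** Normal by default, t optional; unstated in the source
  material and immaterial at these sample sizes.

## Problem sizes

The test suite simulates cohorts of 761 days (20 seeds for the band
checks), 10,000 days for convergence and parameter-recovery checks, and
1,000 random days for the OLS-oracle equivalence; the full suite runs in
well under a minute on one CPU.

## Known limitations

- The per-day line is a descriptive extrapolation: it assumes the fifth
  case resembles the day's first four, with no turnover penalty, fatigue
  effect, or staffing change. The growing per-case spread in the data
  suggests the true fifth-case spread would exceed the extrapolated one.
- No fifth-case ground truth exists; back-prediction MAE is an inferential
  proxy, and it measures interpolation-adjacent extrapolation one case
  ahead, not the 4→5 jump itself.
- The mean-duration baseline (4th time + 119 min ≤ 17:45) is included only
  as the deliberately unrealistic comparator it is: on successful days it
  is successful by construction.
- Scenario arithmetic treats saved cost-hours as a fungible annual budget;
  it ignores which weekday hosts a pooled fifth case, staffing rosters, and
  any monetary conversion.
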