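# actigap

Sensitivity analysis of nonparametric circadian rest–activity metrics to
missing actigraphy data.

Wrist actigraphy studies routinely summarize week-long activity records with
two nonparametric metrics: **intradaily variability (IV)**, which measures
rhythm fragmentation, and **interdaily stability (IS)**, which measures
day-to-day regularity. Both are computed from hourly mean activity
X₁, …, Xₙ (n = 168 for a week) with grand mean X̄:

```
IV = n · Σᵢ₌₂ⁿ (Xᵢ − Xᵢ₋₁)²  /  [(n−1) · Σᵢ (Xᵢ − X̄)²]
IS = n · Σₕ₌₁ᵖ (X̄ₕ − X̄)²    /  [p · Σᵢ (Xᵢ − X̄)²]
```

where p = 24 hour-of-day bins and X̄ₕ is the mean over days of bin h. Real
recordings contain gaps: non-wear (the device keeps logging zeros off the
wrist) and sensor dropouts (nothing is recorded at all). `actigap` quantifies
how the timing and duration of such gaps distort IV and IS, and how well three
simple imputers — linear interpolation, mean time-of-day (ToD), and median ToD
imputation — restore them. It is aimed at researchers who compute IV/IS from
epoch-level accelerometry and need to decide how much missing data is
tolerable and how to fill it.

The pipeline:

1. **synthetic** — generate week-long, midnight-aligned, 30-s epoch cohorts
   with a realistic diurnal profile (calibrated so cohort IV/IS land in the
   ranges reported for large community samples);
2. **masking** — deterministic grids of missing-data bouts: single gaps
   (1–23 h durations × 2-h start increments) and double gaps (115/140 min
   bouts, 3–47 h apart), each under two phenotypes (zeros vs. absent/NaN);
3. **imputation** — fill the bouts with linear, mean-ToD, or median-ToD
   values at epoch resolution;
4. **metrics** — IV/IS with explicit available-case rules for absent hours;
5. **evaluation** — Bland–Altman agreement (mean bias, 1.96 × SD limits,
   proportional-bias slope) per grid cell, assembled into heatmaps.

## Worked example

```python
import numpy as np
from actigap import (SyntheticConfig, generate_cohort, compute_metrics,
                     MaskSpec, run_condition, bland_altman)

cohort = generate_cohort(SyntheticConfig(seed=7), 20)
truth = compute_metrics(cohort[0])
print(f"participant 0: IV = {truth.IV:.3f}, IS = {truth.IS:.3f}")

# a 5-h gap starting 10:00 on day 2, non-wear (zero) phenotype
mask = MaskSpec("zero", (((24 + 10) * 60, 5 * 60),),
                {"start_day": 2, "start_hour": 10, "duration_h": 5})
for method in ("none", "median_tod"):
    pairs = run_condition(cohort, mask, method)
    summ = bland_altman([p[0].IS for p in pairs], [p[1].IS for p in pairs])
    print(f"{method:10s} IS bias = {summ.mean_diff:+.4f}, "
          f"LoA half-width = {summ.loa_half_width:.4f}, slope = {summ.slope:+.3f}")
```

prints

```
participant 0: IV = 1.159, IS = 0.428
none       IS bias = -0.0798, LoA half-width = 0.0438, slope = -0.183
median_tod IS bias = +0.0035, LoA half-width = 0.0384, slope = +0.055
```

A five-hour midday non-wear bout left as zeros depresses cohort IS by ~0.08 —
on the order of group differences reported between clinical and control
populations — while median-ToD imputation shrinks the bias by an order of
magnitude and keeps the limits of agreement and slope small.

The same analysis is available from the shell:

```sh
actigap simulate --n 20 --seed 7 --out cohort/
actigap run --cohort cohort/ --grid single --phenotype zero \
            --method median_tod --start-day 2 --out results.csv
actigap heatmap --results results.csv --out heatmaps.csv
actigap boutstats --cohort cohort/
```

`results.csv` holds one row per heatmap cell (start_day, start_hour,
duration_or_separation, metric, statistic, condition, value); grid cells whose
mask would run past the end of the record are empty.

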