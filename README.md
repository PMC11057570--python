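# rmrs — robust metabolic syndrome risk scoring by triangular areal similarity

Metabolic syndrome (MetS) is diagnosed dichotomously: a subject is
positive when at least 3 of 5 risk factors — fasting glucose (GL),
blood pressure (BP), triglycerides (TG), HDL-cholesterol (HDL) and
waist circumference (WC) — exceed their AHA/NHLBI cutpoints. The count
throws away severity and near-threshold information, while most
continuous alternatives (z-score composites, PCA loadings, sample-based
weights) depend on the sample they were fitted to.

This package implements the **Robust MetS Risk Score (RMRS)**, a
continuous score in [0, 1] anchored only to the diagnostic thresholds.
It is intended for epidemiologists and biostatisticians who want a
sample-independent severity score with a fixed, structurally derived
diagnostic cutoff.

## The score

1. **Axis scaling.** Each measurement x_f is normalized against its
   cutpoint d_f so the threshold maps to 0 and 10 % of the threshold is
   one unit, Z_f = (x_f − d_f)/(0.1 d_f) (sign flipped for HDL; BP uses
   the larger exceedance of systolic/diastolic over their cutpoints in
   units of 4.5 mmHg), then squashed with the Elliot sigmoid
   S = 0.5·Z/(1+|Z|) + 0.5, so that S = 0.25 / 0.5 / 0.75 at one unit
   below / at / one unit above the threshold.

2. **Triangular areal similarity (TAS).** The five axes form all
   C(5,3) = 10 three-axis radar-chart triads. For a triad with scaled
   values (x₁, x₂, x₃), with X = x₁x₂ + x₂x₃ + x₃x₁ and X′ the same sum
   after clipping each value at 0.5,

   TAS = ½ [ X / (0.75 + X − X′) + I · (4/9)(X − X′) ],

   the average of a *closeness* term (area ratio relative to the
   threshold triangle) and a *severity* term (excess area beyond it),
   where I = 1 iff all three axes are at or above threshold. An exact
   interaction-term reformulation (positive mass from supra-threshold
   axes, penalty mass from sub-threshold axes) is provided in
   `rmrs.interactions`.

3. **RMRS.** RMRS = √(mean of the 10 TAS scores) ∈ [0, 1]. The fixed
   diagnostic cutoff **0.547** is the midpoint of the minimum
   three-factor score (0.387, from three axes exactly at threshold) and
   the supremum two-factor score (0.707) — pure structure, no cohort.

## Worked example

```bash
python examples/03_simulate_and_evaluate.py
```

scores a 4,000-subject synthetic Korean-marginal cohort and prints:

```
 risk_factors    n  percent  mean    sd   min   max
            0 1163   29.075 0.245 0.060 0.123 0.500
            1 1245   31.125 0.378 0.064 0.228 0.611
            2  885   22.125 0.493 0.056 0.339 0.662
            3  478   11.950 0.608 0.045 0.492 0.723
            4  192    4.800 0.728 0.030 0.662 0.787
            5   37    0.925 0.862 0.029 0.788 0.911

Pearson r (count vs score): 0.929   adjusted R^2: 0.864
AUC vs count-based MetS:    0.989
at fixed cutoff 0.547: accuracy 0.949, recall 0.928, specificity 0.953
Youden-optimal cutoff: 0.528 (J = 0.901)
```

The mean score rises strictly with the risk-factor count, every group
stays inside its theoretical range, and the fixed 0.547 cutoff performs
close to the empirical Youden optimum. The other examples score a single
subject, reproduce the threshold derivation, and walk through the
interaction decomposition.

A thin CLI wraps the same library:

```bash
rmrs threshold                          # print the 0.387 / 0.707 / 0.547 derivation
rmrs simulate --n 1000 --seed 7 -o cohort.csv
rmrs score cohort.csv -o scored.csv --explain
rmrs evaluate scored.csv -o metrics.csv --summary-out by_count.csv --by sex
```

Input CSVs need columns glucose, sbp, dbp, triglycerides, hdl, waist
(mg/dl, mmHg, cm) and sex; region/age/race/id are optional and column
names are remappable (`rmrs.ColumnMapping`).

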