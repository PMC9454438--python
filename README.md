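# hipcongruency

Toolkit for objective radiographic assessment of canine hip congruency from
polygon annotations of ventrodorsal hip-extended radiographs.

The core quantity is the **Hip Congruency Index (HCI)**: the fraction of
the projected acetabular coverage area (AA) occupied by the femoral head,
`HCI = AAOFH / AA`, where AAOFH is the overlap area between the annotated
acetabular and femoral-head polygons. Because it is a ratio of areas on the
same projection, HCI is invariant to radiographic magnification. The
package also measures the **Norberg angle** from point landmarks, and ships
the statistical battery used to validate such measurements: paired t-test,
Bland–Altman limits of agreement, ICC(3,1) reliability, Welch's ANOVA and
the Games–Howell post hoc across severity grades (FCI categories A–E).

No pixel data is needed anywhere — everything operates on annotation
coordinates (LabelMe-style JSON).

## Modules

| module | contents |
|---|---|
| `hipcongruency.geometry` | polygon area (shoelace), robust polygon intersection (GEOS), circle discretization, closed-form circle–circle lens area, brute-force grid overlap oracle |
| `hipcongruency.metrics` | `compute_hci`, `norberg_angle`, `measure_hip`, the `HipAnnotation` record |
| `hipcongruency.annotations` | LabelMe-subset JSON reader/writer, measurements CSV I/O |
| `hipcongruency.synthetic` | parametric synthetic hips (cup + displaced disc) with oracle ground truth, graded cohorts, examiner jitter |
| `hipcongruency.agreement` | paired t-test, Bland–Altman, limits of agreement, ICC(3,1) with F-based CI and interpretation bands |
| `hipcongruency.groups` | per-grade descriptives, Shapiro–Wilk/Levene checks, Welch ANOVA, Games–Howell |
| `hipcongruency.cli` | `hipci` command-line pipeline |

## Annotation format

One LabelMe-style JSON per radiograph; only `shapes[].label/points/shape_type`
are consumed. Labels: `acetabulum_L/R` and `femoral_head_L/R` (polygons,
required per side), `fhc_L/R` (femoral head center) and `rim_L/R` (cranial
effective acetabular rim) as optional point landmarks. A file may carry one
or both sides; the Norberg angle is computed when a side has both landmarks
and the contralateral center is available.

## CLI

```sh
# generate a synthetic graded cohort with known ground truth
hipci simulate --out cohort/ --seed 1 --count-per-grade 20

# measure every annotation file (HCI + Norberg), attach grades
hipci measure --annotations cohort/ --out measurements.csv \
      --grades cohort/ground_truth.csv

# intra-/inter-examiner agreement (paired t, Bland–Altman, ICC)
hipci agreement --measurements measurements.csv --out report

# grade comparison (descriptives, Welch ANOVA, Games–Howell)
hipci compare --measurements measurements.csv --out report
```

Exit codes: 0 success, 1 validation error, 2 I/O error. Results go to
files (CSV plus a JSON report beside each); logs go to stderr. The whole
pipeline is deterministic under `--seed`.

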