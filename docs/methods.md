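# Methods

This note documents the measurement conventions, statistical models and
design decisions behind `posturemetrics`, in the order a user meets
them: coordinate frame, the postural parameters, normative charts,
reliability statistics, and the synthetic generator that backs the test
suite.

## Coordinate frame and angle primitives

All computation happens in a canonical right-handed frame: `y`
increases cranially, `x` increases toward the subject's anterior in
sagittal views and toward the subject's anatomical left in frontal and
back views. Annotation files carry image pixels; the reader flips the y
axis when `image_size` is present (image convention is y-down), mirrors
x for BACK views (a back photograph shows the subject's left on the
image left) and for sagittal views annotated with `anterior: "-x"`.

The vertical reference is the canonical +y axis. Photographic protocols
level the camera rather than define in-image verticality, so by default
image columns are taken as plumb and a QC warning records that
assumption. When an annotation supplies a two-point
`vertical_calibration` plumbline, the whole landmark set is rotated so
that pair becomes exactly vertical before any angle is computed; this
removes camera roll without touching the measurement code.

Angle primitives are exact `atan2` constructions: unsigned angle to
vertical/horizontal in [0, 90]°, signed angle to vertical (positive =
anterior deviation), and line-to-line angles either undirected
([0, 90]°) or between directions ([0, 180]°). Values are kept at full
float precision; the CLI rounds to 0.1° for display only. Degenerate
geometry (coincident landmarks) raises an error naming the landmark
pair rather than returning a number.

Because every parameter is an angle or a dimensionless ratio, no
pixel-to-centimetre calibration is needed, and all outputs are invariant
under translation and uniform scaling of the landmark set (verified by
property tests).

## Sagittal parameters

Body-contour tangents (sacral, L5–S1, T12–L1, C7–T1) are encoded as
operator-placed lower/upper point pairs — the minimal faithful encoding
of on-screen manual tangent placement; how the operator chooses the
tangent is an annotation concern, not a library one. Tangent directions
are normalized caudal→cranial before use.

* **SS** — unsigned angle of the sacral tangent to the vertical.
* **LL, TK** — the angle between the two bounding tangent directions
  (L5–S1 vs. T12–L1; T12–L1 vs. C7–T1). For a lordotic or kyphotic
  contour whose tangents lean to opposite sides of the vertical this
  equals the sum of their unsigned inclinations, matching the
  two-position differencing of a mechanical inclinometer and keeping
  values in the observed 20–60° range.
* **CI, HP** — unsigned angle to the horizontal of C7→neck-thorax
  junction and C7→ear; smaller HP means a more protracted head.
* **SPT** — signed ASIS–PSIS angle to the horizontal; positive when the
  ASIS sits caudal to the PSIS (anterior pelvic tilt). The source
  parameter is reported unsigned in the literature; the sign convention
  is this package's choice and is documented here.
* **TA, AA, EA** — signed angles between the vertical through the
  lateral malleolus and the rays to trochanter, acromion and ear;
  positive = anterior.

`compute_profile` computes whatever the present landmarks allow:
missing landmarks yield absent fields with a recorded reason, never
fabricated values — screening data is messy and a partial profile is
still useful. `bilateral_mean` averages left and right profiles
field-wise, dropping fields absent on either side.

## Coronal indices

ATSI/POTSI are sums of six sub-indices, each scaled by ×100. The
underlying verbal definitions say only "dividing by"; raw ratios would
give totals near 0.2, while screening cohorts report totals near 21, so
the conventional ×100 of the surface-topography literature is applied
and stated prominently here.

The midline is the vertical through the navel (front) or the gluteal
cleft top (back), the apparent anchors of the published diagrams; both
are encoded in the functions and documented because the verbal
definitions leave "the midline" unspecified. Height differences are
measured along the vertical axis (the other defensible choice — along
the trunk axis — is not implemented). Trunk height `e` is the vertical
distance midline-anchor→reference point (navel→sternal notch, gluteal
cleft→C7).

Limb angles (TFA at the knee, TCA at the Achilles point) are the
included angle at the vertex between the two oriented segments, 180° =
straight. A signed helper reports deviation-from-collinearity with
positive = valgus (distal point deviating laterally), using the
anatomical-left orientation of the canonical frontal frame.

## Normative percentile charts

The packaged table transcribes a published reference grid for
7-year-old girls (N = 1083): five sagittal parameters × percentiles
{3, 10, 25, 50, 75, 90, 97}, integer degrees as printed. One oddity of
the source is preserved deliberately: the LL column's median (29°) sits
well below typical LL study means (~42°); users comparing LL values
against this chart should be aware the chart is transcribed as printed,
without correction.

Placement of an individual value interpolates the percentile linearly
between bracketing knots; exact knot hits return the printed
percentile; values beyond the 3rd/97th knots are reported as the
categories `<3`/`>97` rather than extrapolated, because the charts end
there.

Cohort-built tables use the linearly interpolated empirical quantile
(numpy's default, the "type 7" definition) — the source publication
does not state its estimator, and this is the common default.
Per-age tables are kept raw: no LMS/GAMLSS smoothing across ages is
applied by default, since the reference presents independent per-age
tables; smoothing can be layered on the `chart_series` output. Strata
under 20 subjects trigger a warning (configurable floor); empty strata
are absent rather than fabricated.

## Reliability statistics

"Two-way model" ICC is resolved to **ICC(2,1)**: two-way random
effects, absolute agreement, single measurement — the standard choice
when raters are interchangeable in method studies; `form="average"`
gives ICC(2,k). The estimate comes from the two-way ANOVA mean squares

```
ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
```

with the standard F-based 95% interval (Satterthwaite denominator df).
The implementation is cross-checked in the tests against both an
independently coded explicit-loop oracle (to 1e−9) and pingouin's
`intraclass_corr`. Cronbach's alpha falls out of the same
decomposition as `1 − MSE/MSR`. The reported p-value is the two-way
ANOVA rater-effect p (the alternative reading — ICC different from
zero — is not what the rater-effect column of a reliability table
tests).

**SEM** = SD·√(1−ICC) with SD the pooled (all-ratings) between-subject
standard deviation; the classical SEM citation leaves the SD choice
open and this is the usual resolution. **Qualitative scale**: poor
≤ 0.20 < fair ≤ 0.40 < moderate ≤ 0.60 < good ≤ 0.80 < very good ≤ 1,
implemented as half-open bins so off-grid values fall in the upper bin.

**Method agreement** (e.g. photographic angle vs. inclinometer) treats
the two instruments as raters in an n×2 ICC(2,1) and reports the
Bland–Altman bias and 95% limits of agreement of the paired
differences.

**Session variability** averages replicates per subject×session,
requires a complete grid (missing cells are listed, not imputed), and
runs a one-way repeated-measures ANOVA per parameter via statsmodels'
`AnovaRM`, with Tukey HSD post hoc (the named post hoc choice here;
the source names none), plus Shapiro–Wilk residual-normality and
Levene homogeneity diagnostics. α = 0.05 throughout. When the
between-session sum of squares is exactly zero (replicated sessions)
the F statistic degenerates to 0/0 and is reported as F = 0, p = 1.

## Synthetic generator

The generator is the package's test bed: it constructs landmark sets
whose noise-free measurement returns a chosen truth exactly, then adds
i.i.d. Gaussian noise per landmark coordinate.

Sagittal construction: malleolus at the origin; trochanter, acromion
and ear on rays at TA/AA/EA at anthropometric heights (0.50/0.80/0.93
of stature); C7 placed 0.08·stature behind the ear on the HP ray;
tangent pairs at the inclinations that reproduce SS, LL, TK, with LL
split symmetrically about the vertical between its two tangents (the
split is overridable) and the T12–L1 tangent shared between LL and TK —
mirroring the inclinometer differencing scheme. Truths whose implied
tangent inclinations leave (−90°, 90°) raise a construction error.
Default truth means and SDs (SS 24.7 ± 7.0, LL 41.7 ± 9.5, TK
44.5 ± 6.7, CI 27.1 ± 7.1, HP 53.3 ± 3.1; trunk indices ≈ 21) are
chart/screening-cohort magnitudes for healthy 7–10-year-olds, chosen so
default fixtures are realistic; they are parameters, not constraints.

Rating studies follow the additive variance-component model
`value = μ + subject + rater + session + ε` with independent Gaussian
components, so the downstream ICC has the known target
σ²s/(σ²s + σ²r + σ²e); cohort generation draws per-stratum Gaussians
for percentile-table construction. All generators accept a seed or
shared `numpy` Generator and are bit-reproducible.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real photographs: correlated contour
noise (a mis-levelled tangent moves both of its points together),
operator bias in landmark placement, perspective and lens distortion,
postural sway between exposures, and any non-Gaussian tail behaviour.
Tests demonstrate that the formulas are implemented correctly and that
the statistics are calibrated under their stated models, not that the
photographic protocol itself achieves any particular reliability.

## Problem sizes and numerical choices

Property suites use 500 random truths for the construction identity
(recovery ≤ 0.01°, observed ~1e−13), 200 matrices for the ICC algebra
check (≤ 1e−9), 500 replicates for variance-component calibration
(within 0.02 of target), and 1000 null replicates for the session-ANOVA
type-I calibration ([3.5%, 6.5%] at α = 0.05) — sizes at which the
Monte-Carlo error is comfortably inside each tolerance while the whole
suite stays quick on a single CPU. Ties at percentile knots resolve to
the lowest matching percentile; angles are compared at 1e−8–1e−9°
internally, reflecting pure floating-point constructions.

## Known limitations

* The packaged normative grid covers a single stratum (girls, age 7);
  other sex/age strata must be supplied or built from a cohort.
* Tangent placement quality is entirely the annotator's; the library
  measures whatever pairs it is given.
* HDI height differences use the vertical axis; a trunk-axis variant is
  not provided.
* The published reliability tables of the source studies cannot be
  recomputed here (raw ratings unpublished); the statistics are instead
  validated by construction on synthetic data with known components.
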