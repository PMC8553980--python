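# Methods

## The measurement model

A drawing session is an ordered list of pen strokes; each stroke is a
polyline of (x, y, t) samples at the pen's stated resolution (±0.5 mm,
12 ms). All geometry is computed in page millimetres with the origin at
the top-left corner and y increasing downward; time zero is the first
pen-down of the session. These conventions are load-bearing: "vertical
spatial placement" is the face-centre offset from the page's vertical
midline in this frame, and every speed is mm/s in it.

Sessions are assumed complete (no between-session gap is modelled) and
single-page. Pen pressure and tilt are not modelled.

### Metric definitions

Where a published operational definition exists it is implemented
directly: total time is first pen-down to last pen-up; ink length is the
summed polyline arc length of all strokes; latencies are the pen-up gaps
between consecutive strokes inside that window (mean, sample SD, max);
percent ink time is the summed stroke duration over total time (think
time is its complement — the identity holds to 1e-6 by construction);
drawing-process efficiency is ink length / total time, which lands on the
printed scale of that measure; drawing size is the diameter of the
algebraic least-squares (Kåsa) circle fit of the clock-face samples —
a diameter, because ~80 mm is a plausible diameter on Letter paper and an
implausible radius.

Five metrics have no published formula and are **versioned stand-ins**
(registry `v1`, swappable without touching the scoring layer):

- *clock-face circularity*: mean absolute radial residual of the circle
  fit (mm);
- *oscillatory motion*: mean absolute second difference of the pen
  heading per unit arc length over the face, ×100;
- *component placement*: RMS angular error (radians) of digit centroids
  vs their canonical clock positions and hand directions vs the 11:10
  targets (hour 335°, minute 60°);
- *relative long latency*: mean of latencies at/above their 90th
  percentile over the mean latency;
- *noise*: (noise + cross-out + overwrite ink)/(total ink), offset by
  0.39 so a clean drawing sits at the normative floor ≈ 0.40.

These stand-ins are contract-compatible (same units-scale and direction)
but are **not** calibration targets; only their ordering between cohorts
and approximate scale is meaningful. Speeds are computed over the face
group only, from centred finite differences after a 3-sample moving
average; initiation/termination speeds average the first/last 120 ms.
The long-latency threshold defaults to 3× a configurable normative
reference latency (0.7 s); the published normative standard is not
disclosed, so this constant is a package choice.

Metrics whose prerequisites are absent (e.g. no face resolved) are NaN
and listed in `MetricRecord.missing`, never silently zero; the scoring
layer imputes them at the impaired-direction 5th percentile of training
data, on the view that a missing face is itself informative of severity.

## Symbol classification

Strokes are agglomerated greedily: the closest pair of groups merges
while centroid distance < 6 mm AND temporal gap < 1.5 s; the
largest-perimeter near-closed stroke is seeded as the face candidate and
excluded from merging. A second pass splits any group that matches no
digit glyph template (distance > 0.15) at the temporal split point that
makes both halves match well (< 0.25 and clearly better than unsplit) —
this recovers adjacent symbols over-merged under placement jitter. The
6 mm default reflects the geometry of two-character digits ("10"–"12"),
whose character centroids sit ~0.42–0.47 glyph-heights apart.

The default shape scorer is rule-based: geometric features (closure,
circle-fit residual, elongation, radial position in the face frame,
length, onset time, bbox overlap with other groups) plus template
matching against the package's own digit glyph font, combined into
calibrated-ish probabilities over 18 labels (face, digits 1–12, hour and
minute hand, noise, cross-out, overwrite). Any object mapping groups to
simplex vectors can be plugged in; `fit_shape_scorer` trains a
standardized multinomial logistic model over the same features.

Resolution is exact, not heuristic: one label per group maximizing total
log-probability subject to ≤1 face, each digit value ≤1, ≤1 hour and ≤1
minute hand, with noise/cross-out/overwrite repeatable — a rectangular
assignment problem (groups × unique labels + per-group slack), solved
optimally. Group counts are small (≤ ~40), and exactness gives a
brute-force-checkable contract (tested). If both hands resolve, the
shorter is relabelled the hour hand. Ambiguity below a 0.2 probability
margin sets a per-group low-confidence flag rather than invoking any
third-rater analogue. Unsatisfiable structure degrades to repeatable
labels with a warning, never an exception.

## The synthetic test bed

The generator emulates two cohorts whose extracted metric distributions
reproduce a published normative table of medians and IQRs. Its defaults
ARE those study conditions; the calibration table
(`clockdraw/data/calibration.csv`) is plain CSV so users can re-anchor it.

Construction, per drawing:

1. **Headline draws.** Total time, face diameter, and total ink length are
   lognormal (right-skewed, median < mean, matching the printed
   median-vs-IQR pattern); the think-time fraction is logit-normal. Shape
   parameters come from the printed quartiles (σ = ln(q3/q1)/1.349). Ink
   is sampled as π·D·(ink ratio) so it co-varies with drawing size and the
   glyph budget below stays positive.
2. **Geometry.** The face is a near-closed circle with a low-order radial
   harmonic (amplitude π/2 × the circularity target, since
   mean|a·sin| = 2a/π) plus a high-frequency tremor term; digits are
   rendered from a stylized single-line glyph font (stroke counts chosen
   so the full template — face + 12 digits + 2 hands — has 24 strokes)
   at canonical clock angles with Gaussian angular/radial jitter; hands
   run from near the centre toward the 11:10 targets with angular jitter.
   The glyph scale is solved from the ink budget
   (ink − face − hands − noise strokes), so total ink length emerges
   equal to its sampled target up to resampling loss (~0.3%).
3. **Timing.** Ink time = (1 − think fraction) × total time; the face is
   drawn at a lognormal average speed with a bell-shaped profile whose
   peak reproduces the max/average speed ratio; remaining strokes share
   the remaining ink time proportionally to length. Think time is divided
   across the 23 inter-stroke gaps: one designated long pause (lognormal
   at the longest-latency target) and short within-/between-symbol gaps,
   all rescaled so they sum exactly to the think time. Hence average
   latency ≈ think time / 23-ish by construction, and the think/ink
   complement identity is exact.
4. **Impairment is a parameter vector**, not a switch: the impaired
   calibration column sets slower speeds, longer times, smaller/rougher
   faces, larger jitters, and higher rates of the unexpected-stroke
   processes (Poisson-rate noise marks outside the rim, overwritten
   digits, cross-outs, digit omissions). Graded severities can be
   simulated by interpolating rows.

Per-subject seeds derive from a master `SeedSequence`; identical seeds
reproduce sessions bit-for-bit.

### Calibration procedure and closure

Most table cells are matched *by construction* (sampled directly or
emergent through exact identities). Two latency constants — the raw
between-symbol pause median and the within-symbol pause scale — were
obtained by a one-time solve of the think-time budget equation given the
template's gap counts (9 within-symbol, 14 between-symbol). Closure is
verified empirically: 2,000 drawings per cohort/condition reproduce the
anchored medians (total time, ink length, drawing size, percent think
time, average and longest latency) within 3–5%.

The generator does **not** emulate: handwriting-realistic digit shapes
(glyphs are rigid templates — real glyph-shape variability would stress
the template scorer far more), correlated metric structure beyond what
the shared headline draws induce (real metrics correlate through the
subject), specific diagnoses (no Parkinsonian tremor spectrum, no
hemispatial neglect), or age/education effects. Consequently, passing
tests establish internal consistency of generator + extractor + scorer
and algorithmic correctness — not clinical accuracy; discrimination
figures on synthetic cohorts (AUC ≈ 1) exceed anything attainable on
real, overlapping populations. The impaired ink-length IQR is slightly
narrower than printed: the printed ink IQR ratio for that column is
narrower than the drawing-size IQR ratio it must compose with, so the
ratio dispersion is floored (the median is still matched).

## Scoring layer

Composites are fitted per functional group × condition by
Lasso-regularized logistic regression (liblinear), features standardized
on unimpaired training statistics, penalty chosen by stratified 5-fold
cross-validated log-loss over a small grid — deterministic given the
seed. The linear predictor is negated (so higher = less impaired) and
standardized to the unimpaired training cohort; a composite whose
coefficients are all zeroed by the penalty is constant at 0. The top
model is L1 logistic over the eight composites;
score = 100 × (1 − p̂) clipped to [0, 100] — the published construction
bounds the score in [0, 100] with higher = better but does not state the
mapping, so this choice is the package's. Command and Copy composites are
fitted and standardized separately. Single-condition scoring imputes the
missing condition's composites at 0 (the unimpaired mean) and flags the
result.

Cut scores: the impaired cutoff maximizes the Youden index (ties broken
toward the midpoint of the maximizing interval, so a separable toy yields
the interval midpoint); the indeterminate cutoff ships as the fixed
externally anchored value 75 — the original value was matched to an
established screening cutoff on an instrument we do not model — with a
capture-rate mode (smallest cutoff under which a target fraction of
impaired subjects scores below it) as the generalization.

## Statistics

AUC follows the Mann–Whitney pair convention with midranks everywhere,
which keeps AUC, the rank-sum U and the DeLong structural components
mutually consistent under ties. DeLong's test is implemented from
structural components (it exists in neither scipy nor scikit-learn); its
variance is validated against a bootstrap in the tests. Rank-sum uses
exact enumeration for n ≤ 12 without ties, otherwise the tie-corrected
normal approximation with continuity correction; Holm adjustment and the
Fisher-z correlation interval are delegated to statsmodels/scipy. All
p-values are two-sided.

## Numerical choices and degenerate inputs

- Circle fit: Kåsa algebraic least squares; < 3 points or collinear
  input raises. Radial noise of 0.1 mm on 100 points biases the radius
  < 0.05 mm (tested by Monte Carlo).
- Latencies clipped at 0 (overlapping strokes would otherwise go
  negative; validation reports such sessions).
- A group with a single sample receives a noise-dominated prior, never
  an exception; empty sessions raise.
- Ties in Youden cutoffs: piecewise-constant J evaluated per interval
  between observed scores; the first maximal run's midpoint is returned.
- Composite scale guard: SD floors at 1e-9 so constant composites do not
  divide by zero.

## Problem sizes

The shipped verification uses 2,000 drawings per cohort/condition for
calibration closure, 200 subjects (400 drawings) for stroke-label
recovery, and 912/921 train/test subjects for the end-to-end
discrimination check — sizes at which the sample-median standard error
(≈ 0.9% for total time at n = 2,000) is well inside the closure
tolerances.
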