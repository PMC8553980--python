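# clockdraw

Analysis of the **digitized Clock Drawing Test** (CDT): from time-stamped
pen strokes — a subject draws a clock showing 11:10 from instruction
(*Command*) and then copies a pre-drawn clock (*Copy*) — to an
automatically scored, clinically interpretable assessment of cognitive
performance.

The package is aimed at researchers working with digitizing-pen CDT data
(or building methods for it): it provides the full analysis chain plus a
calibrated synthetic-drawing generator, so every stage is testable end to
end without access to restricted clinical cohorts.

## What it does

1. **Ink model** (`clockdraw.ink`) — pen-stroke domain types and lossless
   I/O (CSV, JSON, InkML subset). Coordinates in mm (origin top-left,
   y down), time in ms, 12-ms sampling.
2. **Symbol classification** (`clockdraw.classify`) — a multi-pass rules
   pipeline: spatio-temporal stroke grouping, a template-based split
   refinement pass, a pluggable shape scorer (geometric features + digit
   glyph templates, or a fitted shallow classifier), and an exact
   constraint pass (one face, unique digit values, two hands) solved as an
   assignment problem.
3. **Drawing metrics** (`clockdraw.metrics`) — the process/final-drawing
   metric catalogue: total time, think/ink time split, inter-stroke
   latencies, face-only pen speeds, oscillatory motion, least-squares
   (Kåsa) face-circle size and circularity, component placement, page
   position, stroke-count conformity, unexpected-ink "noise".
4. **Hierarchical scoring** (`clockdraw.scoring`) — per functional group
   (drawing efficiency, information processing, simple & complex motor,
   spatial reasoning) × condition, a composite scale is learnt by
   **Lasso-regularized logistic regression** on impaired vs unimpaired
   training subjects, standardized to the unimpaired cohort (mean 0, SD 1,
   higher = better). The eight composites are combined by L1-regularized
   logistic regression into a 0–100 overall score:
   `score = 100 × (1 − p̂)`, with `p̂` the predicted impairment
   probability; cut scores 60 (impaired) and 75 (indeterminate), the
   lower one selected by the Youden index `J = sensitivity + specificity − 1`.
5. **Validation statistics** (`clockdraw.stats`) — ROC/AUC (Mann–Whitney
   convention with midranks), DeLong's paired test for correlated AUCs,
   Wilcoxon rank-sum, Bonferroni–Holm adjustment, Kruskal–Wallis, Pearson
   correlations with Fisher-z intervals.
6. **Synthetic cohorts** (`clockdraw.simulate`) — a seeded generator of
   labeled Command/Copy drawings for a cognitively unimpaired and a
   cognitively impaired cohort, calibrated so the extracted metric
   distributions reproduce published normative medians/IQRs (the
   calibration lives in an editable CSV, `clockdraw/data/calibration.csv`).

## Worked example

```python
import numpy as np
import clockdraw as cd
from clockdraw.metrics import compute_metrics, metrics_table
from clockdraw.stats import roc_curve
from clockdraw.scoring import youden_cutoff

subs = cd.generate_cohort(200, 0.42, seed=0)           # synthetic cohort
rows, labels = [], []
for s in subs:
    cmd = compute_metrics(cd.classify_drawing(s.record.command))
    cop = compute_metrics(cd.classify_drawing(s.record.copy))
    rows.append((s.record.subject_id, cmd, cop))
    labels.append(s.record.label)
table = metrics_table(rows)

res = cd.ClockScoringModel(table, labels).fit(seed=0)   # Model -> Results
one = res.score_subject(rows[0][1], rows[0][2], subject_id=rows[0][0])
print(one.score, one.classification)

scores = res.score_table(table)["score"]
print(roc_curve(scores, np.array(labels) == "unimpaired").auc)
print(youden_cutoff(scores, np.array(labels) == "impaired"))
```

prints (abridged):

```
subject: s00000 | true label: unimpaired
score: 100.0 -> unimpaired
  command.drawing_efficiency          -0.19
  command.information_processing      +1.05
  command.simple_complex_motor        -0.69
  command.spatial_reasoning           +0.60
training AUC: 1.0
Youden cutoff 49.7: sensitivity 1.00, specificity 1.00
cmd total_time median: 35.85 s
```

The subject's overall score (100.0, above the 75 cutoff → unimpaired)
decomposes into the eight composites (units: unimpaired-training SDs;
negative = worse than the unimpaired mean), which in turn decompose into
the individual metrics — the same hierarchy a clinician reads. On cleanly
separated synthetic cohorts the training AUC saturates; real cohorts
overlap far more.

There is also a CLI (`clockdraw simulate|classify|metrics|train|score|
validate|report|run`); `clockdraw run --seed 3 --out runs/demo` executes
the whole pipeline into one artifact directory with a reproducibility
manifest.

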