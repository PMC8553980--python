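"""Hierarchical composite scoring of clock-drawing metrics.

The scoring model mirrors the clinical construction: for each of four
functional groups (drawing efficiency, information processing, simple and
complex motor, spatial reasoning) and each condition (Command, Copy), a
composite scale is learnt by Lasso-regularized logistic regression
discriminating impaired from unimpaired training subjects; the eight
composites are then combined by L1-regularized logistic regression into an
overall 0-100 clock score (higher = better), with cut scores at 60
(impaired) and 75 (indeterminate) by default.

Composites are standardized against the unimpaired training subjects
(mean 0, SD 1, oriented so higher = less impaired), which makes the
hierarchy interpretable: a low overall score traces to low composites,
which trace to individual metrics.

Usage follows the Model/Results idiom::

    model = ClockScoringModel(metrics_df, labels)
    res = model.fit(seed=0)
    print(res.summary())
    scored = res.score_table(test_metrics_df)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .metrics import MetricRecord, metrics_table

__all__ = [
    "FUNCTIONAL_GROUPS",
    "CompositeModel",
    "TopModel",
    "ClockScoringModel",
    "ClockScoringResults",
    "ClockScore",
    "youden_cutoff",
    "indeterminate_cutoff",
]

#: Functional-group membership of each metric (the group composites
#: themselves sit above these members).
FUNCTIONAL_GROUPS: dict[str, list[str]] = {
    "drawing_efficiency": [
        "stroke_count_conformity", "total_time", "ink_length", "drawing_size",
        "drawing_process_efficiency", "noise",
    ],
    "information_processing": [
        "percent_think_time", "average_latency", "latency_variability",
        "relative_long_latency", "long_latency_count", "longest_latency",
    ],
    "simple_complex_motor": [
        "percent_ink_time", "average_speed", "max_speed", "initiation_speed",
        "termination_speed", "oscillatory_motion",
    ],
    "spatial_reasoning": [
        "clock_face_circularity", "component_placement", "vertical_spatial_placement",
    ],
}

CONDITIONS = ("command", "copy")
DEFAULT_CUTOFFS = (60.0, 75.0)


@dataclass
class CompositeModel:
    """One fitted group x condition composite scale."""

    group: str
    condition: str
    feature_names: list[str]
    impute_values: list[float]  # impaired-direction 5th-percentile fill-ins
    center: list[float]  # unimpaired training means
    scale: list[float]   # unimpaired training SDs
    coef: list[float]
    intercept: float
    comp_center: float   # unimpaired training mean of the linear predictor
    comp_scale: float
    sign: float          # orientation: higher composite = less impaired
    penalty_c: float

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.feature_names].to_numpy(dtype=float).copy()
        for j, fill in enumerate(self.impute_values):
            col = Z[:, j]
            col[~np.isfinite(col)] = fill
        Z = (Z - np.asarray(self.center)) / np.asarray(self.scale)
        lin = Z @ np.asarray(self.coef) + self.intercept
        return self.sign * (lin - self.comp_center) / self.comp_scale


@dataclass
class TopModel:
    """L1-logistic combination of the eight composites into the 0-100 score."""

    composite_names: list[str]
    coef: list[float]
    intercept: float
    penalty_c: float

    def impairment_probability(self, composites: pd.DataFrame) -> np.ndarray:
        Z = composites[self.composite_names].to_numpy(dtype=float)
        Z = np.nan_to_num(Z, nan=0.0)  # missing condition: composite imputed at 0
        lin = Z @ np.asarray(self.coef) + self.intercept
        return 1.0 / (1.0 + np.exp(-lin))

    def score(self, composites: pd.DataFrame) -> np.ndarray:
        return np.clip(100.0 * (1.0 - self.impairment_probability(composites)), 0.0, 100.0)


@dataclass
class ClockScore:
    """The scored hierarchy for one subject."""

    subject_id: str
    score: float
    classification: str  # impaired | indeterminate | unimpaired
    composites: dict[str, float]
    metrics: dict[str, float]
    flags: list[str] = field(default_factory=list)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        return (y == "impaired").astype(int)
    return y.astype(int)


def _l1_logistic_cv(X, y, Cs, cv, seed) -> tuple[LogisticRegression, float]:
    """Penalty chosen by stratified CV log-loss; deterministic given seed."""
    best_c, best_loss = Cs[0], np.inf
    if cv and cv > 1:
        folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        for C in Cs:
            losses = []
            for tr, te in folds.split(X, y):
                m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                       random_state=seed, max_iter=500)
                m.fit(X[tr], y[tr])
                losses.append(log_loss(y[te], m.predict_proba(X[te])[:, 1], labels=[0, 1]))
            loss = float(np.mean(losses))
            if loss < best_loss - 1e-9:
                best_loss, best_c = loss, C
    model = LogisticRegression(l1_ratio=1.0, C=best_c, solver="liblinear",
                               random_state=seed, max_iter=500)
    model.fit(X, y)
    return model, float(best_c)


class ClockScoringModel:
    """Hierarchical scoring model built from a tidy metric table.

    Parameters
    ----------
    metrics
        One row per subject; columns ``command.<metric>`` / ``copy.<metric>``
        as produced by :func:`clockdraw.metrics.metrics_table`.
    labels
        Per-subject cohort labels ("impaired"/"unimpaired" or 1/0, aligned
        with ``metrics`` rows).
    """

    def __init__(self, metrics: pd.DataFrame, labels):
        self.metrics = metrics
        self.y = _as_binary(labels)
        if len(self.y) != len(metrics):
            raise ValueError("labels and metrics must align")
        counts = np.bincount(self.y, minlength=2)
        if counts.min() < 20:
            raise ValueError(
                f"need >= 20 subjects per class, got {counts[1]} impaired / {counts[0]} unimpaired")

    @classmethod
    def from_records(
        cls,
        records: Sequence[tuple[str, MetricRecord, MetricRecord]],
        labels,
    ) -> "ClockScoringModel":
        return cls(metrics_table(list(records)), labels)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        *,
        Cs: Sequence[float] = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0),
        cv: int = 5,
        seed: int = 0,
        cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    ) -> "ClockScoringResults":
        y = self.y
        unimp = y == 0
        comps: list[CompositeModel] = []
        for cond in CONDITIONS:
            for group, members in FUNCTIONAL_GROUPS.items():
                feats = [f"{cond}.{m}" for m in members if f"{cond}.{m}" in self.metrics.columns]
                if not feats:
                    continue
                X = self.metrics[feats].to_numpy(dtype=float).copy()
                impute, center, scale = [], [], []
                for j, f in enumerate(feats):
                    col = X[:, j]
                    finite = np.isfinite(col)
                    if not finite.any():
                        raise ValueError(f"feature {f} is entirely missing")
                    med_u = np.nanmedian(col[finite & unimp])
                    med_i = np.nanmedian(col[finite & (y == 1)])
                    q = 95.0 if med_i >= med_u else 5.0
                    fill = float(np.percentile(col[finite], q))
                    col[~finite] = fill
                    impute.append(fill)
                    c = float(col[unimp].mean())
                    s = float(col[unimp].std(ddof=0))
                    center.append(c)
                    scale.append(max(s, 1e-9))
                Z = (X - np.array(center)) / np.array(scale)
                model, best_c = _l1_logistic_cv(Z, y, list(Cs), cv, seed)
                lin = Z @ model.coef_[0] + model.intercept_[0]
                # orient so higher = less impaired
                sign = -1.0  # linear predictor points toward impairment
                cc = float(lin[unimp].mean())
                cs = max(float(lin[unimp].std(ddof=0)), 1e-9)
                comps.append(CompositeModel(
                    group, cond, feats, impute, center, scale,
                    list(model.coef_[0]), float(model.intercept_[0]),
                    cc, cs, sign, best_c))

        comp_df = pd.DataFrame(
            {f"{m.condition}.{m.group}": m.transform(self.metrics) for m in comps},
            index=self.metrics.index)
        Xc = comp_df.to_numpy(dtype=float)
        top_fit, top_c = _l1_logistic_cv(Xc, y, list(Cs), cv, seed)
        top = TopModel(list(comp_df.columns), list(top_fit.coef_[0]),
                       float(top_fit.intercept_[0]), top_c)
        return ClockScoringResults(self, comps, top, cutoffs, seed)


class ClockScoringResults:
    """Fitted scoring hierarchy: composites, top model, cut scores."""

    def __init__(self, model: Optional[ClockScoringModel], composites, top, cutoffs, seed):
        self.model = model
        self.composite_models: list[CompositeModel] = composites
        self.top_model: TopModel = top
        self.cutoffs = tuple(cutoffs)
        self.seed = seed

    # -- prediction -------------------------------------------------------

    def predict_composites(self, metrics: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {f"{m.condition}.{m.group}": m.transform(metrics) for m in self.composite_models},
            index=metrics.index)

    def classify(self, score: np.ndarray) -> np.ndarray:
        lo, hi = self.cutoffs
        return np.where(score < lo, "impaired", np.where(score < hi, "indeterminate", "unimpaired"))

    def score_table(self, metrics: pd.DataFrame) -> pd.DataFrame:
        comps = self.predict_composites(metrics)
        score = self.top_model.score(comps)
        out = comps.copy()
        out.insert(0, "score", score)
        out.insert(1, "classification", self.classify(score))
        return out

    def score_subject(
        self,
        command: Optional[MetricRecord],
        copy: Optional[MetricRecord],
        subject_id: str = "subject",
    ) -> ClockScore:
        """Score one subject, carrying the full metric -> composite ->
        score hierarchy; a missing condition is flagged and its composites
        imputed at 0."""
        flags = []
        if command is None or copy is None:
            flags.append("single-condition scoring: missing condition imputed at 0")
        df = metrics_table([(subject_id, command, copy)])
        comps = self.predict_composites(df.reindex(
            columns=[f for m in self.composite_models for f in m.feature_names],
            fill_value=math.nan))
        score = float(self.top_model.score(comps)[0])
        rec_flags = []
        for rec in (command, copy):
            if rec is not None and rec.missing:
                rec_flags.extend(f"{rec.condition}.{m} imputed" for m in sorted(rec.missing))
        return ClockScore(
            subject_id=subject_id,
            score=score,
            classification=str(self.classify(np.array([score]))[0]),
            composites={k: float(v) for k, v in comps.iloc[0].items()},
            metrics={k: float(v) for k, v in df.iloc[0].items()},
            flags=flags + rec_flags,
        )

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        lines = ["Clock scoring model", "=" * 60]
        lines.append(f"cut scores: impaired < {self.cutoffs[0]:g} <= indeterminate < {self.cutoffs[1]:g} <= unimpaired")
        lines.append("")
        lines.append("Top model (L1 logistic over 8 composites):")
        for name, c in zip(self.top_model.composite_names, self.top_model.coef):
            lines.append(f"  {name:40s} {c:+9.4f}")
        lines.append(f"  {'intercept':40s} {self.top_model.intercept:+9.4f}")
        for m in self.composite_models:
            lines.append("")
            lines.append(f"Composite {m.condition}.{m.group} (C={m.penalty_c:g}):")
            for f, c in zip(m.feature_names, m.coef):
                if c != 0.0:
                    lines.append(f"  {f:40s} {c:+9.4f}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "format": "clockdraw-model-bundle-v1",
            "seed": self.seed,
            "cutoffs": list(self.cutoffs),
            "metric_registry": "v1",
            "composites": [asdict(m) for m in self.composite_models],
            "top": asdict(self.top_model),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ClockScoringResults":
        doc = json.loads(Path(path).read_text())
        comps = [CompositeModel(**m) for m in doc["composites"]]
        top = TopModel(**doc["top"])
        return cls(None, comps, top, tuple(doc["cutoffs"]), doc.get("seed"))


# ---------------------------------------------------------------------------
# Cut scores
# ---------------------------------------------------------------------------


def _j_stats(scores: np.ndarray, impaired: np.ndarray, cutoff: float):
    sens = float((scores[impaired] < cutoff).mean())
    spec = float((scores[~impaired] >= cutoff).mean())
    return sens, spec


def youden_cutoff(scores, labels) -> tuple[float, float, float]:
    """Cut score maximizing the Youden index J = sensitivity + specificity - 1.

    Subjects scoring below the cutoff are classified impaired.  J is
    piecewise constant between observed scores; ties are broken toward the
    midpoint of the maximizing interval.
    Returns (cutoff, sensitivity, specificity).
    """
    y = _as_binary(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    uniq = np.unique(s)
    span = max(uniq[-1] - uniq[0], 1.0)
    edges = np.concatenate([[uniq[0] - 0.05 * span], uniq, [uniq[-1] + 0.05 * span]])
    mids = (edges[:-1] + edges[1:]) / 2.0  # one candidate per interval
    js = np.array([sum(_j_stats(s, y, c)) - 1.0 for c in mids])
    best = js.max()
    tied = np.flatnonzero(js >= best - 1e-12)
    # merge the first contiguous run of tied intervals
    run_end = tied[0]
    while run_end + 1 in tied:
        run_end += 1
    lo, hi = edges[tied[0]], edges[run_end + 1]
    cutoff = (lo + hi) / 2.0
    sens, spec = _j_stats(s, y, cutoff)
    return float(cutoff), sens, spec


def indeterminate_cutoff(scores, labels, reference_spec: float = 75.0) -> float:
    """Upper (indeterminate) cut score.

    ``reference_spec`` > 1 is taken as a fixed externally anchored cutoff
    (default 75, matched to an established screening cutoff).  A value in
    (0, 1] is a target capture rate: the smallest cutoff under which that
    fraction of impaired subjects scores below the cutoff.
    """
    if reference_spec > 1.0:
        return float(reference_spec)
    if not 0.0 < reference_spec <= 1.0:
        raise ValueError("specificity target must be in (0, 1]")
    y = _as_binary(labels).astype(bool)
    s = np.asarray(scores, dtype=float)
    imp = np.sort(s[y])
    if imp.size == 0:
        raise ValueError("no impaired subjects")
    k = int(math.ceil(reference_spec * imp.size))
    # smallest cutoff strictly above the k-th impaired score
    return float(np.nextafter(imp[k - 1], np.inf))
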