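"""Stroke-to-symbol classification for clock drawings.

Maps pen strokes to clock symbols (clock face, digits 1-12, hour/minute
hands) or to unexpected marks (noise, cross-outs, overwriting) in three
passes:

1. :func:`group_strokes` — greedy spatio-temporal agglomeration of strokes
   into candidate symbol groups, with the largest near-closed stroke seeded
   as the clock-face candidate;
2. :func:`score_shapes` — a pluggable shape scorer turns each group into a
   probability vector over the 18 symbol labels.  The default
   :class:`TemplateShapeScorer` combines geometric features (closure,
   elongation, radial position, size) with template matching against the
   package's digit glyphs; :func:`fit_shape_scorer` trains a shallow
   feature-based multinomial classifier honoring the same contract;
3. :func:`resolve_labels` — a constraint pass assigning one label per group
   (at most one face, each digit value used once, at most two hands) by an
   exact assignment-problem solve maximizing total log-probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._glyphs import digit_strokes, resample_polyline
from .ink import Condition, DrawingSession, Stroke
from .labels import LABEL_SPACE, SymbolKind, SymbolLabel, label_index
from .simulate import GroundTruth

__all__ = [
    "SymbolGroup",
    "ClassifiedDrawing",
    "ShapeScorer",
    "TemplateShapeScorer",
    "FittedShapeScorer",
    "group_strokes",
    "score_shapes",
    "resolve_labels",
    "classify_drawing",
    "fit_shape_scorer",
    "classified_from_truth",
]

D_MERGE_MM = 6.0
T_MERGE_S = 1.5

_N_LABELS = len(LABEL_SPACE)
_FACE_I = label_index(SymbolLabel(SymbolKind.CLOCK_FACE))
_HOUR_I = label_index(SymbolLabel(SymbolKind.HOUR_HAND))
_MIN_I = label_index(SymbolLabel(SymbolKind.MINUTE_HAND))
_NOISE_I = label_index(SymbolLabel(SymbolKind.NOISE))
_CROSS_I = label_index(SymbolLabel(SymbolKind.CROSS_OUT))
_OVER_I = label_index(SymbolLabel(SymbolKind.OVERWRITE))
_DIGIT_I = {v: label_index(SymbolLabel(SymbolKind.DIGIT, v)) for v in range(1, 13)}


@dataclass
class SymbolGroup:
    """A candidate symbol: an ordered set of stroke indices."""

    stroke_indices: tuple[int, ...]
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1
    centroid: tuple[float, float]
    t_on: float  # ms
    t_off: float  # ms

    @classmethod
    def from_strokes(cls, indices: Sequence[int], strokes: Sequence[Stroke]) -> "SymbolGroup":
        idx = tuple(sorted(indices))
        xs = np.concatenate([strokes[i].x for i in idx])
        ys = np.concatenate([strokes[i].y for i in idx])
        return cls(
            stroke_indices=idx,
            bbox=(float(xs.min()), float(ys.min()), float(xs.max()), float(ys.max())),
            centroid=(float(xs.mean()), float(ys.mean())),
            t_on=min(strokes[i].start_t for i in idx),
            t_off=max(strokes[i].end_t for i in idx),
        )


def _closure(st: Stroke) -> float:
    L = st.length_mm
    if L <= 0:
        return 1.0
    gap = math.hypot(st.x[-1] - st.x[0], st.y[-1] - st.y[0])
    return gap / L


def _face_seed(strokes: Sequence[Stroke]) -> Optional[int]:
    """Largest-perimeter near-closed stroke, if clearly the face."""
    best, best_len = None, 0.0
    for i, st in enumerate(strokes):
        L = st.length_mm
        if L > best_len and L > 40.0 and _closure(st) < 0.25:
            best, best_len = i, L
    return best


def group_strokes(
    session: DrawingSession,
    d_merge: float = D_MERGE_MM,
    t_merge: float = T_MERGE_S,
) -> list[SymbolGroup]:
    """Greedy agglomeration: merge the closest pair of groups whose centroid
    distance is < ``d_merge`` mm AND whose temporal gap is < ``t_merge`` s,
    until no pair qualifies.  The face-candidate stroke never merges."""
    strokes = session.strokes
    if not strokes:
        raise ValueError("empty session")
    face = _face_seed(strokes)
    members: list[list[int]] = [[i] for i in range(len(strokes))]
    cents = np.array([s.centroid for s in strokes])
    weights = np.array([len(s) for s in strokes], dtype=float)
    spans = np.array([[s.start_t, s.end_t] for s in strokes]) / 1000.0

    def tgap(a: int, b: int) -> float:
        lo = max(spans[a][0], spans[b][0])
        hi = min(spans[a][1], spans[b][1])
        return max(lo - hi, 0.0)

    active = set(range(len(strokes)))
    while True:
        best_pair, best_d = None, d_merge
        act = sorted(active)
        for ii, a in enumerate(act):
            if a == face:
                continue
            for b in act[ii + 1:]:
                if b == face:
                    continue
                d = math.hypot(cents[a, 0] - cents[b, 0], cents[a, 1] - cents[b, 1])
                if d < best_d and tgap(a, b) < t_merge:
                    best_pair, best_d = (a, b), d
        if best_pair is None:
            break
        a, b = best_pair
        wa, wb = weights[a], weights[b]
        cents[a] = (cents[a] * wa + cents[b] * wb) / (wa + wb)
        weights[a] = wa + wb
        spans[a] = [min(spans[a][0], spans[b][0]), max(spans[a][1], spans[b][1])]
        members[a].extend(members[b])
        active.discard(b)

    groups = [SymbolGroup.from_strokes(members[i], strokes) for i in sorted(active)]
    groups.sort(key=lambda g: g.t_on)
    return groups


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

_TEMPLATE_N = 16


def _normalized_strokes(strokes: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Centre on the joint centroid and scale by bbox height (fallback width)."""
    allpts = np.vstack(strokes)
    c = allpts.mean(axis=0)
    h = allpts[:, 1].max() - allpts[:, 1].min()
    if h < 1e-9:
        h = max(allpts[:, 0].max() - allpts[:, 0].min(), 1e-9)
    return [(s - c) / h for s in strokes]


def _digit_templates() -> dict[int, list[np.ndarray]]:
    out = {}
    for v in range(1, 13):
        pts = [resample_polyline(s, _TEMPLATE_N) for s in digit_strokes(v)]
        out[v] = _normalized_strokes(pts)
    return out


_TEMPLATES = _digit_templates()


@dataclass
class _GroupFeatures:
    length: float
    n_strokes: int
    n_samples: int
    bbox_w: float
    bbox_h: float
    elongation: float
    closure: float
    circ_resid_rel: float
    rad_pos: float  # centroid distance to face centre / R
    end_center: float  # min endpoint distance to face centre / R
    onset_frac: float
    clock_angle: float  # rad, from 12
    digit_dists: np.ndarray  # (12,) normalized template distances
    face_like: float
    overlaps_other: float  # max fractional bbox overlap with another group


def _extract_features(session: DrawingSession, groups: Sequence[SymbolGroup]) -> list[_GroupFeatures]:
    strokes = session.strokes
    # face context: biggest near-closed group
    fi, flen = None, 0.0
    for gi, g in enumerate(groups):
        L = sum(strokes[i].length_mm for i in g.stroke_indices)
        cl = min(_closure(strokes[i]) for i in g.stroke_indices)
        if L > flen and L > 40.0 and cl < 0.3:
            fi, flen = gi, L
    if fi is not None:
        fc = np.array(groups[fi].centroid)
        fx = np.concatenate([strokes[i].x for i in groups[fi].stroke_indices])
        fy = np.concatenate([strokes[i].y for i in groups[fi].stroke_indices])
        R = float(np.hypot(fx - fc[0], fy - fc[1]).mean())
    else:
        fc = np.array([np.mean([g.centroid[0] for g in groups]), np.mean([g.centroid[1] for g in groups])])
        R = max(max(g.bbox[2] - g.bbox[0] for g in groups), 20.0) / 2.0
    t_lo = min(g.t_on for g in groups)
    t_hi = max(g.t_off for g in groups)
    t_span = max(t_hi - t_lo, 1.0)

    def _overlap_frac(a, b) -> float:
        w = min(a[2], b[2]) - max(a[0], b[0])
        h = min(a[3], b[3]) - max(a[1], b[1])
        if w <= 0 or h <= 0:
            return 0.0
        area_a = max((a[2] - a[0]) * (a[3] - a[1]), 1e-9)
        area_b = max((b[2] - b[0]) * (b[3] - b[1]), 1e-9)
        return w * h / min(area_a, area_b)

    feats = []
    for g in groups:
        sts = [strokes[i] for i in g.stroke_indices]
        pts = np.vstack([np.column_stack([s.x, s.y]) for s in sts])
        L = sum(s.length_mm for s in sts)
        w = g.bbox[2] - g.bbox[0]
        h = g.bbox[3] - g.bbox[1]
        cen = np.array(g.centroid)
        # PCA elongation
        d = pts - pts.mean(axis=0)
        if len(pts) > 2:
            cov = d.T @ d / len(pts)
            ev = np.linalg.eigvalsh(cov)
            elong = math.sqrt(max(ev[1], 1e-12) / max(ev[0], 1e-12))
        else:
            elong = 1.0
        cl = min(_closure(s) for s in sts)
        # radial residual of a crude circle fit (about the centroid)
        rr = np.hypot(pts[:, 0] - cen[0], pts[:, 1] - cen[1])
        circ_rel = float(np.std(rr) / max(rr.mean(), 1e-9))
        rad = math.hypot(cen[0] - fc[0], cen[1] - fc[1]) / R
        ends = np.array([[s.x[0], s.y[0]] for s in sts] + [[s.x[-1], s.y[-1]] for s in sts])
        end_c = float(np.hypot(ends[:, 0] - fc[0], ends[:, 1] - fc[1]).min()) / R
        onset = (g.t_on - t_lo) / t_span
        ang = math.atan2(cen[0] - fc[0], -(cen[1] - fc[1])) % (2 * math.pi)
        # template distances
        norm = _normalized_strokes([resample_polyline(np.column_stack([s.x, s.y]), _TEMPLATE_N) for s in sts])
        dists = np.full(12, 10.0)
        for v, tmpl in _TEMPLATES.items():
            if len(tmpl) != len(norm):
                continue
            dv = np.mean([np.hypot(*(a - b).T).mean() for a, b in zip(norm, tmpl)])
            dists[v - 1] = dv
        face_like = (
            math.exp(-((circ_rel / 0.12) ** 2))
            * math.exp(-((cl / 0.25) ** 2))
            / (1.0 + math.exp(-(L / R - 4.0) / 0.4))
        )
        own_area = max((g.bbox[2] - g.bbox[0]) * (g.bbox[3] - g.bbox[1]), 1e-9)
        ovl = max(
            (_overlap_frac(g.bbox, o.bbox) for o in groups
             if o is not g
             and (o.bbox[2] - o.bbox[0]) * (o.bbox[3] - o.bbox[1]) < 5.0 * own_area),
            default=0.0,
        )
        feats.append(_GroupFeatures(L, len(sts), len(pts), w, h, elong, cl, circ_rel,
                                    rad, end_c, onset, ang, dists, face_like, ovl))
    return feats


# ---------------------------------------------------------------------------
# Shape scorers
# ---------------------------------------------------------------------------


class ShapeScorer(Protocol):
    """Contract: groups of a session -> one simplex vector per group, over
    :data:`clockdraw.labels.LABEL_SPACE`."""

    def score(self, session: DrawingSession, groups: Sequence[SymbolGroup]) -> np.ndarray: ...


class TemplateShapeScorer:
    """Rule-based default scorer: geometric features plus glyph-template
    matching, producing calibrated-ish probabilities."""

    def __init__(self, temp: float = 0.16, angle_kappa: float = 2.0):
        self.temp = temp
        self.angle_kappa = angle_kappa

    def score(self, session: DrawingSession, groups: Sequence[SymbolGroup]) -> np.ndarray:
        feats = _extract_features(session, groups)
        P = np.zeros((len(groups), _N_LABELS))
        for gi, f in enumerate(feats):
            s = np.full(_N_LABELS, 1e-6)
            if f.n_samples < 2:
                s[_NOISE_I] = 1.0  # degenerate dot: noise-dominated prior
                P[gi] = s / s.sum()
                continue
            s[_FACE_I] = 3.0 * f.face_like
            # digits: template shape x angular-position prior
            shape = np.exp(-((f.digit_dists / self.temp) ** 2))
            for v in range(1, 13):
                ang_err = (f.clock_angle - math.radians(30.0 * v) + math.pi) % (2 * math.pi) - math.pi
                prior = math.exp(self.angle_kappa * (math.cos(ang_err) - 1.0))
                in_ring = math.exp(-(((f.rad_pos - 0.78) / 0.25) ** 2))
                s[_DIGIT_I[v]] = shape[v - 1] * prior * in_ring
            best_digit = s[1:13].max()
            # hands: elongated, anchored near the centre, shorter than R
            handness = (
                (1.0 / (1.0 + math.exp(-(f.elongation - 3.0))))
                * math.exp(-((f.end_center / 0.28) ** 2))
                * math.exp(-((max(f.length / max(f.bbox_w + f.bbox_h, 1e-9), 1.0) - 1.0) / 1.0) ** 2)
            )
            if f.n_strokes <= 2 and f.length > 2.0:
                s[_HOUR_I] = handness * math.exp(-(((f.rad_pos - 0.45 / 2) / 0.25) ** 2))
                s[_MIN_I] = handness * math.exp(-(((f.rad_pos - 0.62 / 2) / 0.25) ** 2))
                for idx, target in ((_HOUR_I, 335.0), (_MIN_I, 60.0)):
                    ang_err = (f.clock_angle - math.radians(target) + math.pi) % (2 * math.pi) - math.pi
                    s[idx] *= math.exp(0.5 * (math.cos(ang_err) - 1.0))
            # noise: small marks
            s[_NOISE_I] = math.exp(-f.length / 4.0) + (0.5 if f.n_samples < 4 else 0.0) + 1e-4
            # cross-out: elongated, late, struck through another symbol
            s[_CROSS_I] = (
                0.5
                * (1.0 / (1.0 + math.exp(-(f.elongation - 4.0))))
                * (1.0 / (1.0 + math.exp(-(f.onset_frac - 0.8) / 0.08)))
                * min(f.overlaps_other / 0.3, 1.0)
                * (1.0 if f.end_center > 0.35 else 0.1)
            )
            # overwriting: digit-shaped marks drawn late
            s[_OVER_I] = best_digit * 0.25 * f.onset_frac**2 + 1e-5
            P[gi] = s / s.sum()
        return P


class FittedShapeScorer:
    """Shallow multinomial classifier over geometric + template features,
    honoring the same groups -> simplex contract."""

    def __init__(self, model, classes: list[str]):
        self._model = model
        self._classes = classes

    @staticmethod
    def feature_vector(f: _GroupFeatures) -> np.ndarray:
        return np.concatenate([
            [math.log1p(f.length), f.bbox_w, f.bbox_h, f.elongation, f.closure,
             f.circ_resid_rel, f.rad_pos, f.end_center, f.onset_frac,
             float(f.n_strokes), math.log1p(f.n_samples),
             math.sin(f.clock_angle), math.cos(f.clock_angle), f.face_like,
             f.overlaps_other],
            np.minimum(f.digit_dists, 2.0),
        ])

    def score(self, session: DrawingSession, groups: Sequence[SymbolGroup]) -> np.ndarray:
        feats = _extract_features(session, groups)
        X = np.array([self.feature_vector(f) for f in feats])
        proba = self._model.predict_proba(X)
        P = np.full((len(groups), _N_LABELS), 1e-9)
        for j, cname in enumerate(self._classes):
            P[:, label_index(SymbolLabel.parse(cname))] = proba[:, j]
        return P / P.sum(axis=1, keepdims=True)


def fit_shape_scorer(
    training: Sequence[tuple[DrawingSession, Sequence[SymbolGroup], Sequence[SymbolLabel]]],
    seed: int = 0,
) -> FittedShapeScorer:
    """Fit a shape scorer from labeled groups; deterministic given seed."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X, y = [], []
    for session, groups, labels in training:
        feats = _extract_features(session, groups)
        for f, lab in zip(feats, labels):
            X.append(FittedShapeScorer.feature_vector(f))
            y.append(str(lab))
    if len(set(y)) < 2:
        raise ValueError("need at least two label classes to fit a scorer")
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(max_iter=2000, C=10.0, random_state=seed),
    )
    model.fit(np.array(X), np.array(y))
    return FittedShapeScorer(model, list(model[-1].classes_))


def score_shapes(
    session: DrawingSession,
    groups: Sequence[SymbolGroup],
    scorer: Optional[ShapeScorer] = None,
) -> np.ndarray:
    """Per-group probability vectors over the 18 symbol labels."""
    scorer = scorer or TemplateShapeScorer()
    P = scorer.score(session, groups)
    P = np.asarray(P, dtype=float)
    if P.shape != (len(groups), _N_LABELS):
        raise ValueError("scorer returned wrong shape")
    if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("scorer output is not on the probability simplex")
    return P


# ---------------------------------------------------------------------------
# Constraint resolution
# ---------------------------------------------------------------------------


@dataclass
class ClassifiedDrawing:
    """A session with resolved symbol groups, labels and probabilities."""

    session: DrawingSession
    groups: list[SymbolGroup]
    probabilities: np.ndarray  # (G, 18)
    labels: list[SymbolLabel]
    low_confidence: np.ndarray  # (G,) bool
    warnings: list[str] = field(default_factory=list)

    @property
    def stroke_labels(self) -> list[SymbolLabel]:
        out: list[SymbolLabel] = [SymbolLabel(SymbolKind.NOISE)] * self.session.n_strokes
        for g, lab in zip(self.groups, self.labels):
            for i in g.stroke_indices:
                out[i] = lab
        return out

    def groups_by_kind(self, kind: SymbolKind) -> list[tuple[SymbolGroup, SymbolLabel]]:
        return [(g, l) for g, l in zip(self.groups, self.labels) if l.kind is kind]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "condition": self.session.condition.value,
            "groups": [
                {
                    "strokes": list(g.stroke_indices),
                    "bbox": list(g.bbox),
                    "centroid": list(g.centroid),
                    "t_on_ms": g.t_on,
                    "t_off_ms": g.t_off,
                    "label": str(lab),
                    "low_confidence": bool(lc),
                    "probabilities": {str(L): round(float(p), 6)
                                      for L, p in zip(LABEL_SPACE, P) if p > 1e-4},
                }
                for g, lab, lc, P in zip(self.groups, self.labels, self.low_confidence, self.probabilities)
            ],
            "warnings": self.warnings,
        }
        s = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


def resolve_labels(
    session: DrawingSession,
    groups: Sequence[SymbolGroup],
    probabilities: np.ndarray,
    margin: float = 0.2,
) -> ClassifiedDrawing:
    """Exact constrained assignment of one label per group.

    Structural constraints: at most one clock face, each digit value used at
    most once, at most one hour and one minute hand.  Noise, cross-out and
    overwrite labels are repeatable.  The assignment maximizes the total
    log-probability (rectangular assignment problem, solved exactly), so a
    duplicate digit group degrades to overwrite/noise rather than raising.
    """
    G = len(groups)
    logp = np.log(np.maximum(np.asarray(probabilities, dtype=float), 1e-12))
    unique_cols = [_FACE_I] + [_DIGIT_I[v] for v in range(1, 13)] + [_HOUR_I, _MIN_I]
    nu = len(unique_cols)
    BIG = 1e6
    cost = np.full((G, nu + G), BIG)
    cost[:, :nu] = -logp[:, unique_cols]
    slack_label = np.empty(G, dtype=int)
    for g in range(G):
        rep = [_NOISE_I, _CROSS_I, _OVER_I]
        best = max(rep, key=lambda i: logp[g, i])
        slack_label[g] = best
        cost[g, nu + g] = -logp[g, best]
    rows, cols = linear_sum_assignment(cost)
    labels: list[SymbolLabel] = [SymbolLabel(SymbolKind.NOISE)] * G
    warnings: list[str] = []
    for r, c in zip(rows, cols):
        if c < nu:
            labels[r] = LABEL_SPACE[unique_cols[c]]
        else:
            labels[r] = LABEL_SPACE[slack_label[r]]
    # hand disambiguation: if both hands assigned, the shorter is the hour
    # hand (tie broken by the assignment's angle-aware probabilities)
    hidx = [i for i, l in enumerate(labels) if l.kind in (SymbolKind.HOUR_HAND, SymbolKind.MINUTE_HAND)]
    if len(hidx) == 2:
        lens = []
        for i in hidx:
            lens.append(sum(session.strokes[k].length_mm for k in groups[i].stroke_indices))
        short, lng = (hidx[0], hidx[1]) if lens[0] <= lens[1] else (hidx[1], hidx[0])
        labels[short] = SymbolLabel(SymbolKind.HOUR_HAND)
        labels[lng] = SymbolLabel(SymbolKind.MINUTE_HAND)
    sortp = np.sort(probabilities, axis=1)
    low_conf = (sortp[:, -1] - sortp[:, -2]) < margin
    if not any(l.kind is SymbolKind.CLOCK_FACE for l in labels):
        warnings.append("no clock face resolved")
    return ClassifiedDrawing(session, list(groups), np.asarray(probabilities), labels,
                             low_conf, warnings)


def _best_template_dist(strokes: Sequence[Stroke], indices: Sequence[int]) -> float:
    """Best digit-template distance of a candidate stroke subset."""
    sts = [strokes[i] for i in indices]
    norm = _normalized_strokes(
        [resample_polyline(np.column_stack([s.x, s.y]), _TEMPLATE_N) for s in sts])
    best = 10.0
    for tmpl in _TEMPLATES.values():
        if len(tmpl) != len(norm):
            continue
        d = np.mean([np.hypot(*(a - b).T).mean() for a, b in zip(norm, tmpl)])
        best = min(best, d)
    return best


def refine_groups(
    session: DrawingSession,
    groups: Sequence[SymbolGroup],
    *,
    d_keep: float = 0.15,
    d_accept: float = 0.25,
    max_depth: int = 2,
) -> list[SymbolGroup]:
    """Second grouping pass: split merged neighbours.

    A group that matches no digit template (distance > ``d_keep``) is tried
    at every temporal split point; if both halves then match templates well
    (distance < ``d_accept`` and clearly better than unsplit), the split is
    kept, recursively.  This recovers adjacent symbols that the distance
    threshold agglomerated under placement jitter.
    """
    strokes = session.strokes

    def split(idx: tuple[int, ...], depth: int) -> list[tuple[int, ...]]:
        if len(idx) < 2 or depth == 0:
            return [idx]
        ordered = sorted(idx, key=lambda i: strokes[i].start_t)
        d0 = _best_template_dist(strokes, ordered)
        if d0 <= d_keep:
            return [idx]
        best_k, best_d = None, d_accept
        for k in range(1, len(ordered)):
            d = max(_best_template_dist(strokes, ordered[:k]),
                    _best_template_dist(strokes, ordered[k:]))
            if d < best_d:
                best_k, best_d = k, d
        if best_k is None or best_d >= 0.75 * d0:
            return [idx]
        return (split(tuple(ordered[:best_k]), depth - 1)
                + split(tuple(ordered[best_k:]), depth - 1))

    out: list[SymbolGroup] = []
    for g in groups:
        parts = split(g.stroke_indices, max_depth)
        if len(parts) == 1:
            out.append(g)
        else:
            out.extend(SymbolGroup.from_strokes(p, strokes) for p in parts)
    out.sort(key=lambda g: g.t_on)
    return out


def classify_drawing(
    session: DrawingSession,
    scorer: Optional[ShapeScorer] = None,
    d_merge: float = D_MERGE_MM,
    t_merge: float = T_MERGE_S,
    refine: bool = True,
) -> ClassifiedDrawing:
    """Full pipeline: group, refine, score, resolve."""
    groups = group_strokes(session, d_merge, t_merge)
    if refine:
        groups = refine_groups(session, groups)
    P = score_shapes(session, groups, scorer)
    return resolve_labels(session, groups, P)


def classified_from_truth(session: DrawingSession, truth: GroundTruth) -> ClassifiedDrawing:
    """Build a ClassifiedDrawing directly from generator ground truth
    (one-hot probabilities); used to isolate the metric layer from
    classifier error."""
    by_sym: dict[int, list[int]] = {}
    for i, sid in enumerate(truth.symbol_ids):
        by_sym.setdefault(sid, []).append(i)
    groups, labels = [], []
    for sid in sorted(by_sym):
        idx = by_sym[sid]
        groups.append(SymbolGroup.from_strokes(idx, session.strokes))
        labels.append(truth.stroke_labels[idx[0]])
    P = np.full((len(groups), _N_LABELS), 1e-12)
    for gi, lab in enumerate(labels):
        P[gi, label_index(lab)] = 1.0
    P /= P.sum(axis=1, keepdims=True)
    return ClassifiedDrawing(session, groups, P, labels, np.zeros(len(groups), bool))
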