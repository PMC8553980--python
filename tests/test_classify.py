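"""Stroke grouping, shape scoring and constrained label resolution."""

from __future__ import annotations

import itertools
import json
import math

import numpy as np
import pytest

import clockdraw as cd
from clockdraw.classify import (
    TemplateShapeScorer,
    classified_from_truth,
    classify_drawing,
    fit_shape_scorer,
    group_strokes,
    resolve_labels,
    score_shapes,
)
from clockdraw.ink import Condition, DrawingSession, Stroke
from clockdraw.labels import LABEL_SPACE, SymbolKind, SymbolLabel, label_index


def _line(x0, y0, x1, y1, t0, dur, n=10):
    u = np.linspace(0, 1, n)
    return Stroke(x0 + (x1 - x0) * u, y0 + (y1 - y0) * u, t0 + dur * u)


def _circle(cx, cy, r, t0, dur, n=40):
    a = np.linspace(0, 2 * math.pi * 0.98, n)
    return Stroke(cx + r * np.cos(a), cy + r * np.sin(a), t0 + dur * np.linspace(0, 1, n))


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def test_close_in_space_and_time_merges():
    # a "1" then "0" drawn 80 ms apart, 3 mm apart
    s = DrawingSession(Condition.COMMAND, [
        _line(100, 100, 100, 108, 0, 300),
        _circle(103, 104, 2.5, 380, 400),
    ])
    assert len(group_strokes(s)) == 1


def test_far_apart_stays_split():
    s = DrawingSession(Condition.COMMAND, [
        _line(60, 100, 60, 108, 0, 300),
        _line(160, 100, 160, 108, 10_300, 300),
    ])
    assert len(group_strokes(s)) == 2


def test_single_stroke_single_group():
    s = DrawingSession(Condition.COMMAND, [_line(50, 50, 60, 60, 0, 200)])
    groups = group_strokes(s)
    assert len(groups) == 1 and groups[0].stroke_indices == (0,)


def test_empty_session_rejected():
    with pytest.raises(ValueError):
        group_strokes(DrawingSession(Condition.COMMAND, []))


def test_face_candidate_never_merges(noiseless_drawing):
    session, truth = noiseless_drawing
    groups = group_strokes(session)
    face_groups = [g for g in groups if 0 in g.stroke_indices]
    assert face_groups[0].stroke_indices == (0,)


def test_partition_property(imp_cmd):
    session, _ = cd.generate_drawing(imp_cmd, seed=17)
    cls = classify_drawing(session)
    seen = [i for g in cls.groups for i in g.stroke_indices]
    assert sorted(seen) == list(range(session.n_strokes))
    assert len(cls.stroke_labels) == session.n_strokes


# ---------------------------------------------------------------------------
# shape scoring
# ---------------------------------------------------------------------------


def test_probabilities_lie_on_simplex(imp_cmd):
    session, _ = cd.generate_drawing(imp_cmd, seed=21)
    groups = group_strokes(session)
    P = score_shapes(session, groups)
    assert (P >= 0).all()
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)


def test_noiseless_face_scores_high(noiseless_drawing):
    session, _ = noiseless_drawing
    groups = group_strokes(session)
    P = score_shapes(session, groups)
    gi = next(i for i, g in enumerate(groups) if 0 in g.stroke_indices)
    assert P[gi, label_index(SymbolLabel(SymbolKind.CLOCK_FACE))] > 0.9


def test_tiny_dot_is_noise(noiseless_drawing):
    session, _ = noiseless_drawing
    dot = Stroke([150.0, 150.5, 151.0], [60.0, 60.2, 60.0],
                 [session.total_time_ms + 500 + k * 12 for k in range(3)])
    s2 = DrawingSession(session.condition, session.strokes + [dot], session.page)
    cls = classify_drawing(s2)
    assert str(cls.stroke_labels[-1]) == "noise"


def test_degenerate_single_sample_gets_noise_prior():
    s = DrawingSession(Condition.COMMAND, [
        _circle(108, 140, 40, 0, 2000),
        Stroke([100.0], [100.0], [3000.0]),
    ])
    groups = group_strokes(s)
    P = score_shapes(s, groups)
    gi = next(i for i, g in enumerate(groups) if 1 in g.stroke_indices)
    assert P[gi].argmax() == label_index(SymbolLabel(SymbolKind.NOISE))


def test_hand_stroke_scores_as_hand(noiseless_drawing):
    session, truth = noiseless_drawing
    cls = classify_drawing(session)
    hand_idx = [i for i, l in enumerate(truth.stroke_labels)
                if l.kind in (SymbolKind.HOUR_HAND, SymbolKind.MINUTE_HAND)]
    for i in hand_idx:
        assert cls.stroke_labels[i].kind in (SymbolKind.HOUR_HAND, SymbolKind.MINUTE_HAND)


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------


def _toy_session(n):
    strokes = [_line(20 * i + 10, 30, 20 * i + 10, 40, 1000 * i, 300) for i in range(n)]
    return DrawingSession(Condition.COMMAND, strokes)


def _brute_force_best(P):
    """Exhaustive max-log-prob assignment under the structural constraints."""
    G = len(P)
    unique = {label_index(SymbolLabel(SymbolKind.CLOCK_FACE)),
              label_index(SymbolLabel(SymbolKind.HOUR_HAND)),
              label_index(SymbolLabel(SymbolKind.MINUTE_HAND))} | {
        label_index(SymbolLabel(SymbolKind.DIGIT, v)) for v in range(1, 13)}
    best, best_lp = None, -np.inf
    for combo in itertools.product(range(len(LABEL_SPACE)), repeat=G):
        used = [c for c in combo if c in unique]
        if len(used) != len(set(used)):
            continue
        lp = sum(math.log(max(P[g, c], 1e-12)) for g, c in enumerate(combo))
        if lp > best_lp:
            best, best_lp = combo, lp
    return best, best_lp


def test_resolution_matches_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(5):
        P = rng.dirichlet(np.full(len(LABEL_SPACE), 0.3), size=4)
        s = _toy_session(4)
        groups = group_strokes(s)
        cls = resolve_labels(s, groups, P)
        lp = sum(math.log(P[g, label_index(l)]) for g, l in enumerate(cls.labels))
        _, best_lp = _brute_force_best(P)
        assert lp == pytest.approx(best_lp, abs=1e-9)


def test_duplicate_face_degrades_to_repeatable_label():
    P = np.full((2, len(LABEL_SPACE)), 1e-6)
    fi = label_index(SymbolLabel(SymbolKind.CLOCK_FACE))
    ni = label_index(SymbolLabel(SymbolKind.NOISE))
    P[:, fi] = 0.9
    P[:, ni] = 0.05
    P /= P.sum(axis=1, keepdims=True)
    s = _toy_session(2)
    cls = resolve_labels(s, group_strokes(s), P)
    kinds = [l.kind for l in cls.labels]
    assert kinds.count(SymbolKind.CLOCK_FACE) == 1


def test_hand_pair_disambiguated_by_length(noiseless_drawing):
    session, truth = noiseless_drawing
    cls = classify_drawing(session)
    by_kind = {l.kind: g for g, l in zip(cls.groups, cls.labels)
               if l.kind in (SymbolKind.HOUR_HAND, SymbolKind.MINUTE_HAND)}
    assert set(by_kind) == {SymbolKind.HOUR_HAND, SymbolKind.MINUTE_HAND}
    hl = sum(session.strokes[i].length_mm for i in by_kind[SymbolKind.HOUR_HAND].stroke_indices)
    ml = sum(session.strokes[i].length_mm for i in by_kind[SymbolKind.MINUTE_HAND].stroke_indices)
    assert hl < ml


def test_classified_json_serialization(noiseless_drawing):
    session, _ = noiseless_drawing
    cls = classify_drawing(session)
    doc = json.loads(cls.to_json())
    assert len(doc["groups"]) == len(cls.groups)
    assert all(abs(sum(g["probabilities"].values()) - 1.0) < 0.01 for g in doc["groups"])


# ---------------------------------------------------------------------------
# fitted scorer
# ---------------------------------------------------------------------------


def _training_triples(n, seed, params):
    out = []
    for k in range(n):
        sess, truth = cd.generate_drawing(params, seed=seed + k)
        ct = classified_from_truth(sess, truth)
        out.append((sess, ct.groups, ct.labels))
    return out


def test_fitted_scorer_separable_toy_is_perfect():
    strokes, labels = [], []
    for i in range(6):
        strokes.append(_line(20 * i + 5, 30, 20 * i + 5.6, 30.4, 2000 * i, 100, n=4))
        labels.append(SymbolLabel(SymbolKind.NOISE))
    for i in range(6):
        strokes.append(_line(20 * i + 5, 120, 20 * i + 5, 160, 15_000 + 2000 * i, 500))
        labels.append(SymbolLabel(SymbolKind.MINUTE_HAND))
    s = DrawingSession(Condition.COMMAND, strokes)
    groups = [cd.SymbolGroup.from_strokes([i], s.strokes) for i in range(len(strokes))]
    scorer = fit_shape_scorer([(s, groups, labels)], seed=0)
    P = scorer.score(s, groups)
    pred = [LABEL_SPACE[i] for i in P.argmax(axis=1)]
    assert pred == labels


def test_fitted_scorer_deterministic_and_accurate(unimp_cmd):
    train = _training_triples(25, 1000, unimp_cmd)
    test = _training_triples(8, 5000, unimp_cmd)
    sc1 = fit_shape_scorer(train, seed=3)
    sc2 = fit_shape_scorer(train, seed=3)
    correct = total = 0
    for sess, groups, labels in test:
        P1 = sc1.score(sess, groups)
        P2 = sc2.score(sess, groups)
        np.testing.assert_array_equal(P1, P2)
        for row, lab in zip(P1, labels):
            total += 1
            correct += LABEL_SPACE[row.argmax()] == lab
    assert correct / total >= 0.90


def test_fitted_scorer_rejects_single_class():
    s = _toy_session(3)
    groups = [cd.SymbolGroup.from_strokes([i], s.strokes) for i in range(3)]
    labels = [SymbolLabel(SymbolKind.NOISE)] * 3
    with pytest.raises(ValueError):
        fit_shape_scorer([(s, groups, labels)])


# ---------------------------------------------------------------------------
# end-to-end label recovery
# ---------------------------------------------------------------------------


def _accuracy(subs):
    ok = tot = 0
    for s in subs:
        for sess, truth in ((s.record.command, s.truth_command), (s.record.copy, s.truth_copy)):
            pred = classify_drawing(sess).stroke_labels
            ok += sum(str(p) == str(t) for p, t in zip(pred, truth.stroke_labels))
            tot += sess.n_strokes
    return ok / tot


def test_recovery_degrades_with_jitter(unimp_cmd):
    mild = [cd.generate_drawing(unimp_cmd, seed=s) for s in range(300, 320)]
    wild_p = unimp_cmd.replace(digit_jitter_rad=0.35, radial_jitter_frac=0.12)
    wild = [cd.generate_drawing(wild_p, seed=s) for s in range(300, 320)]

    def acc(drawings):
        ok = tot = 0
        for sess, truth in drawings:
            pred = classify_drawing(sess).stroke_labels
            ok += sum(str(p) == str(t) for p, t in zip(pred, truth.stroke_labels))
            tot += sess.n_strokes
        return ok / tot

    assert acc(mild) > acc(wild)
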