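"""Metric catalogue: exact values on constructed sessions, circle fitting,
equivariances and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

import clockdraw as cd
from clockdraw.classify import ClassifiedDrawing, SymbolGroup
from clockdraw.ink import Condition, DrawingSession, Stroke
from clockdraw.labels import LABEL_SPACE, SymbolKind, SymbolLabel, label_index
from clockdraw.metrics import compute_metrics, fit_circle


def _classified(session, labels):
    groups = [SymbolGroup.from_strokes([i], session.strokes) for i in range(session.n_strokes)]
    P = np.full((len(groups), len(LABEL_SPACE)), 1e-12)
    for i, lab in enumerate(labels):
        P[i, label_index(lab)] = 1.0
    P /= P.sum(axis=1, keepdims=True)
    return ClassifiedDrawing(session, groups, P, list(labels), np.zeros(len(groups), bool))


def test_constructed_session_exact_values():
    # stroke A: 6 mm in 200 ms; gap 500 ms; stroke B: 3 mm in 100 ms
    s = DrawingSession(Condition.COMMAND, [
        Stroke([0, 3, 6], [0, 0, 0], [0, 100, 200]),
        Stroke([6, 6], [8, 11], [700, 800]),
    ])
    rec = compute_metrics(_classified(s, [SymbolLabel(SymbolKind.DIGIT, 1),
                                          SymbolLabel(SymbolKind.DIGIT, 2)]))
    assert rec.total_time == pytest.approx(0.8)
    assert rec.ink_length == pytest.approx(9.0)
    assert rec.percent_ink_time == pytest.approx(100 * 0.3 / 0.8)
    assert rec.percent_think_time + rec.percent_ink_time == pytest.approx(100.0, abs=1e-9)
    assert rec.average_latency == pytest.approx(0.5)
    assert rec.longest_latency == pytest.approx(0.5)
    assert rec.latency_variability == pytest.approx(0.0)
    assert rec.drawing_process_efficiency == pytest.approx(9.0 / 0.8)
    # no face resolved: face-dependent metrics flagged missing, not zero
    assert math.isnan(rec.drawing_size)
    assert "drawing_size" in rec.missing and "average_speed" in rec.missing
    assert rec.noise == pytest.approx(0.39)  # clean drawing floor


def test_long_latency_threshold_configurable():
    s = DrawingSession(Condition.COMMAND, [
        Stroke([0, 5], [0, 0], [0, 100]),
        Stroke([10, 15], [0, 0], [1200, 1300]),   # 1.1 s gap
        Stroke([20, 25], [0, 0], [6300, 6400]),   # 5.0 s gap
    ])
    cls = _classified(s, [SymbolLabel(SymbolKind.DIGIT, v) for v in (1, 2, 3)])
    rec = compute_metrics(cls)  # default threshold 3 x 0.7 = 2.1 s
    assert rec.long_latency_count == 1
    rec2 = compute_metrics(cls, reference_latency_s=0.3)
    assert rec2.long_latency_count == 2


def test_fit_circle_exact_and_three_point():
    a = np.linspace(0, 2 * np.pi, 50, endpoint=False)
    fit = fit_circle(10 + 7 * np.cos(a), -3 + 7 * np.sin(a))
    assert fit.radius == pytest.approx(7.0, abs=1e-9)
    assert np.abs(fit.residuals).max() < 1e-9
    # right triangle on a circle of radius 5 centred at origin
    fit3 = fit_circle(np.array([5.0, -5.0, 0.0]), np.array([0.0, 0.0, 5.0]))
    assert fit3.radius == pytest.approx(5.0, abs=1e-9)
    assert fit3.center == pytest.approx((0.0, 0.0), abs=1e-9)


def test_fit_circle_degenerate_rejected():
    with pytest.raises(ValueError):
        fit_circle(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
    with pytest.raises(ValueError):
        fit_circle(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


def test_fit_circle_radial_noise_monte_carlo():
    rng = np.random.default_rng(4)
    for _ in range(20):
        a = rng.uniform(0, 2 * np.pi, 100)
        r = 40.0 + rng.normal(0, 0.1, 100)
        fit = fit_circle(r * np.cos(a), r * np.sin(a))
        assert abs(fit.radius - 40.0) < 0.05


@pytest.fixture(scope="module")
def generated(unimp_cmd):
    session, truth = cd.generate_drawing(unimp_cmd, seed=77)
    return session, truth, compute_metrics(cd.classified_from_truth(session, truth))


def test_scale_equivariance(generated):
    session, truth, base = generated
    k = 0.5
    scaled = DrawingSession(session.condition,
                            [Stroke(s.x * k, s.y * k, s.t) for s in session.strokes],
                            (session.page[0] * k, session.page[1] * k))
    rec = compute_metrics(cd.classified_from_truth(scaled, truth))
    for name in ("ink_length", "drawing_size", "average_speed", "max_speed",
                 "clock_face_circularity"):
        assert getattr(rec, name) == pytest.approx(k * getattr(base, name), rel=1e-9)
    for name in ("total_time", "percent_think_time", "average_latency",
                 "stroke_count_conformity", "long_latency_count"):
        assert getattr(rec, name) == pytest.approx(getattr(base, name), rel=1e-9)


def test_time_equivariance(generated):
    session, truth, base = generated
    k = 2.0
    slowed = DrawingSession(session.condition,
                            [Stroke(s.x, s.y, s.t * k) for s in session.strokes],
                            session.page)
    rec = compute_metrics(cd.classified_from_truth(slowed, truth))
    assert rec.total_time == pytest.approx(k * base.total_time, rel=1e-9)
    assert rec.average_latency == pytest.approx(k * base.average_latency, rel=1e-9)
    assert rec.average_speed == pytest.approx(base.average_speed / k, rel=1e-9)
    for name in ("ink_length", "drawing_size", "clock_face_circularity",
                 "percent_think_time"):
        assert getattr(rec, name) == pytest.approx(getattr(base, name), rel=1e-9)


def test_brute_force_oracle_ink_and_latencies(unimp_cmd, imp_cmd):
    """Naive per-sample loops agree with the vectorized metrics to 1e-9."""
    for seed in range(30):
        params = unimp_cmd if seed % 2 else imp_cmd
        session, truth = cd.generate_drawing(params, seed=600 + seed)
        rec = compute_metrics(cd.classified_from_truth(session, truth))
        ink = 0.0
        for st in session.strokes:
            for i in range(len(st) - 1):
                ink += math.hypot(st.x[i + 1] - st.x[i], st.y[i + 1] - st.y[i])
        lats = [(session.strokes[i + 1].t[0] - session.strokes[i].t[-1]) / 1000.0
                for i in range(session.n_strokes - 1)]
        assert rec.ink_length == pytest.approx(ink, abs=1e-9)
        assert rec.average_latency == pytest.approx(np.mean(lats), abs=1e-9)
        assert rec.longest_latency == pytest.approx(max(lats), abs=1e-9)


def test_empty_drawing_rejected():
    s = DrawingSession(Condition.COMMAND, [])
    with pytest.raises(ValueError):
        compute_metrics(ClassifiedDrawing(s, [], np.zeros((0, len(LABEL_SPACE))), [],
                                          np.zeros(0, bool)))


def test_unexpected_ink_raises_noise_metric(noiseless_drawing):
    session, truth = noiseless_drawing
    base = compute_metrics(cd.classified_from_truth(session, truth))
    assert base.noise == pytest.approx(0.39)
    assert base.stroke_count_conformity == 0.0
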