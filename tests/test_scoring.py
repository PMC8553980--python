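"""Hierarchical composite scoring: fitting, standardization, score mapping,
cut scores, persistence and determinism."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clockdraw.scoring import (
    ClockScoringModel,
    ClockScoringResults,
    FUNCTIONAL_GROUPS,
    TopModel,
    _l1_logistic_cv,
    indeterminate_cutoff,
    youden_cutoff,
)
from clockdraw.stats import roc_curve


# ---------------------------------------------------------------------------
# synthetic metric tables
# ---------------------------------------------------------------------------


def _toy_table(n=120, seed=0, informative="command.total_time", shift=3.0):
    """A metric table where only one column separates the classes."""
    rng = np.random.default_rng(seed)
    y = np.array(["unimpaired"] * (n // 2) + ["impaired"] * (n // 2))
    cols = {}
    for cond in ("command", "copy"):
        for grp, members in FUNCTIONAL_GROUPS.items():
            for m in members:
                cols[f"{cond}.{m}"] = rng.normal(0, 1, n)
    cols[informative] = rng.normal(0, 1, n) + shift * (y == "impaired")
    return pd.DataFrame(cols), y


@pytest.fixture(scope="module")
def toy_fit():
    X, y = _toy_table()
    res = ClockScoringModel(X, y).fit(seed=0)
    return X, y, res


def test_needs_both_classes_and_minimum_size():
    X, y = _toy_table(n=30)
    with pytest.raises(ValueError):
        ClockScoringModel(X, np.array(["unimpaired"] * 30))
    with pytest.raises(ValueError):
        ClockScoringModel(X, y)  # 15 per class < 20


def test_informative_feature_dominates_and_composite_separates(toy_fit):
    X, y, res = toy_fit
    m = next(c for c in res.composite_models
             if c.condition == "command" and c.group == "drawing_efficiency")
    coefs = dict(zip(m.feature_names, np.abs(m.coef)))
    assert max(coefs, key=coefs.get) == "command.total_time"
    comp = m.transform(X)
    assert roc_curve(comp, y == "unimpaired").auc == pytest.approx(1.0, abs=0.01)


def test_unimpaired_training_composites_standardized(toy_fit):
    X, y, res = toy_fit
    comps = res.predict_composites(X)
    unimp = y == "unimpaired"
    nontrivial = 0
    for m in res.composite_models:
        c = f"{m.condition}.{m.group}"
        assert comps.loc[unimp, c].mean() == pytest.approx(0.0, abs=1e-9)
        if any(v != 0.0 for v in m.coef):  # constant composites have no scale
            assert comps.loc[unimp, c].std(ddof=0) == pytest.approx(1.0, abs=1e-6)
            nontrivial += 1
    assert nontrivial >= 1


def test_record_at_unimpaired_means_scores_zero_composites(toy_fit):
    X, y, res = toy_fit
    mean_row = X[y == "unimpaired"].mean().to_frame().T
    comps = res.predict_composites(mean_row)
    assert np.allclose(comps.to_numpy(), 0.0, atol=1e-9)


def test_score_mapping_endpoints():
    top = TopModel(["a"], [0.0], -50.0, 1.0)  # p ~ 0
    assert top.score(pd.DataFrame({"a": [0.0]}))[0] == pytest.approx(100.0)
    top = TopModel(["a"], [0.0], 50.0, 1.0)  # p ~ 1
    assert top.score(pd.DataFrame({"a": [0.0]}))[0] == pytest.approx(0.0)


def test_scores_bounded_and_monotone_in_risk(toy_fit):
    X, _, res = toy_fit
    t = res.score_table(X)
    assert ((t["score"] >= 0) & (t["score"] <= 100)).all()
    p = res.top_model.impairment_probability(res.predict_composites(X))
    order = np.argsort(p)
    s = t["score"].to_numpy()[order]
    assert (np.diff(s) <= 1e-9).all()


def test_classification_consistent_with_cutoffs(toy_fit):
    X, _, res = toy_fit
    t = res.score_table(X)
    lo, hi = res.cutoffs
    for s, c in zip(t["score"], t["classification"]):
        expected = "impaired" if s < lo else ("indeterminate" if s < hi else "unimpaired")
        assert c == expected


def test_refit_is_bit_deterministic(toy_fit):
    X, y, res = toy_fit
    res2 = ClockScoringModel(X, y).fit(seed=0)
    for a, b in zip(res.composite_models, res2.composite_models):
        assert a.coef == b.coef and a.intercept == b.intercept
    assert res.top_model.coef == res2.top_model.coef


def test_score_subject_repeatable_and_flags_missing_condition(small_cohort, toy_fit):
    _, rows, labels = small_cohort
    model = ClockScoringModel.from_records(rows, labels)
    assert model.metrics.shape[0] == len(rows)
    res = toy_fit[2]
    sid, cmd, copy = rows[0]
    a = res.score_subject(cmd, copy, subject_id=sid)
    b = res.score_subject(cmd, copy, subject_id=sid)
    assert a.score == b.score and a.composites == b.composites
    single = res.score_subject(cmd, None, subject_id=sid)
    assert any("single-condition" in f for f in single.flags)
    assert 0.0 <= single.score <= 100.0


def test_monotone_hierarchy_on_fitted_model(toy_fit):
    """Worsening a metric with nonzero composite weight (composite oriented
    into the top model) never increases the overall score."""
    X, _, res = toy_fit
    x0 = X.iloc[[0]].copy()
    s0 = float(res.top_model.score(res.predict_composites(x0))[0])
    top = dict(zip(res.top_model.composite_names, res.top_model.coef))
    checked = 0
    for m in res.composite_models:
        if top.get(f"{m.condition}.{m.group}", 0.0) > 0:
            continue  # composite not oriented into the top model
        for f, c in zip(m.feature_names, m.coef):
            if c == 0.0:
                continue
            x1 = x0.copy()
            # direction that lowers the composite (= toward impairment)
            x1[f] = x1[f] + np.sign(c) * 5.0 * m.scale[m.feature_names.index(f)]
            s1 = float(res.top_model.score(res.predict_composites(x1))[0])
            assert s1 <= s0 + 1e-9
            checked += 1
    assert checked > 0


def test_save_load_round_trip(tmp_path, toy_fit):
    X, _, res = toy_fit
    p = tmp_path / "model.json"
    res.save(p)
    back = ClockScoringResults.load(p)
    np.testing.assert_allclose(back.score_table(X)["score"], res.score_table(X)["score"])
    assert back.cutoffs == res.cutoffs


def test_summary_lists_hierarchy(toy_fit):
    _, _, res = toy_fit
    text = res.summary()
    assert "Top model" in text and "command.drawing_efficiency" in text


def test_l1_recovers_sparse_support():
    rng = np.random.default_rng(8)
    n, beta = 4000, np.array([2.0, -1.5, 0.0, 0.0, 1.0, 0.0])
    X = rng.normal(0, 1, (n, 6))
    p = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(int)
    model, _ = _l1_logistic_cv(X, y, [10.0], cv=0, seed=0)
    coef = model.coef_[0]
    assert np.all(np.sign(coef[[0, 1, 4]]) == np.sign(beta[[0, 1, 4]]))
    assert np.all(np.abs(coef[[2, 3, 5]]) < 0.2)


# ---------------------------------------------------------------------------
# cut scores
# ---------------------------------------------------------------------------


def test_youden_separable_returns_midpoint():
    scores = np.array([10.0, 20.0, 80.0, 90.0])
    labels = np.array([1, 1, 0, 0])  # 1 = impaired
    cut, sens, spec = youden_cutoff(scores, labels)
    assert cut == pytest.approx(50.0)
    assert sens == 1.0 and spec == 1.0


def test_youden_matches_exhaustive_scan():
    rng = np.random.default_rng(11)
    for _ in range(25):
        n = int(rng.integers(8, 60))
        scores = np.round(rng.normal(50, 20, n), 1)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        cut, sens, spec = youden_cutoff(scores, labels)
        j = sens + spec - 1
        best = -np.inf
        for c in np.concatenate([[scores.min() - 1], np.sort(scores) + 1e-9,
                                 [scores.max() + 1]]):
            s = (scores[labels] < c).mean() + (scores[~labels] >= c).mean() - 1
            best = max(best, s)
        assert j == pytest.approx(best, abs=1e-12)


def test_youden_requires_both_classes():
    with pytest.raises(ValueError):
        youden_cutoff([1.0, 2.0], [1, 1])


def test_indeterminate_cutoff_modes():
    assert indeterminate_cutoff([1, 2], [1, 0]) == 75.0
    scores = np.array([10.0, 20.0, 30.0, 80.0, 90.0, 95.0])
    labels = np.array([1, 1, 1, 0, 0, 0])
    c = indeterminate_cutoff(scores, labels, 1.0)
    assert c > 30.0  # above every impaired score
    assert (scores[labels == 1] < c).mean() == 1.0


def test_indeterminate_specificity_matches_hand_enumeration():
    scores = np.array([5.0, 10, 15, 20, 25, 30, 35, 40, 45, 50.0])
    labels = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 1]) * (scores <= 45)
    c = indeterminate_cutoff(scores, labels, 0.9)
    # 9 impaired scores (5..45): 90% captured below the cutoff at c just
    # above the 9th-smallest impaired score (45); smaller cutoffs fail
    imp = np.sort(scores[labels == 1])
    assert (imp < c).mean() >= 0.9
    assert (imp < imp[-1]).mean() < 0.9
    with pytest.raises(ValueError):
        indeterminate_cutoff(scores, labels, -0.2)
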