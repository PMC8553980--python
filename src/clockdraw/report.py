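"""Pipeline orchestration and human-readable reporting.

:func:`run_pipeline` drives the full flow — simulate, classify, extract
metrics, train, score, validate — writing every intermediate artifact to a
run directory with a seed-stamped manifest so runs are bit-reproducible.
:func:`render_report` turns a scored cohort into a markdown document whose
numbers are all traceable to pipeline artifacts (the renderer recomputes
nothing).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .ink import Condition, write_ink
from .metrics import compute_metrics, metrics_table
from .scoring import ClockScoringModel, ClockScoringResults, youden_cutoff
from .stats import delong_test, holm_adjust, rank_sum_test, roc_curve

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_cohort", "render_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and subject."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "clockdraw_run"
    n_train: int = 120
    n_test: int = 120
    impaired_fraction: float = 0.419
    cutoff_impaired: float = 60.0
    cutoff_indeterminate: float = 75.0
    metric_registry: str = "v1"
    d_merge_mm: float = _classify.D_MERGE_MM
    t_merge_s: float = _classify.T_MERGE_S
    ink_format: str = "csv"

    def __post_init__(self):
        if not self.cutoff_impaired < self.cutoff_indeterminate:
            raise ValueError("cutoff_impaired must be below cutoff_indeterminate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _cohort_to_artifacts(subs, cfg: RunConfig, out: Path, split: str):
    """Write ink + labels, classify, and extract metrics for one split."""
    ink_dir = out / "ink" / split
    cls_dir = out / "classified" / split
    ink_dir.mkdir(parents=True, exist_ok=True)
    cls_dir.mkdir(parents=True, exist_ok=True)
    rows, labels = [], {}
    for s in subs:
        sid = s.record.subject_id
        labels[sid] = s.record.label
        recs = {}
        for cond in Condition:
            sess = getattr(s.record, cond.value)
            try:
                write_ink(sess, ink_dir / f"{sid}_{cond.value}.{cfg.ink_format}",
                          cfg.ink_format, subject=sid)
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"stage=simulate subject={sid}: {e}") from e
            try:
                cd = _classify.classify_drawing(sess, d_merge=cfg.d_merge_mm,
                                                t_merge=cfg.t_merge_s)
                cd.to_json(cls_dir / f"{sid}_{cond.value}.json")
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"stage=classify subject={sid}: {e}") from e
            try:
                recs[cond.value] = compute_metrics(cd, registry_version=cfg.metric_registry)
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"stage=metrics subject={sid}: {e}") from e
        rows.append((sid, recs["command"], recs["copy"]))
    table = metrics_table(rows)
    lab = pd.Series(labels, name="label")
    return table, lab


def run_pipeline(config: RunConfig) -> Path:
    """Run the full pipeline; returns the artifact directory."""
    from .simulate import generate_cohort  # local import keeps startup light

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    train = generate_cohort(config.n_train, config.impaired_fraction, seed=config.seed)
    test = generate_cohort(config.n_test, config.impaired_fraction, seed=config.seed + 1)
    # renumber test subjects so artifact names do not collide
    for s in test:
        s.record.subject_id = "t" + s.record.subject_id[1:]

    tr_metrics, tr_labels = _cohort_to_artifacts(train, config, out, "train")
    te_metrics, te_labels = _cohort_to_artifacts(test, config, out, "test")
    tr_metrics.to_csv(out / "metrics_train.csv")
    te_metrics.to_csv(out / "metrics_test.csv")
    tr_labels.to_csv(out / "labels_train.csv")
    te_labels.to_csv(out / "labels_test.csv")

    try:
        model = ClockScoringModel(tr_metrics, tr_labels.to_numpy())
        results = model.fit(seed=config.seed,
                            cutoffs=(config.cutoff_impaired, config.cutoff_indeterminate))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage=train: {e}") from e
    results.save(out / "model.json")

    scored = results.score_table(te_metrics)
    scored.insert(0, "label", te_labels.reindex(scored.index))
    scored.to_csv(out / "scores_test.csv")

    validation = validate_cohort(scored["score"], scored["label"], scored)
    (out / "validation.json").write_text(json.dumps(validation, indent=1))
    (out / "report.md").write_text(render_report(_report_doc(scored, validation)))
    (out / "report.json").write_text(json.dumps(_report_doc(scored, validation), indent=1))

    manifest = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "artifacts": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
                            and p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def validate_cohort(scores, labels, table: Optional[pd.DataFrame] = None) -> dict:
    """Cohort-level validation: ROC/AUC of the overall score, the Youden
    operating point, and per-composite rank-sum contrasts with Holm
    adjustment."""
    labels = pd.Series(np.asarray(labels), index=None)
    unimp = (labels == "unimpaired").to_numpy()
    s = np.asarray(scores, dtype=float)
    roc = roc_curve(s, unimp)
    cut, sens, spec = youden_cutoff(s, ~unimp)
    out = {
        "n": int(len(s)),
        "n_unimpaired": int(unimp.sum()),
        "n_impaired": int((~unimp).sum()),
        "auc": round(roc.auc, 4),
        "youden_cutoff": round(cut, 2),
        "sensitivity": round(sens, 4),
        "specificity": round(spec, 4),
        "youden_j": round(sens + spec - 1.0, 4),
    }
    if table is not None:
        comps = [c for c in table.columns if "." in c]
        # paired DeLong comparison: does the combined score beat each
        # composite's own discrimination?
        delong = []
        for c in comps:
            v = table[c].to_numpy(dtype=float)
            if not np.isfinite(v).all() or np.ptp(v) == 0:
                continue
            t = delong_test(s, v, unimp)
            delong.append({"comparator": c, "auc_score": round(t.auc_a, 4),
                           "auc_comparator": round(t.auc_b, 4),
                           "z": round(t.z, 3), "p": float(t.p)})
        out["delong_vs_composites"] = delong
        contrasts, ps = [], []
        for c in comps:
            x = table.loc[~unimp, c].to_numpy(dtype=float)
            y = table.loc[unimp, c].to_numpy(dtype=float)
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
            if len(x) == 0 or len(y) == 0:
                continue
            u, p = rank_sum_test(x, y)
            contrasts.append({"measure": c, "U": u,
                              "median_impaired": float(np.median(x)),
                              "median_unimpaired": float(np.median(y)),
                              "p": p})
            ps.append(p)
        adj = holm_adjust(ps)
        for c, a in zip(contrasts, adj):
            c["p_holm"] = float(a)
            c["p"] = float(c["p"])
        out["contrasts"] = contrasts
    return out


def _report_doc(scored: pd.DataFrame, validation: dict) -> dict:
    """Assemble the renderable report document (pure data, no recomputation
    beyond rounding)."""
    subjects = []
    comp_cols = [c for c in scored.columns if "." in c]
    for sid, row in scored.iterrows():
        subjects.append({
            "subject": str(sid),
            "label": str(row.get("label", "")),
            "score": round(float(row["score"]), 2),
            "classification": str(row["classification"]),
            "composites": {c: round(float(row[c]), 3) for c in comp_cols},
        })
    return {"cohort": validation, "subjects": subjects}


def render_report(doc: dict) -> str:
    """Render the report document to markdown (deterministic)."""
    lines = ["# Clock-drawing cohort report", ""]
    coh = doc.get("cohort") or {}
    if coh:
        lines += ["## Cohort validation", ""]
        lines.append(f"- subjects: {coh.get('n', 0)} "
                     f"({coh.get('n_unimpaired', 0)} unimpaired / {coh.get('n_impaired', 0)} impaired)")
        if "auc" in coh:
            lines.append(f"- overall-score AUC: {coh['auc']}")
            lines.append(f"- Youden cutoff {coh['youden_cutoff']}: "
                         f"sensitivity {coh['sensitivity']}, specificity {coh['specificity']} "
                         f"(J = {coh['youden_j']})")
        if coh.get("contrasts"):
            lines += ["", "| measure | median (imp) | median (unimp) | p (Holm) |",
                      "|---|---|---|---|"]
            for c in coh["contrasts"]:
                lines.append(f"| {c['measure']} | {c['median_impaired']:.3f} | "
                             f"{c['median_unimpaired']:.3f} | {c['p_holm']:.2e} |")
        lines.append("")
    for s in doc.get("subjects", []):
        lines += [f"## Subject {s['subject']}", ""]
        lab = f" (cohort label: {s['label']})" if s.get("label") else ""
        lines.append(f"- score: **{s['score']}** -> {s['classification']}{lab}")
        worst = sorted(s["composites"].items(), key=lambda kv: kv[1])[:3]
        lines.append("- lowest composites: " + ", ".join(f"{k} = {v}" for k, v in worst))
        lines.append("")
    return "\n".join(lines)
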