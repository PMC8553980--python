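"""The drawing-metric catalogue: process and final-drawing measurements.

Given a classified drawing, :func:`compute_metrics` produces one
:class:`MetricRecord` per condition — total/think/ink time, latency
statistics, pen kinematics over the clock face, and geometric measures of
the final drawing (face size and roundness, component placement, page
position, unexpected-ink "noise").

Metrics whose exact published formula is unavailable (noise, oscillatory
motion, circularity, component placement, relative long latency) are
contract-compatible stand-ins registered in :data:`METRIC_REGISTRY` so
alternative definitions can be swapped without touching the scoring layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .classify import ClassifiedDrawing
from .labels import SymbolKind
from .simulate import expected_stroke_count

__all__ = [
    "MetricRecord",
    "CircleFit",
    "fit_circle",
    "compute_metrics",
    "metrics_table",
    "METRIC_REGISTRY",
    "METRIC_NAMES",
]

#: pen-lift gaps longer than LONG_LATENCY_FACTOR x the normative reference
#: median latency count as "long"; the reference is configurable.
REFERENCE_LATENCY_S = 0.7
LONG_LATENCY_FACTOR = 3.0

#: the 120-ms window defining initiation/termination speed
EDGE_WINDOW_S = 0.120


@dataclass(frozen=True)
class CircleFit:
    """Least-squares (Kasa) circle fit of the clock-face samples."""

    center: tuple[float, float]
    radius: float
    residuals: np.ndarray  # per-sample radial residual, mm


def fit_circle(x: np.ndarray, y: np.ndarray) -> CircleFit:
    """Algebraic least-squares circle fit; raises on degenerate input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to fit a circle")
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate (collinear) samples: no unique circle")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("degenerate circle fit")
    r = math.sqrt(r2)
    resid = np.hypot(x - cx, y - cy) - r
    return CircleFit((float(cx), float(cy)), float(r), resid)


@dataclass
class MetricRecord:
    """The full per-condition metric vector.

    Metrics whose prerequisites are absent (e.g. no clock face resolved)
    are NaN and listed in ``missing`` — never silently zero.
    """

    condition: str
    total_time: float = math.nan            # s
    ink_length: float = math.nan            # mm
    drawing_size: float = math.nan          # mm (face-circle diameter)
    drawing_process_efficiency: float = math.nan  # mm/s
    noise: float = math.nan
    stroke_count_conformity: float = math.nan
    percent_think_time: float = math.nan    # %
    percent_ink_time: float = math.nan      # %
    average_latency: float = math.nan       # s
    latency_variability: float = math.nan   # s
    relative_long_latency: float = math.nan
    long_latency_count: float = math.nan
    longest_latency: float = math.nan       # s
    average_speed: float = math.nan         # mm/s, clock face only
    max_speed: float = math.nan
    initiation_speed: float = math.nan
    termination_speed: float = math.nan
    oscillatory_motion: float = math.nan
    clock_face_circularity: float = math.nan  # mm
    component_placement: float = math.nan     # rad (RMS angular error)
    vertical_spatial_placement: float = math.nan  # mm
    missing: frozenset = field(default_factory=frozenset)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)
                if f.name not in ("condition", "missing")}


METRIC_NAMES = [f.name for f in dc_fields(MetricRecord) if f.name not in ("condition", "missing")]


# ---------------------------------------------------------------------------
# Registry of unpublished-formula metrics (swappable stand-ins)
# ---------------------------------------------------------------------------


def _noise_v1(ctx) -> float:
    """(noise + cross-out + overwrite ink) / total ink, offset by 0.39 so a
    clean drawing sits at the normative floor (~0.40 scale)."""
    bad = 0.0
    for g, lab in zip(ctx.classified.groups, ctx.classified.labels):
        if lab.kind in (SymbolKind.NOISE, SymbolKind.CROSS_OUT, SymbolKind.OVERWRITE):
            bad += sum(ctx.strokes[i].length_mm for i in g.stroke_indices)
    return 0.39 + bad / ctx.ink_length if ctx.ink_length > 0 else math.nan


def _relative_long_latency_v1(ctx) -> float:
    """Mean of the latencies at/above their 90th percentile, relative to the
    average latency (scale-free)."""
    lat = ctx.latencies
    if lat.size == 0 or lat.mean() <= 0:
        return math.nan
    top = lat[lat >= np.quantile(lat, 0.9)]
    return float(top.mean() / lat.mean())


def _oscillatory_motion_v1(ctx) -> float:
    """Mean absolute second difference of the pen heading per unit arc
    length over the clock face, x100."""
    pts, _ = ctx.face_samples
    if pts is None or len(pts) < 5:
        return math.nan
    d = np.diff(pts, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    keep = seg > 1e-9
    if keep.sum() < 4:
        return math.nan
    heading = np.unwrap(np.arctan2(d[keep, 1], d[keep, 0]))
    dd = np.diff(heading, n=2)
    return float(np.abs(dd).sum() / seg[keep].sum() * 100.0)


def _circularity_v1(ctx) -> float:
    """Mean absolute radial residual of the face circle fit, mm."""
    if ctx.circle is None:
        return math.nan
    return float(np.abs(ctx.circle.residuals).mean())


def _component_placement_v1(ctx) -> float:
    """RMS angular error (radians) of digits vs their canonical clock
    positions and hands vs the 11:10 targets."""
    if ctx.circle is None:
        return math.nan
    cx, cy = ctx.circle.center
    errs = []
    for g, lab in zip(ctx.classified.groups, ctx.classified.labels):
        if lab.kind is SymbolKind.DIGIT:
            ang = math.atan2(g.centroid[0] - cx, -(g.centroid[1] - cy))
            target = math.radians(30.0 * lab.value)
        elif lab.kind in (SymbolKind.HOUR_HAND, SymbolKind.MINUTE_HAND):
            st = ctx.strokes[g.stroke_indices[0]]
            p0 = np.array([st.x[0], st.y[0]])
            p1 = np.array([st.x[-1], st.y[-1]])
            if math.hypot(*(p0 - (cx, cy))) > math.hypot(*(p1 - (cx, cy))):
                p0, p1 = p1, p0
            ang = math.atan2(p1[0] - p0[0], -(p1[1] - p0[1]))
            target = math.radians(335.0) if lab.kind is SymbolKind.HOUR_HAND else math.radians(60.0)
        else:
            continue
        e = (ang - target + math.pi) % (2 * math.pi) - math.pi
        errs.append(e)
    if not errs:
        return math.nan
    return float(np.sqrt(np.mean(np.square(errs))))


METRIC_REGISTRY: dict[str, dict[str, Callable]] = {
    "v1": {
        "noise": _noise_v1,
        "relative_long_latency": _relative_long_latency_v1,
        "oscillatory_motion": _oscillatory_motion_v1,
        "clock_face_circularity": _circularity_v1,
        "component_placement": _component_placement_v1,
    }
}


class _Ctx:
    """Shared intermediates passed to registry metrics."""

    def __init__(self, classified, strokes, latencies, ink_length, circle, face_samples):
        self.classified = classified
        self.strokes = strokes
        self.latencies = latencies
        self.ink_length = ink_length
        self.circle = circle
        self.face_samples = face_samples


def _smooth3(a: np.ndarray) -> np.ndarray:
    if a.size < 3:
        return a
    out = a.copy()
    out[1:-1] = (a[:-2] + a[1:-1] + a[2:]) / 3.0
    return out


def compute_metrics(
    classified: ClassifiedDrawing,
    *,
    reference_latency_s: float = REFERENCE_LATENCY_S,
    long_latency_factor: float = LONG_LATENCY_FACTOR,
    registry_version: str = "v1",
) -> MetricRecord:
    """Compute the full metric vector for one classified drawing."""
    session = classified.session
    strokes = session.strokes
    if not strokes:
        raise ValueError("empty drawing")
    reg = METRIC_REGISTRY[registry_version]
    missing: set[str] = set()

    rec = MetricRecord(condition=session.condition.value)

    # --- time & ink ------------------------------------------------------
    t0 = strokes[0].start_t
    t1 = strokes[-1].end_t
    rec.total_time = (t1 - t0) / 1000.0
    rec.ink_length = float(sum(st.length_mm for st in strokes))
    ink_time = sum(st.duration_ms for st in strokes) / 1000.0
    if rec.total_time > 0:
        rec.percent_ink_time = 100.0 * ink_time / rec.total_time
        rec.percent_think_time = 100.0 - rec.percent_ink_time
        rec.drawing_process_efficiency = rec.ink_length / rec.total_time
    else:
        missing.update({"percent_ink_time", "percent_think_time", "drawing_process_efficiency"})

    # --- latencies -------------------------------------------------------
    lat = np.array([
        max((strokes[i + 1].start_t - strokes[i].end_t) / 1000.0, 0.0)
        for i in range(len(strokes) - 1)
    ])
    if lat.size:
        rec.average_latency = float(lat.mean())
        rec.latency_variability = float(lat.std(ddof=1)) if lat.size > 1 else 0.0
        rec.longest_latency = float(lat.max())
        rec.long_latency_count = float((lat > long_latency_factor * reference_latency_s).sum())
    else:
        missing.update({"average_latency", "latency_variability", "longest_latency",
                        "relative_long_latency", "long_latency_count"})

    # --- face-dependent metrics -----------------------------------------
    face_groups = classified.groups_by_kind(SymbolKind.CLOCK_FACE)
    circle = None
    face_pts, face_t = None, None
    if face_groups:
        g = face_groups[0][0]
        fx = np.concatenate([strokes[i].x for i in g.stroke_indices])
        fy = np.concatenate([strokes[i].y for i in g.stroke_indices])
        ft = np.concatenate([strokes[i].t for i in g.stroke_indices])
        try:
            circle = fit_circle(fx, fy)
        except ValueError:
            circle = None
        face_pts = np.column_stack([_smooth3(fx), _smooth3(fy)])
        face_t = ft / 1000.0
    if circle is not None:
        rec.drawing_size = 2.0 * circle.radius
        rec.vertical_spatial_placement = abs(circle.center[1] - session.page[1] / 2.0)
    else:
        missing.update({"drawing_size", "vertical_spatial_placement",
                        "clock_face_circularity", "component_placement"})

    # speeds over the face only: centred differences on 3-sample-smoothed
    # coordinates
    if face_pts is not None and len(face_pts) >= 5:
        dt = face_t[2:] - face_t[:-2]
        ok = dt > 1e-9
        v = np.hypot(face_pts[2:, 0] - face_pts[:-2, 0],
                     face_pts[2:, 1] - face_pts[:-2, 1])[ok] / dt[ok]
        tv = face_t[1:-1][ok]
        if v.size:
            rec.average_speed = float(v.mean())
            rec.max_speed = float(v.max())
            first = v[tv - tv[0] <= EDGE_WINDOW_S]
            last = v[tv[-1] - tv <= EDGE_WINDOW_S]
            rec.initiation_speed = float(first.mean()) if first.size else float(v[0])
            rec.termination_speed = float(last.mean()) if last.size else float(v[-1])
    else:
        missing.update({"average_speed", "max_speed", "initiation_speed",
                        "termination_speed", "oscillatory_motion"})

    # --- counts ----------------------------------------------------------
    n_expected = expected_stroke_count()
    n_observed = sum(
        len(g.stroke_indices)
        for g, lab in zip(classified.groups, classified.labels)
        if lab.kind is not SymbolKind.NOISE
    )
    rec.stroke_count_conformity = float(abs(n_observed - n_expected))

    # --- registry metrics ------------------------------------------------
    ctx = _Ctx(classified, strokes, lat, rec.ink_length, circle, (face_pts, face_t))
    for name, fn in reg.items():
        if name in missing:
            continue
        val = fn(ctx)
        if isinstance(val, float) and math.isnan(val):
            missing.add(name)
        else:
            setattr(rec, name, val)

    rec.missing = frozenset(missing)
    return rec


def metrics_table(records: list[tuple[str, MetricRecord, MetricRecord]]) -> pd.DataFrame:
    """Tidy table: one row per subject, columns ``command.<metric>`` and
    ``copy.<metric>``; input is (subject_id, command record, copy record)."""
    rows = {}
    for sid, cmd, copy in records:
        row = {}
        for cond, rec in (("command", cmd), ("copy", copy)):
            if rec is None:
                continue
            for k, v in rec.to_dict().items():
                row[f"{cond}.{k}"] = v
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")
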