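"""Seeded generator of labeled clock drawings for two cohorts.

The generator emulates the drawing process of the clock-drawing test —
Command ("draw a clock showing 10 minutes after 11") and Copy conditions —
for a cognitively unimpaired and a cognitively impaired cohort.  It is the
test bed standing in for restricted clinical data: its default calibration
is a plain CSV table of per-cohort normative medians and quartiles, and the
drawing process is constructed so the extracted metric distributions
reproduce those table cells.

Construction principles
-----------------------
* Headline quantities (total time, think-time fraction, clock-face
  diameter, total ink length) are sampled per drawing from right-skewed
  families (lognormal; logit-normal for fractions) whose median/quartiles
  come straight from the calibration table.
* Everything else is *emergent*: ink length is allocated across face,
  digits, hands and noise strokes; think time is divided among inter-stroke
  latencies (one designated "long pause" plus short within/between-symbol
  gaps); so identities like percent-think + percent-ink = 100 hold by
  construction.
* Impairment is a parameter vector, not a switch: both cohorts run the
  same machinery with different :class:`CohortParams`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._glyphs import digit_strokes, digit_stroke_count, polyline_length
from .ink import Condition, DrawingSession, Stroke, SubjectRecord, US_LETTER_MM
from .labels import SymbolKind, SymbolLabel

__all__ = [
    "CohortParams",
    "GroundTruth",
    "SimulatedSubject",
    "GenerationError",
    "default_calibration",
    "expected_stroke_count",
    "generate_drawing",
    "generate_cohort",
]

SAMPLE_DT_S = 0.012  # pen temporal resolution
_Z_IQR = 2 * 0.6744897501960817  # quartile spread of a standard normal


class GenerationError(ValueError):
    """Degenerate generator parameters (e.g. non-positive clock size)."""


@dataclass(frozen=True)
class CohortParams:
    """Per-cohort, per-condition generator calibration.

    The ``*_med/_q1/_q3`` fields are normative median/quartile targets in
    the units of the corresponding drawing metric; the remaining fields are
    kinematic/structural choices (documented in the methods note).  Stored
    as a plain CSV data table (one row per cohort x condition) so users can
    edit them.
    """

    cohort: str
    condition: str
    # headline distributions (units: s, mm, %)
    total_time_med: float
    total_time_q1: float
    total_time_q3: float
    ink_length_med: float
    ink_length_q1: float
    ink_length_q3: float
    drawing_size_med: float
    drawing_size_q1: float
    drawing_size_q3: float
    percent_think_med: float
    percent_think_q1: float
    percent_think_q3: float
    # latency structure (s)
    average_latency_med: float
    longest_latency_med: float
    longest_latency_q1: float
    longest_latency_q3: float
    intra_latency_med: float
    intra_latency_sigma: float
    inter_latency_sigma: float
    latency_calib: float  # solved multiplier on the raw long-pause median
    # face kinematics (mm/s)
    average_speed_med: float
    average_speed_q1: float
    average_speed_q3: float
    max_speed_med: float
    initiation_speed_med: float
    termination_speed_med: float
    # shape perturbations
    circularity_med: float
    circularity_q1: float
    circularity_q3: float
    tremor_amp_mm: float
    tremor_hz: float
    digit_jitter_rad: float
    hand_jitter_rad: float
    digit_radius_frac: float
    radial_jitter_frac: float
    hour_hand_frac: float
    minute_hand_frac: float
    hand_len_jitter: float
    # page placement
    vertical_offset_med: float
    center_x_sd: float
    # unexpected-stroke process
    noise_rate: float
    noise_len_med: float
    noise_len_sigma: float
    omission_rate: float
    overwrite_rate: float
    crossout_rate: float

    def replace(self, **kw) -> "CohortParams":
        return dataclasses.replace(self, **kw)


def _sigma(med: float, q1: float, q3: float) -> float:
    """Lognormal shape parameter matching a printed median/IQR."""
    if med <= 0 or q1 <= 0 or q3 <= q1:
        return 0.0
    return math.log(q3 / q1) / _Z_IQR


_CAL_CACHE: dict[tuple[str, str], CohortParams] = {}


def _calibration_path() -> Path:
    return Path(str(resources.files("clockdraw") / "data" / "calibration.csv"))


def default_calibration(
    cohort: str, condition: Condition | str, path: Optional[Path] = None
) -> CohortParams:
    """Load the shipped (or a user-edited) calibration row."""
    cond = Condition(condition).value
    key = (cohort, cond)
    if path is None and key in _CAL_CACHE:
        return _CAL_CACHE[key]
    table = pd.read_csv(path or _calibration_path())
    row = table[(table.cohort == cohort) & (table.condition == cond)]
    if len(row) != 1:
        raise KeyError(f"no calibration row for cohort={cohort!r}, condition={cond!r}")
    params = CohortParams(**row.iloc[0].to_dict())
    if path is None:
        _CAL_CACHE[key] = params
    return params


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

#: canonical symbol order: face, digits 12, 1..11, hour hand, minute hand
DIGIT_ORDER = (12, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11)

#: 11:10 -> hour hand at the continuous 11h10 position, minute hand at "2".
HOUR_HAND_ANGLE = math.radians((11 + 10 / 60) * 30.0)
MINUTE_HAND_ANGLE = math.radians(60.0)


def expected_stroke_count() -> int:
    """Template stroke count: face + all digit glyph strokes + two hands."""
    return 1 + sum(digit_stroke_count(v) for v in DIGIT_ORDER) + 2


@dataclass
class GroundTruth:
    """Per-stroke labels and intended geometry for one generated drawing."""

    stroke_labels: list[SymbolLabel]
    symbol_ids: list[int]  # strokes sharing an id belong to one symbol
    digit_angles: dict[int, float]  # intended (canonical) clock angle, rad
    hand_angles: tuple[float, float]  # (hour, minute), rad from 12
    face_center: tuple[float, float]
    face_radius: float
    expected_strokes: int = field(default_factory=expected_stroke_count)


@dataclass
class SimulatedSubject:
    """A generated subject: the ink record plus the generator's truth."""

    record: SubjectRecord
    truth_command: GroundTruth
    truth_copy: GroundTruth


# ---------------------------------------------------------------------------
# Geometry builders
# ---------------------------------------------------------------------------


def _clock_xy(center, r, angle):
    """Clock angle (rad from 12, clockwise) to page coords (y down)."""
    return center[0] + r * np.sin(angle), center[1] - r * np.cos(angle)


def _lognorm(rng, med, sig, size=None):
    if med <= 0:
        return np.zeros(size) if size is not None else 0.0
    return med * np.exp(sig * rng.standard_normal(size))


def _build_face_path(rng, center, radius, circ_amp, n=540):
    """Dense near-closed circle with low-order radial harmonics."""
    gap = rng.uniform(0.5, 3.0)  # mm of pen-up gap at closure
    a0 = rng.normal(0.0, 0.2)
    span = 2 * math.pi - gap / radius
    alpha = a0 + np.linspace(0.0, span, n) * (1 if rng.random() < 0.5 else -1)
    k = rng.integers(2, 5)
    phase = rng.uniform(0, 2 * math.pi)
    r = radius + circ_amp * np.sin(k * alpha + phase)
    x, y = _clock_xy(center, r, alpha)
    return np.column_stack([x, y])


def _sample_stroke_path(path, duration, profile_cdf=None):
    """Resample a dense polyline at the pen's 12-ms tick.

    ``profile_cdf`` is an optional (u_grid, cdf_grid) pair mapping
    normalized time to normalized arc length (non-uniform speed).
    """
    seg = np.hypot(*np.diff(path, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(duration / SAMPLE_DT_S), 1)
    t = np.arange(n + 1) * SAMPLE_DT_S
    if t[-1] < duration - 1e-12:
        t = np.append(t, duration)
    else:
        t[-1] = duration
    u = t / duration if duration > 0 else np.zeros_like(t)
    frac = np.interp(u, *profile_cdf) if profile_cdf is not None else u
    st = frac * total
    x = np.interp(st, s, path[:, 0])
    y = np.interp(st, s, path[:, 1])
    return np.column_stack([x, y]), t


def _speed_profile_cdf(avg_med, max_med, n=257):
    """Bell-shaped speed profile: slow start/finish, mid-stroke peak.

    Returns (u_grid, arc-length cdf) with mean speed 1 and peak
    ``max_med/avg_med``; the Gaussian bump width is fixed at 0.1 of the
    stroke.
    """
    sg = 0.10
    peak = max(max_med / avg_med, 1.05)
    amp = (peak - 1.0) / (1.0 - sg * math.sqrt(2 * math.pi))
    base = 1.0 - amp * sg * math.sqrt(2 * math.pi)
    u = np.linspace(0.0, 1.0, n)
    shape = base + amp * np.exp(-((u - 0.5) ** 2) / (2 * sg * sg))
    cdf = np.concatenate([[0.0], np.cumsum((shape[1:] + shape[:-1]) * 0.5 * np.diff(u))])
    return u, cdf / cdf[-1]


# ---------------------------------------------------------------------------
# Drawing generation
# ---------------------------------------------------------------------------


def generate_drawing(
    params: CohortParams,
    condition: Condition | str | None = None,
    seed: int | np.random.Generator = 0,
    *,
    randomize_digit_order: bool = False,
    page: tuple[float, float] = US_LETTER_MM,
) -> tuple[DrawingSession, GroundTruth]:
    """Generate one labeled clock drawing; deterministic given the seed."""
    cond = Condition(condition) if condition is not None else Condition(params.condition)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if params.drawing_size_med <= 0 or params.total_time_med <= 0 or params.ink_length_med <= 0:
        raise GenerationError("non-positive size/time/ink calibration")

    # --- headline draws -------------------------------------------------
    T_total = _lognorm(rng, params.total_time_med, _sigma(
        params.total_time_med, params.total_time_q1, params.total_time_q3))
    p = params.percent_think_med / 100.0
    lo, hi = params.percent_think_q1 / 100.0, params.percent_think_q3 / 100.0
    mu_f = math.log(p / (1 - p))
    sig_f = (math.log(hi / (1 - hi)) - math.log(lo / (1 - lo))) / _Z_IQR
    f_think = 1.0 / (1.0 + math.exp(-(mu_f + sig_f * rng.standard_normal())))
    f_think = min(max(f_think, 0.25), 0.88)
    T_think, T_ink = f_think * T_total, (1 - f_think) * T_total

    sig_size = _sigma(params.drawing_size_med, params.drawing_size_q1, params.drawing_size_q3)
    D = _lognorm(rng, params.drawing_size_med, sig_size)
    D = min(max(D, 18.0), 0.85 * min(page))
    R = D / 2.0

    sig_ink = _sigma(params.ink_length_med, params.ink_length_q1, params.ink_length_q3)
    ratio_med = params.ink_length_med / (math.pi * params.drawing_size_med)
    sig_ratio = math.sqrt(max(sig_ink**2 - sig_size**2, 0.06**2))
    ratio = max(_lognorm(rng, ratio_med, sig_ratio), 1.18)
    L_target = math.pi * D * ratio

    # --- page placement -------------------------------------------------
    margin = R + 8.0
    v_sd = params.vertical_offset_med / 0.6744897501960817
    cy = page[1] / 2.0 + float(np.clip(rng.normal(0.0, v_sd), -(page[1] / 2 - margin), page[1] / 2 - margin))
    cx = page[0] / 2.0 + float(np.clip(rng.normal(0.0, params.center_x_sd), -(page[0] / 2 - margin), page[0] / 2 - margin))
    center = (cx, cy)

    # --- face -----------------------------------------------------------
    # mean |a sin| = 2a/pi, so a = pi/2 * target mean-absolute radial residual
    circ_amp = _lognorm(rng, math.pi / 2.0 * params.circularity_med,
                        _sigma(params.circularity_med, params.circularity_q1, params.circularity_q3)) \
        if params.circularity_med > 0 else 0.0
    face_path = _build_face_path(rng, center, R, circ_amp)
    face_len0 = polyline_length(face_path)

    v_face = _lognorm(rng, params.average_speed_med, _sigma(
        params.average_speed_med, params.average_speed_q1, params.average_speed_q3))
    t_face = face_len0 / max(v_face, 1e-6)
    if t_face > 0.7 * T_ink:
        t_face = 0.7 * T_ink
    profile = _speed_profile_cdf(params.average_speed_med, params.max_speed_med)
    face_pts, face_t = _sample_stroke_path(face_path, t_face, profile)
    if params.tremor_amp_mm > 0:
        amp = _lognorm(rng, params.tremor_amp_mm, 0.3)
        tang = np.gradient(face_pts, axis=0)
        norm = np.hypot(tang[:, 0], tang[:, 1])
        norm[norm == 0] = 1.0
        nvec = np.column_stack([-tang[:, 1] / norm, tang[:, 0] / norm])
        face_pts = face_pts + nvec * (amp * np.sin(2 * math.pi * params.tremor_hz * face_t
                                                   + rng.uniform(0, 2 * math.pi)))[:, None]
    face_len = polyline_length(face_pts)

    # --- symbol plan ----------------------------------------------------
    order = list(DIGIT_ORDER)
    if randomize_digit_order:
        order = list(rng.permutation(order))
    n_omit = min(int(rng.poisson(params.omission_rate)), 3)
    omitted = set(rng.choice([v for v in order if v != 12], size=n_omit, replace=False)) if n_omit else set()
    drawn = [v for v in order if v not in omitted]
    n_over = min(int(rng.poisson(params.overwrite_rate)), 2)
    n_cross = min(int(rng.poisson(params.crossout_rate)), 2)
    n_noise = int(rng.poisson(params.noise_rate))

    digit_r = {v: R * params.digit_radius_frac * (1 + rng.normal(0, params.radial_jitter_frac))
               for v in drawn}
    digit_theta = {v: math.radians(v * 30.0) + rng.normal(0, params.digit_jitter_rad) for v in drawn}

    hour_a = HOUR_HAND_ANGLE + rng.normal(0, params.hand_jitter_rad)
    minute_a = MINUTE_HAND_ANGLE + rng.normal(0, params.hand_jitter_rad)
    hour_len = R * params.hour_hand_frac * (1 + rng.normal(0, params.hand_len_jitter))
    minute_len = R * params.minute_hand_frac * (1 + rng.normal(0, params.hand_len_jitter))

    noise_lens = _lognorm(rng, params.noise_len_med, params.noise_len_sigma, n_noise) if n_noise else np.array([])
    hands_len = (hour_len - 0.06 * R) + (minute_len - 0.06 * R)

    # glyph scale: allocate remaining ink budget across digit/overwrite/
    # cross-out glyph units
    over_vals = list(rng.choice(drawn, size=n_over, replace=False)) if n_over else []
    cross_vals = list(rng.choice(drawn, size=n_cross, replace=False)) if n_cross else []
    unit_total = sum(sum(polyline_length(s) for s in digit_strokes(v)) for v in drawn)
    unit_total += sum(sum(polyline_length(s) for s in digit_strokes(v)) for v in over_vals)
    unit_total += 2.4 * len(cross_vals)  # cross-out stroke ~2.4 glyph heights long
    budget = L_target - face_len - hands_len - float(noise_lens.sum())
    h = budget / unit_total if unit_total > 0 else 0.0
    # glyph scale bounded so digits stay legible and groupable
    h = min(max(h, 3.5), 12.5, 0.40 * R)

    # --- assemble stroke geometry in drawing order ----------------------
    geoms: list[np.ndarray] = []           # dense paths
    labels: list[SymbolLabel] = []
    sym_ids: list[int] = []
    sid = 0

    geoms.append(face_pts)
    labels.append(SymbolLabel(SymbolKind.CLOCK_FACE))
    sym_ids.append(sid)

    for v in drawn:
        sid += 1
        px, py = _clock_xy(center, digit_r[v], digit_theta[v])
        for st in digit_strokes(v):
            geoms.append(st * h + np.array([px, py]))
            labels.append(SymbolLabel(SymbolKind.DIGIT, v))
            sym_ids.append(sid)

    for angle, length, kind in (
        (hour_a, hour_len, SymbolKind.HOUR_HAND),
        (minute_a, minute_len, SymbolKind.MINUTE_HAND),
    ):
        sid += 1
        bx, by = _clock_xy(center, 0.06 * R, angle + rng.normal(0, 0.3))
        tx, ty = _clock_xy(center, length, angle)
        mid = np.array([(bx + tx) / 2, (by + ty) / 2]) + rng.normal(0, 0.4, 2)
        geoms.append(np.array([[bx, by], list(mid), [tx, ty]]))
        labels.append(SymbolLabel(kind))
        sym_ids.append(sid)

    for v in over_vals:  # overdrawn duplicate of an existing digit
        sid += 1
        px, py = _clock_xy(center, digit_r[v], digit_theta[v])
        off = rng.normal(0, 1.2, 2)
        for st in digit_strokes(v):
            geoms.append(st * (h * 1.05) + np.array([px, py]) + off)
            labels.append(SymbolLabel(SymbolKind.OVERWRITE))
            sym_ids.append(sid)

    for v in cross_vals:  # a stroke struck through a digit
        sid += 1
        px, py = _clock_xy(center, digit_r[v], digit_theta[v])
        ca = rng.uniform(0, math.pi)
        dx, dy = 1.2 * h * math.cos(ca), 1.2 * h * math.sin(ca)
        geoms.append(np.array([[px - dx, py - dy], [px + 0.1 * dy, py - 0.1 * dx], [px + dx, py + dy]]))
        labels.append(SymbolLabel(SymbolKind.CROSS_OUT))
        sym_ids.append(sid)

    for ln in noise_lens:  # small stray marks outside the rim
        sid += 1
        na = rng.uniform(0, 2 * math.pi)
        nr = R * rng.uniform(1.06, 1.30)
        px, py = _clock_xy(center, nr, na)
        da = rng.uniform(0, math.pi)
        dx, dy = 0.5 * ln * math.cos(da), 0.5 * ln * math.sin(da)
        geoms.append(np.array([[px - dx, py - dy], [px + 0.2 * dy, py + 0.2 * dx], [px + dx, py + dy]]))
        labels.append(SymbolLabel(SymbolKind.NOISE))
        sym_ids.append(sid)

    # clip everything to the page
    for g in geoms:
        np.clip(g[:, 0], 1.0, page[0] - 1.0, out=g[:, 0])
        np.clip(g[:, 1], 1.0, page[1] - 1.0, out=g[:, 1])

    # --- timing ---------------------------------------------------------
    lens = np.array([polyline_length(g) for g in geoms])
    rest_len = lens[1:].sum()
    t_rest = max(T_ink - t_face, 0.15 * T_ink)
    v_rest = rest_len / t_rest if rest_len > 0 else 1.0
    durations = np.concatenate([[t_face], lens[1:] / max(v_rest, 1e-9)])

    n_lat = len(geoms) - 1
    intra = np.array([sym_ids[i] == sym_ids[i + 1] for i in range(n_lat)])
    raw = np.where(
        intra,
        _lognorm(rng, params.intra_latency_med, params.intra_latency_sigma, n_lat),
        _lognorm(rng, _inter_latency_med(params), params.inter_latency_sigma, n_lat),
    )
    inter_idx = np.flatnonzero(~intra)
    long_sig = _sigma(params.longest_latency_med, params.longest_latency_q1, params.longest_latency_q3)
    if inter_idx.size:
        li = int(rng.choice(inter_idx))
        raw[li] = _lognorm(rng, params.longest_latency_med * params.latency_calib, long_sig)
    latencies = raw * (T_think / raw.sum()) if n_lat else raw

    # --- emit strokes ----------------------------------------------------
    strokes: list[Stroke] = []
    t0 = 0.0
    for i, g in enumerate(geoms):
        if i == 0:
            pts, tt = face_pts, face_t
        else:
            pts, tt = _sample_stroke_path(g, durations[i])
        strokes.append(Stroke(pts[:, 0], pts[:, 1], (t0 + tt) * 1000.0))
        if i < n_lat:
            t0 += durations[i] + latencies[i]

    session = DrawingSession(cond, strokes, page)
    truth = GroundTruth(
        stroke_labels=labels,
        symbol_ids=sym_ids,
        digit_angles={v: math.radians(v * 30.0) for v in drawn},
        hand_angles=(HOUR_HAND_ANGLE, MINUTE_HAND_ANGLE),
        face_center=center,
        face_radius=R,
    )
    return session, truth


def _inter_latency_med(params: CohortParams) -> float:
    """Between-symbol short-pause median solved from the think-time budget.

    With the base template (9 within-symbol gaps, 14 between-symbol gaps,
    one of which is the long pause), the raw gap means are solved so their
    expected sum matches the median think time; per-drawing rescaling then
    makes the sum exact.
    """
    t_think = params.total_time_med * params.percent_think_med / 100.0
    n_intra, n_inter = 9, 13
    long_sig = _sigma(params.longest_latency_med, params.longest_latency_q1, params.longest_latency_q3)
    used = (
        n_intra * params.intra_latency_med * math.exp(params.intra_latency_sigma**2 / 2)
        + params.longest_latency_med * params.latency_calib * math.exp(long_sig**2 / 2)
    )
    med = (t_think - used) / (n_inter * math.exp(params.inter_latency_sigma**2 / 2))
    return max(med, 0.05)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def generate_cohort(
    n: int,
    impaired_fraction: float,
    seed: int = 0,
    *,
    calibration_path: Optional[Path] = None,
) -> list[SimulatedSubject]:
    """Generate ``n`` subjects (Command + Copy each) with labels assigned
    exactly per ``impaired_fraction`` (rounded); per-subject seeds derive
    reproducibly from the master seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= impaired_fraction <= 1.0:
        raise ValueError("impaired_fraction must be in [0, 1]")
    n_imp = int(round(n * impaired_fraction))
    master = np.random.SeedSequence(seed)
    label_rng = np.random.default_rng(master.spawn(1)[0])
    status = np.array(["impaired"] * n_imp + ["unimpaired"] * (n - n_imp))
    label_rng.shuffle(status)

    params = {
        (c, cond.value): default_calibration(c, cond, path=calibration_path)
        for c in ("unimpaired", "impaired")
        for cond in Condition
    }
    out: list[SimulatedSubject] = []
    for i, child in enumerate(master.spawn(n + 1)[1:]):
        lab = str(status[i])
        ss_cmd, ss_copy = child.spawn(2)
        sess_cmd, truth_cmd = generate_drawing(
            params[(lab, "command")], Condition.COMMAND, np.random.default_rng(ss_cmd))
        sess_copy, truth_copy = generate_drawing(
            params[(lab, "copy")], Condition.COPY, np.random.default_rng(ss_copy))
        rec = SubjectRecord(
            subject_id=f"s{i:05d}", command=sess_cmd, copy=sess_copy, label=lab)
        out.append(SimulatedSubject(rec, truth_cmd, truth_copy))
    return out
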