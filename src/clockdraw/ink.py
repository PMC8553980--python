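"""Domain types and I/O for digitized pen-stroke data.

The digitizing pen records time-stamped page coordinates while the subject
draws a clock.  This module fixes the coordinate conventions every downstream
geometric measurement relies on:

* x, y in millimetres, origin at the top-left page corner, y increasing
  downward;
* t in milliseconds since the first pen-down of the session;
* one :class:`Stroke` per pen-down..pen-up interval, strokes ordered in time.

Three lossless interchange formats are supported: a minimal CSV dialect
(one row per sample), a JSON mirror of the same schema, and a subset of
W3C InkML (one ``trace`` per stroke with an explicit timestamp channel).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "US_LETTER_MM",
    "Condition",
    "PenSample",
    "Stroke",
    "DrawingSession",
    "SubjectRecord",
    "Violation",
    "InkParseError",
    "read_ink",
    "write_ink",
    "validate_session",
]

#: Default page size (width, height) in mm -- US Letter.
US_LETTER_MM = (215.9, 279.4)

#: Stated device resolution: +-0.05 cm spatial, 12 ms temporal.
SPATIAL_RESOLUTION_MM = 0.5
TEMPORAL_RESOLUTION_MS = 12.0


class Condition(str, enum.Enum):
    """The two administrations of the clock-drawing test."""

    COMMAND = "command"
    COPY = "copy"


@dataclass(frozen=True)
class PenSample:
    """One pen position: x/y in mm (origin top-left, y down), t in ms."""

    x: float
    y: float
    t: float


class Stroke:
    """An ordered pen-down..pen-up sequence of samples.

    Coordinates are held as numpy arrays for efficient geometry; the
    ``samples`` property exposes the record view.
    """

    __slots__ = ("x", "y", "t")

    def __init__(self, x: Sequence[float], y: Sequence[float], t: Sequence[float]):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.t = np.asarray(t, dtype=float)
        if not (self.x.shape == self.y.shape == self.t.shape) or self.x.ndim != 1:
            raise ValueError("x, y, t must be 1-D arrays of equal length")
        if self.x.size < 1:
            raise ValueError("a stroke needs at least one sample")

    def __len__(self) -> int:
        return self.x.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Stroke)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.t, other.t)
        )

    def __repr__(self) -> str:
        return f"Stroke(n={len(self)}, t=[{self.t[0]:.0f}..{self.t[-1]:.0f}] ms)"

    @property
    def samples(self) -> list[PenSample]:
        return [PenSample(*v) for v in zip(self.x, self.y, self.t)]

    @property
    def start_t(self) -> float:
        return float(self.t[0])

    @property
    def end_t(self) -> float:
        return float(self.t[-1])

    @property
    def duration_ms(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def length_mm(self) -> float:
        """Polyline arc length."""
        if len(self) < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.x.mean()), float(self.y.mean())


@dataclass
class DrawingSession:
    """One subject's drawing for one condition: ordered strokes on a page."""

    condition: Condition
    strokes: list[Stroke]
    page: tuple[float, float] = US_LETTER_MM

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)

    @property
    def total_time_ms(self) -> float:
        """First pen-down to last pen-up."""
        if not self.strokes:
            return 0.0
        return self.strokes[-1].end_t - self.strokes[0].start_t

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DrawingSession)
            and self.condition == other.condition
            and self.page == other.page
            and self.strokes == other.strokes
        )


@dataclass
class SubjectRecord:
    """Both conditions for one subject, with optional cohort label."""

    subject_id: str
    command: Optional[DrawingSession] = None
    copy: Optional[DrawingSession] = None
    label: Optional[str] = None  # "unimpaired" | "impaired"
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_session`."""

    kind: str
    stroke: Optional[int]
    sample: Optional[int]
    message: str


class InkParseError(ValueError):
    """Malformed ink file; message names the offending line/element."""


class InkValidationError(ValueError):
    """Ink data violates a session invariant (e.g. non-monotone time)."""


def validate_session(session: DrawingSession) -> list[Violation]:
    """Check all session invariants; returns violations, never raises.

    Checked per sample: finite coordinates, within page bounds, t >= 0.
    Per stroke: non-decreasing timestamps.  Per session: strokes temporally
    ordered (stroke i ends at or before stroke i+1 begins) and >= 1 stroke.
    """
    out: list[Violation] = []
    w, h = session.page
    if not session.strokes:
        out.append(Violation("empty_session", None, None, "session has no strokes"))
        return out
    for si, st in enumerate(session.strokes):
        bad = ~(np.isfinite(st.x) & np.isfinite(st.y) & np.isfinite(st.t))
        for i in np.flatnonzero(bad):
            out.append(Violation("nonfinite", si, int(i), f"stroke {si} sample {i} non-finite"))
        off = (st.x < 0) | (st.x > w) | (st.y < 0) | (st.y > h)
        for i in np.flatnonzero(off & ~bad):
            out.append(
                Violation(
                    "out_of_page", si, int(i),
                    f"stroke {si} sample {i} at ({st.x[i]:.2f}, {st.y[i]:.2f}) outside page {w}x{h} mm",
                )
            )
        for i in np.flatnonzero(st.t < 0):
            out.append(Violation("negative_time", si, int(i), f"stroke {si} sample {i} t<0"))
        dec = np.flatnonzero(np.diff(st.t) < 0)
        for i in dec:
            out.append(
                Violation("nonmonotone_time", si, int(i + 1), f"stroke {si} timestamps decrease at sample {i + 1}")
            )
        if si > 0 and st.start_t < session.strokes[si - 1].end_t:
            out.append(
                Violation(
                    "stroke_overlap", si, None,
                    f"stroke {si} begins at {st.start_t:.1f} ms before stroke {si - 1} ends",
                )
            )
    return out


def _require_valid(session: DrawingSession, where: str) -> None:
    v = validate_session(session)
    if v:
        raise InkValidationError(f"{where}: {v[0].message} ({len(v)} violation(s))")


# ---------------------------------------------------------------------------
# CSV dialect: subject,condition,stroke_index,x_mm,y_mm,t_ms
# ---------------------------------------------------------------------------

_CSV_HEADER = "subject,condition,stroke_index,x_mm,y_mm,t_ms"


def _write_csv(session: DrawingSession, path: Path, subject: str) -> None:
    lines = [_CSV_HEADER]
    for si, st in enumerate(session.strokes):
        for x, y, t in zip(st.x, st.y, st.t):
            lines.append(f"{subject},{session.condition.value},{si},{x:.4f},{y:.4f},{t:.3f}")
    path.write_text("\n".join(lines) + "\n")


def _read_csv(path: Path, xy_scale: float, t_scale: float) -> DrawingSession:
    text = path.read_text().splitlines()
    if not text or text[0].strip() != _CSV_HEADER:
        raise InkParseError(f"{path}: line 1: expected header '{_CSV_HEADER}'")
    cond: Optional[str] = None
    per_stroke: dict[int, list[tuple[float, float, float]]] = {}
    for ln, row in enumerate(text[1:], start=2):
        if not row.strip():
            continue
        parts = row.split(",")
        if len(parts) != 6:
            raise InkParseError(f"{path}: line {ln}: expected 6 fields, got {len(parts)}")
        try:
            si = int(parts[2])
            x, y, t = float(parts[3]), float(parts[4]), float(parts[5])
        except ValueError as e:
            raise InkParseError(f"{path}: line {ln}: {e}") from None
        if cond is None:
            cond = parts[1]
        per_stroke.setdefault(si, []).append((x * xy_scale, y * xy_scale, t * t_scale))
    if not per_stroke:
        raise InkParseError(f"{path}: no samples")
    strokes = []
    for si in sorted(per_stroke):
        xs, ys, ts = zip(*per_stroke[si])
        strokes.append(Stroke(xs, ys, ts))
    return DrawingSession(Condition(cond), strokes)


# ---------------------------------------------------------------------------
# JSON mirror of the CSV schema
# ---------------------------------------------------------------------------


def _write_json(session: DrawingSession, path: Path, subject: str) -> None:
    doc = {
        "subject": subject,
        "condition": session.condition.value,
        "page_mm": list(session.page),
        "strokes": [
            {"x_mm": [round(v, 4) for v in st.x], "y_mm": [round(v, 4) for v in st.y],
             "t_ms": [round(v, 3) for v in st.t]}
            for st in session.strokes
        ],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def _read_json(path: Path, xy_scale: float, t_scale: float) -> DrawingSession:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise InkParseError(f"{path}: invalid JSON: {e}") from None
    try:
        strokes = [
            Stroke(
                np.asarray(s["x_mm"], dtype=float) * xy_scale,
                np.asarray(s["y_mm"], dtype=float) * xy_scale,
                np.asarray(s["t_ms"], dtype=float) * t_scale,
            )
            for s in doc["strokes"]
        ]
        page = tuple(doc.get("page_mm", US_LETTER_MM))
        return DrawingSession(Condition(doc["condition"]), strokes, page)  # type: ignore[arg-type]
    except (KeyError, TypeError, ValueError) as e:
        raise InkParseError(f"{path}: malformed ink JSON: {e}") from None


# ---------------------------------------------------------------------------
# InkML subset: <ink><traceFormat><channel .../></traceFormat><trace>...</trace></ink>
# ---------------------------------------------------------------------------

_INKML_NS = "http://www.w3.org/2003/InkML"
_UNIT_TO_MM = {"mm": 1.0, "0.1mm": 0.1, "cm": 10.0, "m": 1000.0}
_UNIT_TO_MS = {"ms": 1.0, "s": 1000.0}


def _write_inkml(session: DrawingSession, path: Path, subject: str) -> None:
    E = lambda tag: etree.SubElement  # noqa: E731  (brevity)
    root = etree.Element("{%s}ink" % _INKML_NS, nsmap={None: _INKML_NS})
    root.set("documentID", subject)
    ann = etree.SubElement(root, "{%s}annotation" % _INKML_NS)
    ann.set("type", "condition")
    ann.text = session.condition.value
    fmt = etree.SubElement(root, "{%s}traceFormat" % _INKML_NS)
    for name, unit in (("X", "mm"), ("Y", "mm"), ("T", "ms")):
        ch = etree.SubElement(fmt, "{%s}channel" % _INKML_NS)
        ch.set("name", name)
        ch.set("type", "decimal")
        ch.set("units", unit)
    for st in session.strokes:
        tr = etree.SubElement(root, "{%s}trace" % _INKML_NS)
        tr.text = ", ".join(f"{x:.4f} {y:.4f} {t:.3f}" for x, y, t in zip(st.x, st.y, st.t))
    path.write_bytes(etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8"))


def _read_inkml(path: Path, xy_scale: float, t_scale: float) -> DrawingSession:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise InkParseError(f"{path}: invalid XML: {e}") from None
    root = tree.getroot()
    ns = {"i": _INKML_NS}
    cond = Condition.COMMAND
    for ann in root.findall("i:annotation", ns):
        if ann.get("type") == "condition" and ann.text:
            cond = Condition(ann.text.strip())
    sx = sy = xy_scale
    stt = t_scale
    for ch in root.findall("i:traceFormat/i:channel", ns):
        unit = ch.get("units", "")
        name = ch.get("name", "")
        if name in ("X", "Y") and unit:
            if unit not in _UNIT_TO_MM:
                raise InkParseError(f"{path}: channel {name}: unsupported unit '{unit}'")
            scale = _UNIT_TO_MM[unit] * xy_scale
            if name == "X":
                sx = scale
            else:
                sy = scale
        elif name == "T" and unit:
            if unit not in _UNIT_TO_MS:
                raise InkParseError(f"{path}: channel T: unsupported unit '{unit}'")
            stt = _UNIT_TO_MS[unit] * t_scale
    strokes = []
    for ti, tr in enumerate(root.findall("i:trace", ns)):
        pts = []
        for pi, chunk in enumerate((tr.text or "").split(",")):
            vals = chunk.split()
            if not vals:
                continue
            if len(vals) != 3:
                raise InkParseError(f"{path}: trace {ti} point {pi}: expected 'x y t'")
            try:
                pts.append(tuple(map(float, vals)))
            except ValueError:
                raise InkParseError(f"{path}: trace {ti} point {pi}: non-numeric value") from None
        if not pts:
            raise InkParseError(f"{path}: trace {ti} is empty")
        xs, ys, ts = zip(*pts)
        strokes.append(
            Stroke(np.asarray(xs) * sx, np.asarray(ys) * sy, np.asarray(ts) * stt)
        )
    if not strokes:
        raise InkParseError(f"{path}: no traces")
    return DrawingSession(cond, strokes)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

_READERS = {"csv": _read_csv, "json": _read_json, "inkml": _read_inkml}
_WRITERS = {"csv": _write_csv, "json": _write_json, "inkml": _write_inkml}


def read_ink(
    path: str | Path,
    format: str = "csv",
    *,
    xy_scale: float = 1.0,
    t_scale: float = 1.0,
    validate: bool = True,
) -> DrawingSession:
    """Read one drawing session from ``path``.

    Parameters
    ----------
    format : {"csv", "json", "inkml"}
    xy_scale, t_scale
        Multipliers applied to raw coordinate/time values to convert device
        units to mm/ms (e.g. ``xy_scale=0.1`` for a file recorded in 0.1-mm
        device units).  InkML channel ``units`` declarations are applied on
        top of these.
    validate
        When true (default) raise :class:`InkValidationError` if the parsed
        session violates a session invariant.
    """
    path = Path(path)
    if format not in _READERS:
        raise ValueError(f"unknown ink format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    session = _READERS[format](path, xy_scale, t_scale)
    if validate:
        _require_valid(session, str(path))
    return session


def write_ink(
    session: DrawingSession,
    path: str | Path,
    format: str = "csv",
    *,
    subject: str = "anon",
) -> Path:
    """Write a session; ``read_ink(write_ink(s))`` round-trips samples to
    the declared precision (0.05 mm, 1 ms)."""
    path = Path(path)
    if format not in _WRITERS:
        raise ValueError(f"unknown ink format {format!r}")
    if not session.strokes or any(len(st) == 0 for st in session.strokes):
        raise ValueError("cannot write a session with empty strokes")
    _WRITERS[format](session, path, subject)
    return path
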