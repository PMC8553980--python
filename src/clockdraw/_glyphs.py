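"""Stylized single-line stroke glyphs for clock digits.

Digits are rendered as parameterized polyline strokes with
class-distinguishing geometry (not handwriting-realistic).  Coordinates are
in a unit box: glyph height 1, y increasing downward, x in [0, ~0.6].
The same templates drive the synthetic generator and the default template
shape scorer.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

__all__ = [
    "GLYPHS",
    "CHAR_STROKE_COUNTS",
    "digit_chars",
    "digit_strokes",
    "digit_stroke_count",
    "digit_unit_length",
    "polyline_length",
    "resample_polyline",
]


def _arc(cx, cy, rx, ry, a0, a1, n=16, closed=False):
    th = np.linspace(a0, a1, n)
    pts = np.column_stack([cx + rx * np.cos(th), cy + ry * np.sin(th)])
    if closed:
        pts = np.vstack([pts, pts[:1]])
    return pts


def _poly(*pts):
    return np.asarray(pts, dtype=float)


# Each glyph: list of polyline strokes in a unit box (y down).  Multi-stroke
# characters are designed with near-coincident stroke centroids so the
# spatio-temporal grouper (centroid distance threshold) re-joins them
# reliably at realistic glyph sizes.
GLYPHS: dict[str, list[np.ndarray]] = {
    "0": [  # two half-ellipse arcs, left then right
        _arc(0.30, 0.50, 0.26, 0.47, 0.5 * math.pi, 1.5 * math.pi, n=12),
        _arc(0.30, 0.50, 0.26, 0.47, -0.5 * math.pi, 0.5 * math.pi, n=12),
    ],
    "1": [_poly((0.18, 0.18), (0.34, 0.02), (0.34, 1.00))],
    "2": [  # one continuous stroke, base included
        np.vstack([
            _arc(0.30, 0.26, 0.26, 0.24, -math.pi, 0.15, n=10),
            _poly((0.56, 0.32), (0.06, 0.96), (0.58, 0.96)),
        ]),
    ],
    "3": [
        _arc(0.26, 0.32, 0.28, 0.22, -0.75 * math.pi, 0.5 * math.pi, n=10),
        _arc(0.26, 0.68, 0.30, 0.24, -0.5 * math.pi, 0.75 * math.pi, n=10),
    ],
    "4": [
        _poly((0.44, 0.02), (0.04, 0.62), (0.60, 0.62)),
        _poly((0.44, 0.30), (0.44, 1.00)),
    ],
    "5": [  # one continuous stroke
        np.vstack([
            _poly((0.56, 0.04), (0.12, 0.04), (0.12, 0.42), (0.28, 0.38)),
            _arc(0.28, 0.68, 0.28, 0.28, -0.5 * math.pi, 0.6 * math.pi, n=10),
        ]),
    ],
    "6": [
        np.vstack([
            _poly((0.52, 0.04), (0.16, 0.48)),
            _arc(0.30, 0.74, 0.24, 0.25, -math.pi, math.pi, n=14),
        ])
    ],
    "7": [  # crossed seven: bar+diagonal, then crossbar
        _poly((0.04, 0.04), (0.58, 0.04), (0.18, 0.96)),
        _poly((0.14, 0.50), (0.46, 0.50)),
    ],
    "8": [
        _arc(0.30, 0.30, 0.22, 0.22, -0.5 * math.pi, 1.5 * math.pi, n=14),
        _arc(0.30, 0.68, 0.26, 0.24, -0.5 * math.pi, 1.5 * math.pi, n=14),
    ],
    "9": [
        _arc(0.32, 0.27, 0.24, 0.24, -0.1 * math.pi, 1.9 * math.pi, n=14),
        _poly((0.55, 0.24), (0.44, 1.00)),
    ],
}

#: glyphs are drawn squat (wider than tall) to keep multi-stroke centroids
#: within the grouping radius
_Y_SQUASH = 0.78
for _strokes in GLYPHS.values():
    for _s in _strokes:
        _s[:, 1] *= _Y_SQUASH

CHAR_STROKE_COUNTS = {c: len(s) for c, s in GLYPHS.items()}

#: Horizontal advance between adjacent characters of a two-character digit,
#: as a fraction of glyph scale.
CHAR_ADVANCE = 0.42


def polyline_length(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts, axis=0).T).sum())


def resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points equally spaced in arc length."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) == 1:
        return np.repeat(pts, n, axis=0)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, pts[:, 0]), np.interp(target, s, pts[:, 1])])


def digit_chars(value: int) -> str:
    if not 1 <= value <= 12:
        raise ValueError(f"digit value {value} outside 1..12")
    return str(value)


@lru_cache(maxsize=None)
def digit_strokes(value: int) -> tuple[np.ndarray, ...]:
    """Polyline strokes for a clock digit, centred on the origin, height 1."""
    chars = digit_chars(value)
    strokes: list[np.ndarray] = []
    x0 = -0.5 * CHAR_ADVANCE * (len(chars) - 1)
    for k, c in enumerate(chars):
        for st in GLYPHS[c]:
            pts = st.copy()
            pts[:, 0] += x0 + k * CHAR_ADVANCE - 0.31
            strokes.append(pts)
    # centre the composite on its bounding-box centre
    allpts = np.vstack(strokes)
    cx = (allpts[:, 0].max() + allpts[:, 0].min()) / 2.0
    cy = (allpts[:, 1].max() + allpts[:, 1].min()) / 2.0
    return tuple(s - np.array([cx, cy]) for s in strokes)


def digit_stroke_count(value: int) -> int:
    return len(digit_strokes(value))


@lru_cache(maxsize=None)
def digit_unit_length(value: int) -> float:
    return sum(polyline_length(s) for s in digit_strokes(value))
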